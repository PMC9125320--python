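"""Ortholog-based intersection with a reference peroxisomal proteome.

A quantified query protein is called peroxisomal when its ortholog appears
in the reference list. Membrane proteins take their category straight from
the reference compartment; matrix proteins are classified by scanning the
query sequence for a PTS1 (C-terminal tripeptide) then a PTS2 (N-terminal
nonapeptide), falling back to the reference entry's annotated PTS notation,
and finally to "matrix, no PTS". Query-organism sequence evidence therefore
outranks transferred annotation, which outranks nothing.
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

from .motifs import MotifTable, parse_pts_notation, scan_pts1, scan_pts2
from .types import (
    CATEGORY_MATRIX_NO_PTS,
    CATEGORY_MATRIX_PTS1,
    CATEGORY_MATRIX_PTS2,
    CATEGORY_MEMBRANE,
    NO_PTS,
    MinedProtein,
    MiningSummary,
    PeroxReferenceEntry,
    ProteinQuant,
    ProteinRecord,
    REGULATION_DOWN,
    REGULATION_NONE,
    REGULATION_UP,
)

_REFERENCE_ID_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9._-]*$")


def mine_peroxisomal(
    quants: Sequence[ProteinQuant],
    proteome: Sequence[ProteinRecord],
    orthomap: Mapping[str, str],
    reference: Sequence[PeroxReferenceEntry],
    motifs: MotifTable,
) -> list[MinedProtein]:
    """Intersect quantified proteins with the reference peroxisomal list."""
    seq_by_acc = {p.accession: p for p in proteome}
    ref_by_id: dict[str, PeroxReferenceEntry] = {}
    for entry in reference:
        prev = ref_by_id.get(entry.reference_id)
        if prev is not None and prev.compartment != entry.compartment:
            raise ValueError(
                f"reference ID {entry.reference_id!r} listed under both "
                "matrix and membrane"
            )
        ref_by_id[entry.reference_id] = entry

    mined: list[MinedProtein] = []
    for quant in quants:
        ref_id = orthomap.get(quant.accession)
        if ref_id is None:
            continue
        if not _REFERENCE_ID_RE.match(ref_id):
            raise ValueError(
                f"malformed reference ID {ref_id!r} for {quant.accession}"
            )
        entry = ref_by_id.get(ref_id)
        if entry is None:
            continue
        protein = seq_by_acc.get(quant.accession)
        if protein is None:
            raise ValueError(f"quantified accession {quant.accession} not in proteome")

        if entry.compartment == "membrane":
            category, pts = CATEGORY_MEMBRANE, NO_PTS
        else:
            pts = scan_pts1(protein.sequence, motifs)
            if pts.pts_type == "none" and len(protein.sequence) >= 9:
                pts = scan_pts2(protein.sequence, motifs)
            if pts.pts_type == "none" and entry.pts_notation:
                pts = parse_pts_notation(entry.pts_notation, motifs)
            if pts.pts_type == "PTS1":
                category = CATEGORY_MATRIX_PTS1
            elif pts.pts_type == "PTS2":
                category = CATEGORY_MATRIX_PTS2
            else:
                category = CATEGORY_MATRIX_NO_PTS

        mined.append(
            MinedProtein(
                accession=quant.accession,
                protein_name=protein.description or quant.accession,
                reference_id=ref_id,
                category=category,
                pts=pts,
                log2fc=quant.log2fc,
                q=quant.q,
                regulation=quant.regulation or REGULATION_NONE,
            )
        )
    return mined


def summarize_mining(mined: Sequence[MinedProtein]) -> MiningSummary:
    """Exact category and regulation tallies; internal sums reconcile."""
    pts1 = sum(1 for m in mined if m.category == CATEGORY_MATRIX_PTS1)
    pts2 = sum(1 for m in mined if m.category == CATEGORY_MATRIX_PTS2)
    no_pts = sum(1 for m in mined if m.category == CATEGORY_MATRIX_NO_PTS)
    membrane = sum(1 for m in mined if m.category == CATEGORY_MEMBRANE)
    up = sum(1 for m in mined if m.regulation == REGULATION_UP)
    down = sum(1 for m in mined if m.regulation == REGULATION_DOWN)
    none = sum(1 for m in mined if m.regulation == REGULATION_NONE)
    return MiningSummary(
        total=len(mined),
        matrix=pts1 + pts2 + no_pts,
        membrane=membrane,
        pts1=pts1,
        pts2=pts2,
        no_pts=no_pts,
        up=up,
        down=down,
        none=none,
    )
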