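"""Readers and writers for every external format the pipeline touches.

All tabular interchange files are UTF-8, tab-delimited, with a mandatory
header row; lines starting with ``#`` are skipped. FASTA goes through
Biopython. The experimental design is a small YAML document.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    CONDITION_A,
    CONDITION_B,
    DesignSpec,
    MinedProtein,
    PeroxReferenceEntry,
    ProteinRecord,
    PSMRecord,
)

log = logging.getLogger(__name__)

PSM_FIXED_COLUMNS = ("spectrum_id", "peptide", "proteins", "score", "is_decoy")

MINED_REPORT_COLUMNS = (
    "protein_name",
    "accession",
    "reference_ortholog",
    "category",
    "pts_type",
    "pts_motif",
    "pts_tier",
    "log2FC",
    "q",
    "regulation",
)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased and a single trailing ``*`` stop character is
    stripped so that C-terminal tripeptide extraction is well defined.
    Duplicate accessions and empty files are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if rec.id in seen:
            raise ValueError(f"duplicate accession in FASTA: {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(accession=rec.id, sequence=seq, description=rec.description)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# tab-delimited helpers

def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# design

def read_design(path: str | Path) -> DesignSpec:
    """Load an experimental design from YAML.

    Expected keys: ``channels`` (channel label -> sample name) and
    ``conditions`` (sample name -> "A" | "B").
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return DesignSpec(
        channel_to_sample={str(k): str(v) for k, v in doc["channels"].items()},
        sample_to_condition={str(k): str(v) for k, v in doc["conditions"].items()},
    )


def write_design(design: DesignSpec, path: str | Path) -> None:
    doc = {
        "channels": dict(design.channel_to_sample),
        "conditions": dict(design.sample_to_condition),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# PSM table

def read_psm_table(path: str | Path, design: DesignSpec) -> list[PSMRecord]:
    """Read the PSM/reporter-intensity TSV defined by the pipeline contract.

    Required columns: ``spectrum_id``, ``peptide``, ``proteins``
    (';'-separated accessions), ``score``, ``is_decoy``, plus one intensity
    column per channel label of ``design``. Missing intensity cells become 0
    (a warning reports how many); negative intensities are an error.
    """
    df = _read_tsv(path)
    missing = [c for c in PSM_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table missing required column(s): {missing}")
    missing_channels = [ch for ch in design.channels if ch not in df.columns]
    if missing_channels:
        raise ValueError(f"PSM table missing channel column(s): {missing_channels}")

    n_blank = 0
    records: list[PSMRecord] = []
    # channel labels like "113" are not valid identifiers, so no itertuples
    for _, row in df.iterrows():
        intensities = {}
        for ch in design.channels:
            cell = str(row[ch]).strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                n_blank += 1
                val = 0.0
            else:
                val = float(cell)
            if val < 0:
                raise ValueError(
                    f"negative intensity {val} in channel {ch} "
                    f"(spectrum {row['spectrum_id']})"
                )
            intensities[ch] = val
        records.append(
            PSMRecord(
                spectrum_id=str(row["spectrum_id"]),
                peptide=str(row["peptide"]),
                protein_accessions=tuple(
                    p for p in str(row["proteins"]).split(";") if p
                ),
                score=float(row["score"]),
                is_decoy=str(row["is_decoy"]).strip().lower() in ("1", "true", "yes"),
                intensities=intensities,
            )
        )
    if n_blank:
        log.warning("%d missing reporter intensity cells set to 0", n_blank)
    return records


def write_psm_table(
    psms: Sequence[PSMRecord], design: DesignSpec, path: str | Path
) -> None:
    cols = list(PSM_FIXED_COLUMNS) + list(design.channels)
    rows = []
    for p in psms:
        rows.append(
            [
                p.spectrum_id,
                p.peptide,
                ";".join(p.protein_accessions),
                repr(p.score) if isinstance(p.score, float) else p.score,
                "1" if p.is_decoy else "0",
            ]
            + [repr(float(p.intensities[ch])) for ch in design.channels]
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ortholog map and reference list

def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Read query accession -> reference gene ID (one best hit per query)."""
    df = _read_tsv(path)
    for col in ("query_accession", "reference_id"):
        if col not in df.columns:
            raise ValueError(f"ortholog map missing column {col!r}")
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        q = str(row["query_accession"]).strip()
        r = str(row["reference_id"]).strip()
        if q in mapping and mapping[q] != r:
            raise ValueError(f"query {q!r} mapped to more than one reference ID")
        mapping[q] = r
    return mapping


def write_ortholog_map(mapping: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(mapping.items()), columns=["query_accession", "reference_id"]
    ).to_csv(path, sep="\t", index=False)


def read_reference_list(path: str | Path) -> list[PeroxReferenceEntry]:
    df = _read_tsv(path)
    for col in ("reference_id", "compartment"):
        if col not in df.columns:
            raise ValueError(f"reference list missing column {col!r}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            PeroxReferenceEntry(
                reference_id=str(row["reference_id"]).strip(),
                compartment=str(row["compartment"]).strip(),
                pts_notation=str(row.get("pts_notation", "")).strip(),
                notes=str(row.get("notes", "")).strip(),
            )
        )
    return entries


def write_reference_list(
    entries: Sequence[PeroxReferenceEntry], path: str | Path
) -> None:
    pd.DataFrame(
        [
            (e.reference_id, e.compartment, e.pts_notation, e.notes)
            for e in entries
        ],
        columns=["reference_id", "compartment", "pts_notation", "notes"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mined report

def write_mined_report(
    mined: Sequence[MinedProtein],
    path: str | Path,
    summary_path: str | Path | None = None,
) -> dict[str, int]:
    """Write the mined peroxisomal proteome as TSV plus a JSON summary.

    Returns the summary counts (total / per-category / per-regulation).
    """
    from .mining import summarize_mining  # local import avoids a cycle

    rows = []
    for m in mined:
        rows.append(
            [
                m.protein_name,
                m.accession,
                m.reference_id,
                m.category,
                m.pts.pts_type,
                m.pts.motif,
                m.pts.tier,
                "" if m.log2fc is None else f"{m.log2fc:.4g}",
                "" if m.q is None else f"{m.q:.4g}",
                m.regulation,
            ]
        )
    pd.DataFrame(rows, columns=list(MINED_REPORT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
    summary = summarize_mining(mined).as_dict()
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)
            fh.write("\n")
    return summary
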