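"""Peroxisomal targeting-signal (PTS) detection and notation parsing.

Two import signals are recognized:

* **PTS1** — a C-terminal tripeptide (prototype SKL) bound by the PEX5
  receptor. Detection is accept-list driven: the shipped table combines the
  classical [SA][KR][LMI]-style family with non-classical tripeptides that
  have been observed on genuine peroxisomal matrix proteins (ANL, ASL, TNL,
  SSV, SAK, SNM, ...), each carrying a confidence tier.
* **PTS2** — an N-terminal nonapeptide R[LIQV]-x5-H[LF] bound by PEX7,
  searched within a configurable window from the N-terminus (default 40
  residues, covering cleavable presequences).

Annotation strings of the form ``"SKL"``, ``"RIx5HL"`` or ``"QKL
(internal)"`` — the compact notation used in curated peroxisomal proteome
lists — are parsed by :func:`parse_pts_notation` into the same call type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .types import NO_PTS, PTSCall

_PTS2_NOTATION_RE = re.compile(r"^([A-Z]{2})x5([A-Z]{2})$")
_PTS1_NOTATION_RE = re.compile(r"^([A-Z]{3})(?:\s*\((internal)\))?$")


@dataclass(frozen=True)
class MotifTable:
    """Accept-list of PTS1 tripeptides and the PTS2 nonapeptide pattern."""

    pts1: dict[str, str]  # tripeptide -> tier (canonical|verified|putative)
    pts2_pos1: frozenset[str] = frozenset("R")
    pts2_pos2: frozenset[str] = frozenset("LIQV")
    pts2_pos8: frozenset[str] = frozenset("H")
    pts2_pos9: frozenset[str] = frozenset("LF")
    pts2_gap: int = 5
    pts2_window: int = 40

    def __post_init__(self) -> None:
        for tri, tier in self.pts1.items():
            if len(tri) != 3 or not tri.isupper():
                raise ValueError(f"PTS1 entries must be uppercase tripeptides: {tri!r}")
            if tier not in ("canonical", "verified", "putative"):
                raise ValueError(f"unknown tier {tier!r} for {tri!r}")
        if self.pts2_gap != 5:
            raise ValueError("the PTS2 gap is fixed at 5 residues")

    def pts2_matches_frame(self, frame: str) -> bool:
        """True when a 9-residue frame fits the PTS2 pattern."""
        if len(frame) != 2 + self.pts2_gap + 2:
            return False
        return (
            frame[0] in self.pts2_pos1
            and frame[1] in self.pts2_pos2
            and frame[7] in self.pts2_pos8
            and frame[8] in self.pts2_pos9
        )


def load_motif_table(path: str | Path) -> MotifTable:
    """Load a motif table from its YAML config (see data/motifs.yaml)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    pts1 = {str(k).upper(): str(v) for k, v in doc["pts1"].items()}
    pts2 = doc.get("pts2", {})
    return MotifTable(
        pts1=pts1,
        pts2_pos1=frozenset(pts2.get("pos1", "R")),
        pts2_pos2=frozenset(pts2.get("pos2", "LIQV")),
        pts2_pos8=frozenset(pts2.get("pos8", "H")),
        pts2_pos9=frozenset(pts2.get("pos9", "LF")),
        pts2_gap=int(pts2.get("gap", 5)),
        pts2_window=int(pts2.get("window", 40)),
    )


def default_motif_table() -> MotifTable:
    """The shipped motif table (data/motifs.yaml)."""
    ref = resources.files("peroxmine.data").joinpath("motifs.yaml")
    with resources.as_file(ref) as path:
        return load_motif_table(path)


def scan_pts1(seq: str, table: MotifTable) -> PTSCall:
    """Check the final three residues of ``seq`` against the PTS1 accept-list.

    Only C-terminal signals are found here; internal PTS1-like signals
    (e.g. the catalase QKL) come from reference annotation, not scanning.
    """
    if len(seq) < 3:
        raise ValueError(f"sequence too short for PTS1 scan (len {len(seq)})")
    tri = seq[-3:].upper()
    tier = table.pts1.get(tri)
    if tier is None:
        return NO_PTS
    return PTSCall(
        pts_type="PTS1",
        motif=tri,
        location="c_terminal",
        tier=tier,
        position=len(seq) - 2,
    )


def scan_pts2(seq: str, table: MotifTable) -> PTSCall:
    """Slide the 9-residue PTS2 frame over the N-terminal window.

    The first (most N-terminal) matching frame wins; frames starting after
    ``table.pts2_window`` are ignored.
    """
    if len(seq) < 9:
        raise ValueError(f"sequence too short for PTS2 scan (len {len(seq)})")
    s = seq.upper()
    frame_len = 2 + table.pts2_gap + 2
    last_start = min(table.pts2_window, len(s) - frame_len + 1)
    for start in range(last_start):
        frame = s[start : start + frame_len]
        if table.pts2_matches_frame(frame):
            return PTSCall(
                pts_type="PTS2",
                motif=frame,
                location="n_terminal",
                tier="canonical",
                position=start + 1,
            )
    return NO_PTS


def parse_pts_notation(s: str, table: MotifTable | None = None) -> PTSCall:
    """Parse a compact PTS annotation string into a :class:`PTSCall`.

    ``"XXx5YY"`` is a PTS2 nonapeptide pattern; a bare tripeptide is a
    C-terminal PTS1 (tier looked up in ``table`` when given, otherwise
    ``notation``); a ``"(internal)"`` suffix marks an internal PTS1-like
    signal; ``"-"``, an en-dash, ``"NA"`` or the empty string mean no PTS.
    """
    text = s.strip()
    if text in ("", "-", "–", "—", "NA", "none"):
        return NO_PTS
    m = _PTS2_NOTATION_RE.match(text)
    if m:
        return PTSCall(
            pts_type="PTS2",
            motif=text,
            location="n_terminal",
            tier="notation",
        )
    m = _PTS1_NOTATION_RE.match(text)
    if m:
        tri, internal = m.group(1), m.group(2)
        tier = "notation"
        if table is not None and tri in table.pts1:
            tier = table.pts1[tri]
        return PTSCall(
            pts_type="PTS1",
            motif=tri,
            location="internal" if internal else "c_terminal",
            tier=tier,
        )
    raise ValueError(f"unparseable PTS notation: {s!r}")
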