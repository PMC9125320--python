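"""Domain types shared across the peroxisome-mining pipeline.

The pipeline moves through a fixed chain of evidence:

PSM (peptide-spectrum match, 8 reporter channels)
  -> FDR-filtered peptide
  -> per-protein reporter matrix (``ProteinQuant``)
  -> ortholog-transferred peroxisomal annotation (``MinedProtein``).

Conditions follow the green/red fruit-ripening contrast: condition ``A``
is the immature (green) stage, condition ``B`` the ripe (red) stage, and
log2FC = log2(B) - log2(A) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

N_CHANNELS = 8
#: Standard iTRAQ 8-plex reporter labels.
DEFAULT_CHANNELS = ("113", "114", "115", "116", "117", "118", "119", "121")

CONDITION_A = "A"  # green / immature
CONDITION_B = "B"  # red / ripe

REGULATION_UP = "UP"
REGULATION_DOWN = "DOWN"
REGULATION_NONE = "NONE"

CATEGORY_MATRIX_PTS1 = "matrix_pts1"
CATEGORY_MATRIX_PTS2 = "matrix_pts2"
CATEGORY_MATRIX_NO_PTS = "matrix_no_pts"
CATEGORY_MEMBRANE = "membrane"
CATEGORIES = (
    CATEGORY_MATRIX_PTS1,
    CATEGORY_MATRIX_PTS2,
    CATEGORY_MATRIX_NO_PTS,
    CATEGORY_MEMBRANE,
)


@dataclass(frozen=True)
class ProteinRecord:
    """One entry of a query proteome."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for {self.accession!r}")
        if any(ch.isspace() for ch in self.sequence):
            raise ValueError(f"whitespace inside sequence of {self.accession!r}")


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match with its 8 reporter-channel intensities."""

    spectrum_id: str
    peptide: str
    protein_accessions: tuple[str, ...]
    score: float
    is_decoy: bool
    intensities: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.intensities) != N_CHANNELS:
            raise ValueError(
                f"{self.spectrum_id}: expected {N_CHANNELS} reporter channels, "
                f"got {len(self.intensities)}"
            )
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError(f"{self.spectrum_id}: negative reporter intensity")


@dataclass(frozen=True)
class DesignSpec:
    """8-plex experimental design: channel -> sample -> condition (A or B)."""

    channel_to_sample: Mapping[str, str]
    sample_to_condition: Mapping[str, str]

    def __post_init__(self) -> None:
        samples = list(self.channel_to_sample.values())
        if len(samples) != len(set(samples)):
            raise ValueError("a sample is assigned to more than one channel")
        conds = set(self.sample_to_condition.values())
        if not conds <= {CONDITION_A, CONDITION_B}:
            raise ValueError(f"conditions must be {{A, B}}, got {sorted(conds)}")
        for sample in samples:
            if sample not in self.sample_to_condition:
                raise ValueError(f"sample {sample!r} has no condition assigned")
        for cond in (CONDITION_A, CONDITION_B):
            if len(self.channels_for(cond)) < 2:
                raise ValueError(f"condition {cond} needs >= 2 replicate channels")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.channel_to_sample)

    def condition_of_channel(self, channel: str) -> str:
        return self.sample_to_condition[self.channel_to_sample[channel]]

    def channels_for(self, condition: str) -> tuple[str, ...]:
        return tuple(
            ch for ch in self.channel_to_sample
            if self.condition_of_channel(ch) == condition
        )

    def swapped(self) -> "DesignSpec":
        """Design with the A/B condition labels exchanged."""
        flip = {CONDITION_A: CONDITION_B, CONDITION_B: CONDITION_A}
        return DesignSpec(
            channel_to_sample=dict(self.channel_to_sample),
            sample_to_condition={
                s: flip[c] for s, c in self.sample_to_condition.items()
            },
        )


def default_design(n_per_condition: int = 4) -> DesignSpec:
    """4+4 design on the standard iTRAQ 8-plex channels (A first, B last)."""
    if 2 * n_per_condition != N_CHANNELS:
        raise ValueError("default design uses all 8 channels")
    chan_map = {}
    cond_map = {}
    for i, ch in enumerate(DEFAULT_CHANNELS):
        cond = CONDITION_A if i < n_per_condition else CONDITION_B
        sample = f"{cond}{(i % n_per_condition) + 1}"
        chan_map[ch] = sample
        cond_map[sample] = cond
    return DesignSpec(channel_to_sample=chan_map, sample_to_condition=cond_map)


@dataclass
class ScoredPeptide:
    """A distinct peptide with its best search score and target-decoy q-value."""

    peptide: str
    score: float
    is_decoy: bool
    q: float | None = None


@dataclass
class ProteinQuant:
    """Per-protein reporter matrix plus the differential-abundance summary."""

    accession: str
    intensities: dict[str, float]
    n_peptides: int
    log2fc: float | None = None
    p: float | None = None
    q: float | None = None
    regulation: str | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class PTSCall:
    """Outcome of peroxisomal targeting-signal detection for one sequence.

    ``tier`` records provenance of the call: ``canonical``/``verified``/
    ``putative`` for accept-list tripeptides, ``notation`` for calls parsed
    from an annotation string rather than found by scanning.
    """

    pts_type: str  # "PTS1" | "PTS2" | "none"
    motif: str = ""
    location: str = ""  # "c_terminal" | "n_terminal" | "internal" | ""
    tier: str = ""  # "canonical" | "verified" | "putative" | "notation" | ""
    position: int = 0  # 1-based start offset; 0 when pts_type == "none"

    def __post_init__(self) -> None:
        if self.pts_type == "none" and self.motif:
            raise ValueError("a 'none' call cannot carry a motif")


NO_PTS = PTSCall(pts_type="none")


@dataclass(frozen=True)
class PeroxReferenceEntry:
    """One protein of the reference (Arabidopsis-style) peroxisomal list."""

    reference_id: str
    compartment: str  # "matrix" | "membrane"
    pts_notation: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in ("matrix", "membrane"):
            raise ValueError(
                f"{self.reference_id}: compartment must be matrix or membrane, "
                f"got {self.compartment!r}"
            )


@dataclass
class MinedProtein:
    """One row of the mined peroxisomal proteome (a Tables-style entry)."""

    accession: str
    protein_name: str
    reference_id: str
    category: str
    pts: PTSCall
    log2fc: float | None = None
    q: float | None = None
    regulation: str = REGULATION_NONE

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        expected = {
            CATEGORY_MATRIX_PTS1: "PTS1",
            CATEGORY_MATRIX_PTS2: "PTS2",
            CATEGORY_MATRIX_NO_PTS: "none",
        }
        if self.category in expected and self.pts.pts_type != expected[self.category]:
            raise ValueError(
                f"{self.accession}: category {self.category} inconsistent with "
                f"PTS call {self.pts.pts_type}"
            )


@dataclass(frozen=True)
class MiningSummary:
    """Category and regulation tallies over a mined protein list."""

    total: int
    matrix: int
    membrane: int
    pts1: int
    pts2: int
    no_pts: int
    up: int
    down: int
    none: int

    def __post_init__(self) -> None:
        if self.total != self.matrix + self.membrane:
            raise ValueError("total != matrix + membrane")
        if self.matrix != self.pts1 + self.pts2 + self.no_pts:
            raise ValueError("matrix != pts1 + pts2 + no_pts")
        if self.up + self.down + self.none != self.total:
            raise ValueError("up + down + none != total")

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "matrix": self.matrix,
            "membrane": self.membrane,
            "pts1": self.pts1,
            "pts2": self.pts2,
            "no_pts": self.no_pts,
            "up": self.up,
            "down": self.down,
            "none": self.none,
        }
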