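"""Synthetic 8-plex experiment generator with planted ground truth.

Emulates the full input side of the pipeline so the analysis runs without
any downloaded data: a random query proteome with peroxisomal targeting
signals planted per category, an ortholog map into a fabricated AGI-style
reference namespace, a reference peroxisomal list, and a PSM/reporter table
with known per-protein log2 fold changes, decoy PSMs and a tunable
co-isolation contamination fraction.

Reporter model (per peptide, per channel)::

    I_true  = base * 2**(s * f/2 + eps)      s = +1 (B) or -1 (A)
    I_obs   = (1 - c) * I_true + c * B_bg    eps ~ N(0, noise_sd)

where ``f`` is the protein's true log2FC, ``c`` the contamination fraction
and ``B_bg`` a background level common to all 8 channels of a spectrum
(the co-isolated background contributes equally to every reporter, which is
exactly the mechanism that compresses measured ratios toward 1). ``B_bg``
is the global mean true intensity times a lognormal jitter. For a true
ratio R and background at the mean of the channel signals this yields the
closed-form compressed ratio ((1-c)R + c m)/((1-c) + c m), m = (R+1)/2.

Planted motifs are exactly recoverable: the generator scrubs accidental
accept-list tripeptides at the C-terminus and accidental PTS2 frames in the
N-terminal window of proteins that are not supposed to carry them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as pio
from .motifs import MotifTable, default_motif_table
from .types import (
    AMINO_ACIDS,
    CATEGORY_MATRIX_NO_PTS,
    CATEGORY_MATRIX_PTS1,
    CATEGORY_MATRIX_PTS2,
    CATEGORY_MEMBRANE,
    DesignSpec,
    PeroxReferenceEntry,
    ProteinRecord,
    PSMRecord,
    ScoredPeptide,
    default_design,
)

#: Category proportions of the mined pepper peroxisomal proteome
#: (PTS1 : PTS2 : no-PTS : membrane = 36 : 8 : 5 : 8).
DEFAULT_CATEGORY_MIX = (36 / 57, 8 / 57, 5 / 57, 8 / 57)

_CATEGORIES = (
    CATEGORY_MATRIX_PTS1,
    CATEGORY_MATRIX_PTS2,
    CATEGORY_MATRIX_NO_PTS,
    CATEGORY_MEMBRANE,
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic 8-plex experiment.

    Defaults mirror the emulated experiment: 4+4 biological replicates,
    moderate log2-scale reporter noise, roughly 40% of proteins truly
    regulated with unit log2 fold change, and no co-isolation contamination
    unless ratio compression is under study.
    """

    n_proteins: int = 400
    frac_perox: float = 0.25
    category_mix: tuple[float, float, float, float] = DEFAULT_CATEGORY_MIX
    peptides_per_protein: tuple[int, int] = (4, 8)  # uniform inclusive range
    n_replicates: int = 4
    #: (value, weight) point masses for the true log2FC distribution
    log2fc_point_masses: tuple[tuple[float, float], ...] = (
        (0.0, 0.6),
        (1.0, 0.2),
        (-1.0, 0.2),
    )
    #: assign point masses to exact (largest-remainder) protein counts,
    #: randomly permuted, instead of i.i.d. draws
    stratify_log2fc: bool = True
    noise_sd: float = 0.25  # log2 scale
    contamination: float = 0.0  # co-isolation fraction c in [0, 1)
    decoy_ratio: float = 1.0
    false_target_frac: float = 0.0
    target_score_loc: float = 7.0  # Gumbel location of true-target scores
    decoy_score_loc: float = 0.0  # Gumbel location of decoy/false scores
    base_log2_mean: float = 20.0
    base_log2_sd: float = 1.5
    seq_length: tuple[int, int] = (150, 600)
    peptide_length: tuple[int, int] = (8, 20)
    shared_peptide_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_perox <= 1:
            raise ValueError("frac_perox must be in [0, 1]")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category mix proportions must sum to 1")
        if not 0 <= self.contamination < 1:
            raise ValueError("contamination must be in [0, 1)")
        total_w = sum(w for _, w in self.log2fc_point_masses)
        if abs(total_w - 1.0) > 1e-9:
            raise ValueError("log2FC point-mass weights must sum to 1")


@dataclass
class SimTruth:
    """Planted ground truth covering every emitted record."""

    categories: dict[str, str] = field(default_factory=dict)  # acc -> category
    motifs: dict[str, str] = field(default_factory=dict)  # acc -> planted motif
    log2fc: dict[str, float] = field(default_factory=dict)  # acc -> true log2FC
    reference_ids: dict[str, str] = field(default_factory=dict)
    #: spectrum_id -> generating accession ("decoy:..." for decoys,
    #: "false:<acc>" for false target matches)
    psm_origin: dict[str, str] = field(default_factory=dict)

    def planted_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in _CATEGORIES}
        for cat in self.categories.values():
            if cat in counts:
                counts[cat] += 1
        return {
            "total": sum(counts.values()),
            "matrix": counts[CATEGORY_MATRIX_PTS1]
            + counts[CATEGORY_MATRIX_PTS2]
            + counts[CATEGORY_MATRIX_NO_PTS],
            "membrane": counts[CATEGORY_MEMBRANE],
            "pts1": counts[CATEGORY_MATRIX_PTS1],
            "pts2": counts[CATEGORY_MATRIX_PTS2],
            "no_pts": counts[CATEGORY_MATRIX_NO_PTS],
        }


def _apportion(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items over proportions."""
    raw = [n * p for p in proportions]
    counts = [int(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(AMINO_ACIDS), size=length))


def _scrub_accidental_motifs(
    seq: list[str], table: MotifTable, protect_from: int | None = None
) -> None:
    """Remove accept-list tripeptides at the C-terminus and PTS2 frames in
    the N-terminal window (in place). Frames at or after ``protect_from``
    (0-based) are left alone."""
    if "".join(seq[-3:]) in table.pts1:
        seq[-1] = "G"  # no accept-list tripeptide ends in G
    frame_len = 2 + table.pts2_gap + 2
    for start in range(min(table.pts2_window, len(seq) - frame_len + 1)):
        if protect_from is not None and start >= protect_from:
            break
        if table.pts2_matches_frame("".join(seq[start : start + frame_len])):
            seq[start] = "G" if "G" not in table.pts2_pos1 else "P"


def generate_proteome(
    config: SimConfig,
    motifs: MotifTable | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ProteinRecord], SimTruth, dict[str, str], list[PeroxReferenceEntry]]:
    """Random proteome with planted PTS motifs, ortholog map and reference.

    Peroxisomal proteins (``frac_perox`` of the proteome, apportioned over
    the category mix by largest remainder so counts are deterministic) get
    a fabricated AGI-style reference entry with the correct compartment;
    background proteins get ortholog IDs absent from the reference.
    """
    if motifs is None:
        motifs = default_motif_table()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_perox = round(config.n_proteins * config.frac_perox)
    if n_perox < 1 and any(p > 0 for p in config.category_mix):
        raise ValueError("frac_perox * n_proteins < 1: no peroxisomal proteins")
    cat_counts = _apportion(n_perox, config.category_mix)
    categories = [
        cat for cat, cnt in zip(_CATEGORIES, cat_counts) for _ in range(cnt)
    ]
    categories += ["background"] * (config.n_proteins - n_perox)

    fc_values = np.array([v for v, _ in config.log2fc_point_masses])
    fc_weights = np.array([w for _, w in config.log2fc_point_masses])
    if config.stratify_log2fc:
        fc_counts = _apportion(config.n_proteins, fc_weights)
        fc_pool = np.repeat(fc_values, fc_counts)
        fc_assigned = fc_pool[rng.permutation(config.n_proteins)]
    pts1_choices = sorted(motifs.pts1)

    truth = SimTruth()
    records: list[ProteinRecord] = []
    orthomap: dict[str, str] = {}
    reference: list[PeroxReferenceEntry] = []

    for idx, category in enumerate(categories):
        acc = f"CA{idx:05d}"
        length = int(rng.integers(config.seq_length[0], config.seq_length[1] + 1))
        seq = _random_sequence(rng, length)
        motif = ""
        notation = ""
        if category == CATEGORY_MATRIX_PTS1:
            motif = str(rng.choice(pts1_choices))
            _scrub_accidental_motifs(seq, motifs)
            seq = seq + list(motif)
            notation = motif
        elif category == CATEGORY_MATRIX_PTS2:
            frame = (
                str(rng.choice(sorted(motifs.pts2_pos1)))
                + str(rng.choice(sorted(motifs.pts2_pos2)))
                + "".join(rng.choice(list(AMINO_ACIDS), size=motifs.pts2_gap))
                + str(rng.choice(sorted(motifs.pts2_pos8)))
                + str(rng.choice(sorted(motifs.pts2_pos9)))
            )
            start = int(rng.integers(1, motifs.pts2_window - len(frame) + 1))
            _scrub_accidental_motifs(seq, motifs)
            seq[start : start + len(frame)] = list(frame)
            motif = frame
            notation = f"{frame[:2]}x5{frame[-2:]}"
        else:
            _scrub_accidental_motifs(seq, motifs)

        sequence = "".join(seq)
        ref_id = f"At{(idx % 5) + 1}g{(idx + 1) * 10:05d}"
        records.append(
            ProteinRecord(accession=acc, sequence=sequence, description=f"{acc} {category}")
        )
        orthomap[acc] = ref_id
        truth.categories[acc] = category
        truth.motifs[acc] = motif
        truth.reference_ids[acc] = ref_id
        truth.log2fc[acc] = (
            float(fc_assigned[idx])
            if config.stratify_log2fc
            else float(rng.choice(fc_values, p=fc_weights))
        )
        if category != "background":
            reference.append(
                PeroxReferenceEntry(
                    reference_id=ref_id,
                    compartment="membrane"
                    if category == CATEGORY_MEMBRANE
                    else "matrix",
                    pts_notation=notation,
                )
            )
    return records, truth, orthomap, reference


def generate_psms(
    proteome: Sequence[ProteinRecord],
    truth: SimTruth,
    config: SimConfig,
    design: DesignSpec | None = None,
    rng: np.random.Generator | None = None,
) -> list[PSMRecord]:
    """Emit the PSM/reporter table for a generated proteome.

    Peptides are unique random substrings of their parent protein; true
    targets score Gumbel(``target_score_loc``, 1), false targets and decoys
    Gumbel(``decoy_score_loc``, 1). Contamination mixes each spectrum's
    true signal with a channel-constant background (see module docstring).
    """
    if design is None:
        design = default_design(config.n_replicates)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    c = config.contamination
    channels = design.channels
    signs = np.array(
        [1.0 if design.condition_of_channel(ch) == "B" else -1.0 for ch in channels]
    )

    used_peptides: set[str] = set()

    def draw_peptide(sequence: str) -> str:
        for _ in range(200):
            plen = int(rng.integers(config.peptide_length[0], config.peptide_length[1] + 1))
            if plen >= len(sequence):
                plen = max(6, len(sequence) - 1)
            start = int(rng.integers(0, len(sequence) - plen + 1))
            pep = sequence[start : start + plen]
            if pep not in used_peptides:
                used_peptides.add(pep)
                return pep
        raise RuntimeError("could not draw a unique peptide")

    def random_peptide() -> str:
        for _ in range(200):
            plen = int(rng.integers(config.peptide_length[0], config.peptide_length[1] + 1))
            pep = "".join(rng.choice(list(AMINO_ACIDS), size=plen))
            if pep not in used_peptides:
                used_peptides.add(pep)
                return pep
        raise RuntimeError("could not draw a unique random peptide")

    # pass 1: true intensity matrices
    entries: list[dict] = []
    for protein in proteome:
        n_pep = int(
            rng.integers(
                config.peptides_per_protein[0], config.peptides_per_protein[1] + 1
            )
        )
        f = truth.log2fc[protein.accession]
        for _ in range(n_pep):
            pep = draw_peptide(protein.sequence)
            base = 2.0 ** rng.normal(config.base_log2_mean, config.base_log2_sd)
            eps = rng.normal(0.0, config.noise_sd, size=len(channels))
            intensity = base * 2.0 ** (signs * (f / 2.0) + eps)
            false_target = rng.random() < config.false_target_frac
            loc = config.decoy_score_loc if false_target else config.target_score_loc
            entries.append(
                {
                    "peptide": pep,
                    "accession": protein.accession,
                    "intensity": intensity,
                    "score": float(rng.gumbel(loc, 1.0)),
                    "decoy": False,
                    "false": false_target,
                }
            )
    n_targets = len(entries)
    n_decoys = int(round(config.decoy_ratio * n_targets))
    for i in range(n_decoys):
        pep = random_peptide()
        base = 2.0 ** rng.normal(config.base_log2_mean, config.base_log2_sd)
        eps = rng.normal(0.0, config.noise_sd, size=len(channels))
        intensity = base * 2.0 ** eps
        entries.append(
            {
                "peptide": pep,
                "accession": f"DECOY{i:05d}",
                "intensity": intensity,
                "score": float(rng.gumbel(config.decoy_score_loc, 1.0)),
                "decoy": True,
                "false": False,
            }
        )

    global_mean = float(np.mean([e["intensity"] for e in entries]))

    # pass 2: apply co-isolation contamination, assemble records
    psms: list[PSMRecord] = []
    shared_pool = [p.accession for p in proteome]
    for i, e in enumerate(entries):
        spectrum_id = f"spec{i:06d}"
        background = global_mean * 2.0 ** rng.normal(0.0, config.noise_sd)
        observed = (1.0 - c) * e["intensity"] + c * background
        accessions = (e["accession"],)
        if (
            not e["decoy"]
            and config.shared_peptide_frac > 0
            and rng.random() < config.shared_peptide_frac
        ):
            other = str(rng.choice(shared_pool))
            if other != e["accession"]:
                accessions = (e["accession"], other)
        psms.append(
            PSMRecord(
                spectrum_id=spectrum_id,
                peptide=e["peptide"],
                protein_accessions=accessions,
                score=e["score"],
                is_decoy=e["decoy"],
                intensities={ch: float(v) for ch, v in zip(channels, observed)},
            )
        )
        if e["decoy"]:
            origin = f"decoy:{e['accession']}"
        elif e["false"]:
            origin = f"false:{e['accession']}"
        else:
            origin = e["accession"]
        truth.psm_origin[spectrum_id] = origin
    return psms


def simulate_scored_peptides(
    n_true: int,
    n_false: int,
    n_decoy: int,
    target_loc: float = 7.0,
    null_loc: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[ScoredPeptide], set[str]]:
    """Scored peptide list for FDR calibration experiments.

    True targets score Gumbel(``target_loc``, 1); false targets and decoys
    share the Gumbel(``null_loc``, 1) null. Returns the peptides and the
    set of false-target peptide IDs (the planted labels).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    peptides: list[ScoredPeptide] = []
    false_ids: set[str] = set()
    for i in range(n_true):
        peptides.append(
            ScoredPeptide(f"T{i:06d}", float(rng.gumbel(target_loc, 1.0)), False)
        )
    for i in range(n_false):
        name = f"F{i:06d}"
        peptides.append(ScoredPeptide(name, float(rng.gumbel(null_loc, 1.0)), False))
        false_ids.add(name)
    for i in range(n_decoy):
        peptides.append(
            ScoredPeptide(f"D{i:06d}", float(rng.gumbel(null_loc, 1.0)), True)
        )
    return peptides, false_ids


# ---------------------------------------------------------------------------
# synthetic ontology + annotations (for the enrichment stage)

_SYNTH_TERMS = (
    ("SYN:0000001", "cellular process", "biological_process", None),
    ("SYN:0000002", "organelle metabolic process", "biological_process", "SYN:0000001"),
    ("SYN:0000003", "peroxisomal metabolic process", "biological_process", "SYN:0000002"),
    ("SYN:0000004", "fatty acid beta-oxidation", "biological_process", "SYN:0000003"),
    ("SYN:0000005", "cytosolic process", "biological_process", "SYN:0000001"),
)


def write_synthetic_ontology(path: str | Path) -> None:
    """A small synthetic GO-like ontology (OBO 1.2) for self-contained runs."""
    lines = ["format-version: 1.2", "ontology: syn", ""]
    for term_id, name, namespace, parent in _SYNTH_TERMS:
        lines += [
            "[Term]",
            f"id: {term_id}",
            f"name: {name}",
            f"namespace: {namespace}",
        ]
        if parent:
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_synthetic_annotations(
    truth: SimTruth, path: str | Path, rng: np.random.Generator | None = None
) -> None:
    """Term/gene annotations over the reference namespace.

    Peroxisomal reference genes annotate to the synthetic peroxisomal term
    (matrix PTS proteins additionally to the beta-oxidation leaf);
    background genes annotate to the cytosolic branch.
    """
    rows: list[tuple[str, str]] = []
    for acc, category in truth.categories.items():
        gene = truth.reference_ids[acc]
        if category == "background":
            rows.append(("SYN:0000005", gene))
        else:
            rows.append(("SYN:0000003", gene))
            if category in (CATEGORY_MATRIX_PTS1, CATEGORY_MATRIX_PTS2):
                rows.append(("SYN:0000004", gene))
    with open(path, "w") as fh:
        fh.write("term_id\tgene_id\n")
        for term, gene in rows:
            fh.write(f"{term}\t{gene}\n")


# ---------------------------------------------------------------------------
# one-call dataset writer

def simulate_to_dir(
    config: SimConfig, outdir: str | Path, motifs: MotifTable | None = None
) -> SimTruth:
    """Generate a complete dataset under ``outdir``.

    Writes proteome.fa, psms.tsv, design.yaml, orthologs.tsv, perox_ref.tsv,
    truth.tsv, ontology.obo and annotations.tsv. Identical config (and seed)
    produces byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    design = default_design(config.n_replicates)
    proteome, truth, orthomap, reference = generate_proteome(config, motifs, rng)
    psms = generate_psms(proteome, truth, config, design, rng)

    pio.write_fasta(proteome, outdir / "proteome.fa")
    pio.write_psm_table(psms, design, outdir / "psms.tsv")
    pio.write_design(design, outdir / "design.yaml")
    pio.write_ortholog_map(orthomap, outdir / "orthologs.tsv")
    pio.write_reference_list(reference, outdir / "perox_ref.tsv")
    write_synthetic_ontology(outdir / "ontology.obo")
    write_synthetic_annotations(truth, outdir / "annotations.tsv")

    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("accession\tcategory\tplanted_motif\ttrue_log2fc\treference_id\n")
        for acc in sorted(truth.categories):
            fh.write(
                f"{acc}\t{truth.categories[acc]}\t{truth.motifs[acc]}\t"
                f"{truth.log2fc[acc]!r}\t{truth.reference_ids[acc]}\n"
            )
    return truth
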