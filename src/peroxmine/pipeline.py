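"""End-to-end orchestration: FDR filter -> quantify -> mine -> enrich.

Also hosts the packaged-table runner (:func:`run_fixture`), which rebuilds
the mined peroxisomal proteome of the pepper-fruit study from the shipped
57-row table (name, accession, PTS notation, compartment, log2FC,
regulation) by notation parsing and compartment assignment alone — no
spectra required.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from . import fdr as pfdr
from . import io as pio
from . import quant as pquant
from .enrichment import (
    enrich,
    load_ontology,
    read_term_gene_tsv,
    reduce_redundancy,
    write_enrichment_table,
)
from .mining import mine_peroxisomal, summarize_mining
from .motifs import default_motif_table, load_motif_table, parse_pts_notation
from .types import (
    CATEGORY_MATRIX_NO_PTS,
    CATEGORY_MATRIX_PTS1,
    CATEGORY_MATRIX_PTS2,
    CATEGORY_MEMBRANE,
    MinedProtein,
    MiningSummary,
)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (caught before any stage runs)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths and thresholds for a full pipeline run."""

    psms: str
    design: str
    proteome: str
    orthologs: str
    reference: str
    outdir: str
    motifs: str | None = None
    ontology: str | None = None
    annotations: str | None = None
    alpha_fdr: float = 0.01
    alpha_diff: float = 0.05
    min_peptides: int = 1
    jaccard: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha_fdr", "alpha_diff"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {value}")
        if self.min_peptides < 1:
            raise ConfigError("min_peptides must be >= 1")
        for name in ("psms", "design", "proteome", "orthologs", "reference"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")
        for name in ("motifs", "ontology", "annotations"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")
        if (self.ontology is None) != (self.annotations is None):
            raise ConfigError("ontology and annotations must be given together")


def load_pipeline_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a pipeline config from YAML; keyword overrides win."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    doc.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return PipelineConfig(**doc)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def run_pipeline(config: PipelineConfig) -> MiningSummary:
    """Execute all stages, writing every stage's output under ``outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partial_marker = outdir / ".partial"
    partial_marker.write_text("pipeline in progress\n")
    run_log: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha_fdr": config.alpha_fdr,
        "alpha_diff": config.alpha_diff,
        "min_peptides": config.min_peptides,
        "counts": {},
    }
    counts = run_log["counts"]

    stage = "filter-fdr"
    try:
        design = pio.read_design(config.design)
        psms = pio.read_psm_table(config.psms, design)
        counts["psms_in"] = len(psms)
        peptides = pfdr.collapse_to_peptides(psms)
        pfdr.estimate_qvalues(peptides)
        accepted = pfdr.filter_fdr(peptides, alpha=config.alpha_fdr)
        kept_psms = pfdr.filter_psms(psms, accepted)
        counts["peptides"] = len(peptides)
        counts["peptides_accepted"] = len(accepted)
        counts["psms_accepted"] = len(kept_psms)
        pd.DataFrame(
            [(p.peptide, p.score, p.q) for p in accepted],
            columns=["peptide", "score", "q"],
        ).to_csv(outdir / "peptides.tsv", sep="\t", index=False)
        log.info(
            "FDR filter: %d/%d peptides accepted at alpha=%.3g",
            len(accepted), len(peptides), config.alpha_fdr,
        )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    stage = "quantify"
    try:
        quants = pquant.aggregate_to_proteins(
            kept_psms, min_peptides=config.min_peptides
        )
        counts["proteins_quantified"] = len(quants)
        pquant.normalize_channels(quants)
        pquant.fit_differential(quants, design)
        pquant.classify_regulation(quants, alpha=config.alpha_diff)
        rows = []
        for q in quants:
            rows.append(
                dict(
                    accession=q.accession,
                    n_peptides=q.n_peptides,
                    **{ch: q.intensities[ch] for ch in design.channels},
                    log2FC=q.log2fc,
                    p=q.p,
                    q=q.q,
                    regulation=q.regulation,
                )
            )
        pd.DataFrame(rows).to_csv(outdir / "protein_quant.tsv", sep="\t", index=False)
        log.info("quantified %d proteins", len(quants))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "mine"
    try:
        proteome = pio.read_fasta(config.proteome)
        orthomap = pio.read_ortholog_map(config.orthologs)
        reference = pio.read_reference_list(config.reference)
        motifs = (
            load_motif_table(config.motifs)
            if config.motifs
            else default_motif_table()
        )
        mined = mine_peroxisomal(quants, proteome, orthomap, reference, motifs)
        summary_counts = pio.write_mined_report(
            mined, outdir / "mined.tsv", outdir / "summary.json"
        )
        counts["proteins_mined"] = len(mined)
        counts["mined_by_category"] = {
            k: summary_counts[k] for k in ("pts1", "pts2", "no_pts", "membrane")
        }
        log.info("mined %d peroxisomal proteins: %s", len(mined), summary_counts)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "enrich"
    try:
        if config.ontology is not None:
            graph = load_ontology(config.ontology)
            annotations = read_term_gene_tsv(config.annotations)
            background = {orthomap[q.accession] for q in quants if q.accession in orthomap}
            foreground = {m.reference_id for m in mined}
            results = enrich(foreground, background, annotations, graph)
            reduce_redundancy(
                results, graph, alpha=config.alpha_diff,
                jaccard_threshold=config.jaccard,
            )
            write_enrichment_table(results, outdir / "enrichment.tsv")
            counts["terms_tested"] = len(results)
            counts["terms_kept"] = sum(r.kept_after_reduction for r in results)
            log.info("enrichment: %d terms tested", len(results))
        else:
            log.info("no ontology/annotations configured; enrichment skipped")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
        fh.write("\n")
    partial_marker.unlink()
    return summarize_mining(mined)


# ---------------------------------------------------------------------------
# packaged-table fixture

_CATEGORY_BY_PTS = {
    "PTS1": CATEGORY_MATRIX_PTS1,
    "PTS2": CATEGORY_MATRIX_PTS2,
    "none": CATEGORY_MATRIX_NO_PTS,
}


def load_fixture_table() -> pd.DataFrame:
    """The packaged 57-row pepper peroxisomal protein table."""
    ref = resources.files("peroxmine.data").joinpath("pepper_perox_tables.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )


def run_fixture() -> tuple[list[MinedProtein], MiningSummary]:
    """Rebuild the mined protein list from the packaged table.

    Applies PTS-notation parsing, compartment assignment and regulation
    parsing to each row, then summarizes.
    """
    table = load_fixture_table()
    motifs = default_motif_table()
    mined: list[MinedProtein] = []
    for _, row in table.iterrows():
        pts = parse_pts_notation(row["pts_notation"], motifs)
        if row["compartment"] == "membrane":
            category = CATEGORY_MEMBRANE
            # membrane category is compartment-driven; PTS column is empty
        else:
            category = _CATEGORY_BY_PTS[pts.pts_type]
        log2fc = None if row["log2FC"] in ("", "NA") else float(row["log2FC"])
        mined.append(
            MinedProtein(
                accession=row["accession"],
                protein_name=row["protein_name"],
                reference_id="",
                category=category,
                pts=pts,
                log2fc=log2fc,
                regulation=row["regulation"],
            )
        )
    return mined, summarize_mining(mined)
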