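"""The synthetic-experiment generator: determinism, planted truth, and the
co-isolation compression model."""

import math

import numpy as np
import pytest

from peroxmine import quant as pq
from peroxmine.fdr import collapse_to_peptides, estimate_qvalues, filter_fdr
from peroxmine.motifs import scan_pts1, scan_pts2
from peroxmine.simulate import (
    SimConfig,
    _apportion,
    generate_proteome,
    generate_psms,
    simulate_scored_peptides,
    simulate_to_dir,
)
from peroxmine.types import default_design


def compressed_ratio(r, c):
    """Closed-form observed ratio when the background equals the mean of
    the two channel signals: ((1-c)R + c m) / ((1-c) + c m), m = (R+1)/2."""
    m = (r + 1) / 2
    return ((1 - c) * r + c * m) / ((1 - c) + c * m)


class TestConfig:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(category_mix=(0.5, 0.5, 0.5, 0.0))

    def test_contamination_range(self):
        with pytest.raises(ValueError):
            SimConfig(contamination=1.0)

    def test_no_perox_possible_is_error(self):
        with pytest.raises(ValueError, match="frac_perox"):
            generate_proteome(SimConfig(n_proteins=10, frac_perox=0.0))

    def test_apportionment_is_exact(self):
        assert sum(_apportion(100, (0.63, 0.14, 0.09, 0.14))) == 100
        assert _apportion(10, (0.5, 0.5, 0.0, 0.0)) == [5, 5, 0, 0]


class TestProteome:
    def test_all_pts1_config(self, motif_table):
        cfg = SimConfig(n_proteins=10, frac_perox=0.5, category_mix=(1, 0, 0, 0), seed=3)
        records, truth, orthomap, reference = generate_proteome(cfg)
        perox = [r for r in records if truth.categories[r.accession] == "matrix_pts1"]
        assert len(perox) == 5
        for rec in perox:
            assert rec.sequence[-3:] in motif_table.pts1
        assert len(reference) == 5
        assert set(orthomap) == {r.accession for r in records}

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        cfg = SimConfig(n_proteins=30, seed=9)
        for sub in ("a", "b"):
            simulate_to_dir(cfg, tmp_path / sub)
        assert (tmp_path / "a/proteome.fa").read_bytes() == (
            tmp_path / "b/proteome.fa"
        ).read_bytes()
        assert (tmp_path / "a/psms.tsv").read_bytes() == (
            tmp_path / "b/psms.tsv"
        ).read_bytes()

    def test_planted_labels_fully_recoverable(self, motif_table, small_sim):
        """Scanning generated sequences reproduces every planted category."""
        truth = small_sim["truth"]
        for rec in small_sim["proteome"]:
            category = truth.categories[rec.accession]
            pts1 = scan_pts1(rec.sequence, motif_table)
            pts2 = scan_pts2(rec.sequence, motif_table)
            if category == "matrix_pts1":
                assert pts1.pts_type == "PTS1"
            elif category == "matrix_pts2":
                assert pts1.pts_type == "none"
                assert pts2.pts_type == "PTS2"
            elif category in ("matrix_no_pts", "membrane", "background"):
                if category == "matrix_no_pts":
                    assert pts1.pts_type == "none"
                    assert pts2.pts_type == "none"

    def test_stratified_log2fc_counts_exact(self):
        cfg = SimConfig(
            n_proteins=200,
            log2fc_point_masses=((0.0, 0.8), (1.0, 0.2)),
            seed=5,
        )
        _, truth, _, _ = generate_proteome(cfg)
        values = list(truth.log2fc.values())
        assert values.count(1.0) == 40
        assert values.count(0.0) == 160


class TestPSMs:
    def test_noiseless_limit_recovers_true_log2fc(self, design):
        cfg = SimConfig(
            n_proteins=20, frac_perox=0.1, noise_sd=1e-8, contamination=0.0,
            base_log2_sd=0.0, log2fc_point_masses=((1.5, 1.0),),
            decoy_ratio=0.0, seed=21,
        )
        rng = np.random.default_rng(cfg.seed)
        proteome, truth, _, _ = generate_proteome(cfg, rng=rng)
        psms = generate_psms(proteome, truth, cfg, design, rng)
        quants = pq.aggregate_to_proteins(psms)
        pq.fit_differential(quants, design)
        for q in quants:
            assert q.log2fc == pytest.approx(1.5, abs=1e-6)

    def test_closed_form_compression(self, design):
        """c=0.5, true ratio 4: observed ratio collapses to 13/7."""
        cfg = SimConfig(
            n_proteins=40, frac_perox=0.1, noise_sd=1e-8, contamination=0.5,
            base_log2_sd=0.0, log2fc_point_masses=((2.0, 1.0),),
            decoy_ratio=0.0, seed=22,
        )
        rng = np.random.default_rng(cfg.seed)
        proteome, truth, _, _ = generate_proteome(cfg, rng=rng)
        psms = generate_psms(proteome, truth, cfg, design, rng)
        quants = pq.aggregate_to_proteins(psms)
        pq.fit_differential(quants, design)
        observed = np.mean([2.0 ** q.log2fc for q in quants])
        assert observed == pytest.approx(13 / 7, abs=1e-6)
        assert compressed_ratio(4.0, 0.5) == pytest.approx(13 / 7)

    def test_compression_monotone_in_contamination(self, design):
        means = []
        for c in (0.0, 0.3, 0.6):
            cfg = SimConfig(
                n_proteins=200, frac_perox=0.1, noise_sd=0.1, contamination=c,
                log2fc_point_masses=((1.0, 1.0),), decoy_ratio=0.0, seed=23,
            )
            rng = np.random.default_rng(cfg.seed)
            proteome, truth, _, _ = generate_proteome(cfg, rng=rng)
            psms = generate_psms(proteome, truth, cfg, design, rng)
            quants = pq.aggregate_to_proteins(psms)
            pq.fit_differential(quants, design)
            means.append(np.mean([abs(q.log2fc) for q in quants]))
        assert means[0] > means[1] > means[2]

    def test_decoy_accessions_disjoint_from_targets(self, small_sim):
        targets = {
            acc for p in small_sim["psms"] if not p.is_decoy
            for acc in p.protein_accessions
        }
        decoys = {
            acc for p in small_sim["psms"] if p.is_decoy
            for acc in p.protein_accessions
        }
        assert not targets & decoys

    def test_truth_covers_every_psm(self, small_sim):
        assert set(small_sim["truth"].psm_origin) == {
            p.spectrum_id for p in small_sim["psms"]
        }

    def test_shared_peptide_injection(self, design):
        cfg = SimConfig(n_proteins=30, shared_peptide_frac=0.5, seed=31)
        rng = np.random.default_rng(cfg.seed)
        proteome, truth, _, _ = generate_proteome(cfg, rng=rng)
        psms = generate_psms(proteome, truth, cfg, design, rng)
        assert any(len(p.protein_accessions) == 2 for p in psms)


class TestScoredPeptides:
    def test_labels_and_sizes(self):
        peps, false_ids = simulate_scored_peptides(70, 30, 100, rng=np.random.default_rng(1))
        assert sum(p.is_decoy for p in peps) == 100
        assert len(false_ids) == 30
        assert len(peps) == 200

    def test_fdr_control_on_null_mixture(self):
        """Realized false-accept proportion stays near alpha (seeded)."""
        props = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            peps, false_ids = simulate_scored_peptides(700, 300, 1000, rng=rng)
            estimate_qvalues(peps)
            accepted = filter_fdr(peps, alpha=0.05)
            assert accepted
            props.append(np.mean([p.peptide in false_ids for p in accepted]))
        assert np.mean(props) <= 1.5 * 0.05
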