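"""Aggregation, normalization and the moderated differential fit."""

import numpy as np
import pytest
from scipy import stats

from peroxmine.quant import (
    aggregate_to_proteins,
    classify_regulation,
    fit_differential,
    normalize_channels,
)
from peroxmine.types import ProteinQuant, PSMRecord, default_design

CHANNELS = ("113", "114", "115", "116", "117", "118", "119", "121")


def psm(peptide, proteins, channel1=100.0, score=10.0, decoy=False):
    intensities = {ch: 10.0 for ch in CHANNELS}
    intensities["113"] = channel1
    return PSMRecord(
        spectrum_id=f"s-{peptide}",
        peptide=peptide,
        protein_accessions=tuple(proteins),
        score=score,
        is_decoy=decoy,
        intensities=intensities,
    )


def quant(accession, values):
    return ProteinQuant(
        accession=accession,
        intensities=dict(zip(CHANNELS, values)),
        n_peptides=2,
    )


class TestAggregate:
    def test_sum_rule(self):
        psms = [psm("PEPA", ["P1"], 100.0), psm("PEPB", ["P1"], 50.0)]
        (q,) = aggregate_to_proteins(psms)
        assert q.intensities["113"] == 150.0
        assert q.n_peptides == 2

    def test_shared_peptide_contributes_to_neither(self):
        psms = [psm("PEPA", ["P1", "P2"])]
        assert aggregate_to_proteins(psms) == []

    def test_min_peptides_threshold(self):
        psms = [psm("PEPA", ["P1"]), psm("PEPB", ["P2"]), psm("PEPC", ["P2"])]
        out = aggregate_to_proteins(psms, min_peptides=2)
        assert [q.accession for q in out] == ["P2"]

    def test_decoys_ignored(self):
        assert aggregate_to_proteins([psm("PEPA", ["D1"], decoy=True)]) == []


class TestNormalize:
    def test_idempotent_when_already_centered(self):
        rng = np.random.default_rng(0)
        vals = 2.0 ** rng.normal(10, 1, size=(31, 8))
        # force identical per-channel medians by construction (odd row
        # count keeps the median an exact matrix element)
        vals = vals / np.median(vals, axis=0, keepdims=True)
        quants = [quant(f"P{i}", row) for i, row in enumerate(vals)]
        before = np.array([[q.intensities[ch] for ch in CHANNELS] for q in quants])
        normalize_channels(quants)
        after = np.array([[q.intensities[ch] for ch in CHANNELS] for q in quants])
        assert np.allclose(before, after, rtol=1e-12)

    def test_global_channel_scaling_corrected(self):
        rng = np.random.default_rng(1)
        vals = 2.0 ** rng.normal(10, 1, size=(25, 8))
        scaled = vals.copy()
        scaled[:, 3] *= 2.0
        qa = [quant(f"P{i}", row) for i, row in enumerate(vals)]
        qb = [quant(f"P{i}", row) for i, row in enumerate(scaled)]
        normalize_channels(qa)
        normalize_channels(qb)
        a = np.array([[q.intensities[ch] for ch in CHANNELS] for q in qa])
        b = np.array([[q.intensities[ch] for ch in CHANNELS] for q in qb])
        assert np.allclose(a, b, rtol=1e-10)

    def test_medians_equal_after_normalization(self):
        rng = np.random.default_rng(2)
        vals = 2.0 ** rng.normal(8, 2, size=(40, 8))
        quants = [quant(f"P{i}", row) for i, row in enumerate(vals)]
        normalize_channels(quants)
        mat = np.log2([[q.intensities[ch] for ch in CHANNELS] for q in quants])
        medians = np.median(mat, axis=0)
        assert np.allclose(medians, medians[0], atol=1e-9)

    def test_all_zero_channel_is_error(self):
        vals = np.ones((5, 8))
        vals[:, 0] = 0.0
        quants = [quant(f"P{i}", row) for i, row in enumerate(vals)]
        with pytest.raises(ValueError, match="all-zero"):
            normalize_channels(quants)

    def test_zeros_replaced_by_half_minimum(self):
        vals = np.full((3, 8), 4.0)
        vals[0, 0] = 0.0
        quants = [quant(f"P{i}", row) for i, row in enumerate(vals)]
        normalize_channels(quants)
        assert quants[0].intensities["113"] == pytest.approx(2.0)


class TestDifferential:
    def test_doubling_gives_log2fc_one(self, design):
        values = [10.0] * 4 + [20.0] * 4
        quants = [quant("P1", values), quant("P2", [7, 8, 9, 10, 14, 16, 18, 20])]
        fit_differential(quants, design)
        assert quants[0].log2fc == pytest.approx(1.0)

    def test_identical_conditions_degenerate(self, design):
        quants = [quant("P1", [10.0] * 8)]
        fit_differential(quants, design)
        assert quants[0].log2fc == 0.0
        assert quants[0].p == 1.0
        assert quants[0].degenerate

    def test_label_swap_negates_log2fc_keeps_q(self, design):
        rng = np.random.default_rng(3)
        vals = 2.0 ** rng.normal(10, 1, size=(50, 8))
        qa = [quant(f"P{i}", row) for i, row in enumerate(vals)]
        qb = [quant(f"P{i}", row) for i, row in enumerate(vals)]
        fit_differential(qa, design)
        fit_differential(qb, design.swapped())
        assert np.allclose([x.log2fc for x in qa], [-x.log2fc for x in qb])
        assert np.allclose([x.q for x in qa], [x.q for x in qb])

    def test_unmoderated_matches_scipy_ttest(self, design):
        rng = np.random.default_rng(4)
        vals = 2.0 ** rng.normal(10, 0.5, size=(20, 8))
        quants = [quant(f"P{i}", row) for i, row in enumerate(vals)]
        fit_differential(quants, design, moderate=False)
        logs = np.log2(vals)
        for i, q in enumerate(quants):
            t, p = stats.ttest_ind(logs[i, 4:], logs[i, :4], equal_var=True)
            assert q.p == pytest.approx(p, rel=1e-9)

    def test_bh_qvalues_bounded_and_monotone_in_p(self, design):
        rng = np.random.default_rng(5)
        vals = 2.0 ** rng.normal(10, 1, size=(40, 8))
        quants = [quant(f"P{i}", row) for i, row in enumerate(vals)]
        fit_differential(quants, design)
        pairs = sorted((q.p, q.q) for q in quants)
        assert all(0 <= q <= 1 for _, q in pairs)
        for (_, q1), (_, q2) in zip(pairs, pairs[1:]):
            assert q1 <= q2 + 1e-12

    def test_too_few_replicates_is_error(self):
        from peroxmine.types import DesignSpec

        with pytest.raises(ValueError):
            DesignSpec(
                channel_to_sample={"113": "a1", "114": "a2", "115": "b1"},
                sample_to_condition={"a1": "A", "a2": "A", "b1": "B"},
            )


class TestRegulation:
    def _fitted(self, log2fc, q):
        pq = ProteinQuant(
            accession="P1", intensities={}, n_peptides=1,
            log2fc=log2fc, p=q, q=q,
        )
        return pq

    @pytest.mark.parametrize(
        "log2fc,q,expected",
        [
            (1.396, 0.001, "UP"),
            (-0.017, 0.001, "DOWN"),  # magnitude irrelevant: no FC cutoff
            (3.0, 0.9, "NONE"),
            (-2.0, 0.9, "NONE"),
        ],
    )
    def test_calls(self, log2fc, q, expected):
        pq = self._fitted(log2fc, q)
        classify_regulation([pq], alpha=0.05)
        assert pq.regulation == expected

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            classify_regulation([], alpha=0.0)
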