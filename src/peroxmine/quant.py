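"""Reporter-intensity aggregation, normalization and differential abundance.

The contrast is always condition B (ripe red fruit) minus condition A
(immature green fruit) on the log2 scale::

    log2FC = mean(log2 B channels) - mean(log2 A channels)

Significance comes from a per-protein two-group linear model whose residual
variance is moderated toward the across-protein mean variance (an
empirical-Bayes-style shrinkage with a configurable equivalent prior df,
default 4), followed by Benjamini-Hochberg q-values across proteins. No
fold-change magnitude cutoff is applied when calling regulation: isobaric
reporter ratios are compressed toward 1 by co-isolation interference, which
makes fixed fold-change thresholds meaningless while leaving well-supported
small ratios statistically sound.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    DesignSpec,
    ProteinQuant,
    PSMRecord,
    REGULATION_DOWN,
    REGULATION_NONE,
    REGULATION_UP,
)


def aggregate_to_proteins(
    psms: Sequence[PSMRecord], min_peptides: int = 1
) -> list[ProteinQuant]:
    """Sum reporter intensities of unique-protein PSMs per protein.

    PSMs whose peptide maps to more than one protein accession are discarded
    (unique-peptide rule); proteins supported by fewer than ``min_peptides``
    distinct peptides are dropped. Decoy PSMs are ignored.
    """
    sums: dict[str, dict[str, float]] = {}
    peptides: dict[str, set[str]] = {}
    for psm in psms:
        if psm.is_decoy or len(psm.protein_accessions) != 1:
            continue
        acc = psm.protein_accessions[0]
        acc_sums = sums.setdefault(acc, {})
        for ch, val in psm.intensities.items():
            acc_sums[ch] = acc_sums.get(ch, 0.0) + val
        peptides.setdefault(acc, set()).add(psm.peptide)
    out = []
    for acc in sums:
        n_pep = len(peptides[acc])
        if n_pep < min_peptides:
            continue
        out.append(
            ProteinQuant(accession=acc, intensities=dict(sums[acc]), n_peptides=n_pep)
        )
    return out


def normalize_channels(quants: Sequence[ProteinQuant]) -> list[ProteinQuant]:
    """Median-center channels in log2 space (in place; returns the list).

    Each channel's log2 intensities are shifted so all channel medians equal
    the grand median of the matrix. Zeros are replaced by half the smallest
    nonzero intensity of the whole matrix before logging.
    """
    if not quants:
        raise ValueError("no proteins to normalize")
    channels = list(quants[0].intensities)
    mat = np.array([[q.intensities[ch] for ch in channels] for q in quants])
    if np.any((mat == 0).all(axis=0)):
        dead = [ch for j, ch in enumerate(channels) if (mat[:, j] == 0).all()]
        raise ValueError(f"channel(s) with all-zero intensities: {dead}")
    nonzero = mat[mat > 0]
    floor = nonzero.min() / 2.0
    mat = np.where(mat == 0, floor, mat)
    logmat = np.log2(mat)
    channel_medians = np.median(logmat, axis=0)
    # target = median of the channel medians, so an already-centered matrix
    # is left untouched
    grand = np.median(channel_medians)
    shifts = grand - channel_medians
    logmat = logmat + shifts
    mat = 2.0 ** logmat
    for i, q in enumerate(quants):
        q.intensities = {ch: float(mat[i, j]) for j, ch in enumerate(channels)}
    return list(quants)


def fit_differential(
    quants: Sequence[ProteinQuant],
    design: DesignSpec,
    prior_df: float = 4.0,
    moderate: bool = True,
) -> list[ProteinQuant]:
    """Per-protein B-vs-A contrast with moderated t-statistics (in place).

    The two-group linear model (intercept + condition indicator) reduces to
    the difference of condition means on log2 intensities; its residual
    variance ``s2`` (pooled, ``n_A + n_B - 2`` df) is shrunk toward the
    across-protein mean variance ``s0^2``::

        s2_mod = (prior_df * s0^2 + df * s2) / (prior_df + df)

    and the contrast is tested two-sided against t(df + prior_df). With
    ``moderate=False`` a plain per-protein t-test is used. Zero contrast
    with zero variance is degenerate and gets p = 1 (flagged).
    """
    if not quants:
        return []
    ch_a = design.channels_for("A")
    ch_b = design.channels_for("B")
    if len(ch_a) < 2 or len(ch_b) < 2:
        raise ValueError("both conditions need >= 2 replicate channels")
    n_a, n_b = len(ch_a), len(ch_b)
    df_resid = n_a + n_b - 2

    log_a = np.empty((len(quants), n_a))
    log_b = np.empty((len(quants), n_b))
    for i, q in enumerate(quants):
        vals_a = [q.intensities[ch] for ch in ch_a]
        vals_b = [q.intensities[ch] for ch in ch_b]
        if min(vals_a + vals_b) <= 0:
            raise ValueError(
                f"{q.accession}: nonpositive intensity; normalize first"
            )
        log_a[i] = np.log2(vals_a)
        log_b[i] = np.log2(vals_b)

    fc = log_b.mean(axis=1) - log_a.mean(axis=1)
    sse = ((log_a - log_a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (log_b - log_b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = sse / df_resid

    if moderate:
        s0_sq = float(s2.mean())
        s2_mod = (prior_df * s0_sq + df_resid * s2) / (prior_df + df_resid)
        df_total = df_resid + prior_df
    else:
        s2_mod = s2
        df_total = df_resid

    se = np.sqrt(s2_mod * (1.0 / n_a + 1.0 / n_b))
    pvals = np.empty(len(quants))
    degenerate = np.zeros(len(quants), dtype=bool)
    for i in range(len(quants)):
        if se[i] == 0.0:
            # all replicates identical: no evidence of variability
            degenerate[i] = True
            pvals[i] = 1.0 if fc[i] == 0.0 else 0.0
        else:
            t = fc[i] / se[i]
            pvals[i] = 2.0 * stats.t.sf(abs(t), df_total)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    for i, q in enumerate(quants):
        q.log2fc = float(fc[i])
        q.p = float(pvals[i])
        q.q = float(qvals[i])
        q.degenerate = bool(degenerate[i])
    return list(quants)


def classify_regulation(
    quants: Sequence[ProteinQuant], alpha: float = 0.05
) -> list[ProteinQuant]:
    """UP/DOWN/NONE calls at q <= alpha; no fold-change magnitude threshold."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    for q in quants:
        if q.q is None or q.log2fc is None:
            raise ValueError(f"{q.accession}: differential fit not run")
        if q.q <= alpha and q.log2fc > 0:
            q.regulation = REGULATION_UP
        elif q.q <= alpha and q.log2fc < 0:
            q.regulation = REGULATION_DOWN
        else:
            q.regulation = REGULATION_NONE
    return list(quants)
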