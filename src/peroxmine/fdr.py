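"""Target-decoy FDR estimation and the peptide-level FDR filter.

Identifications searched against a composite target/decoy database are
collapsed to distinct peptides (best score wins), assigned q-values by the
standard target-decoy estimator, and filtered at a peptide-level FDR
threshold (default 0.01) before any quantification.

For a score threshold ``t``::

    FDR(t) = #{decoys with score >= t} / max(1, #{targets with score >= t})

and a peptide's q-value is the minimum ``FDR(t)`` over all thresholds that
would accept it (``t <= score``), capped at 1. Tied scores share one
threshold, so q-values do not depend on input order.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .types import PSMRecord, ScoredPeptide


def collapse_to_peptides(psms: Sequence[PSMRecord]) -> list[ScoredPeptide]:
    """One entry per distinct peptide sequence, keeping the best (max) score.

    A peptide observed in both target and decoy context is an error: the
    composite-database convention guarantees decoy peptides never coincide
    with target peptides.
    """
    if not psms:
        raise ValueError("empty PSM list")
    best: dict[str, ScoredPeptide] = {}
    for psm in psms:
        prev = best.get(psm.peptide)
        if prev is None:
            best[psm.peptide] = ScoredPeptide(
                peptide=psm.peptide, score=psm.score, is_decoy=psm.is_decoy
            )
        else:
            if prev.is_decoy != psm.is_decoy:
                raise ValueError(
                    f"peptide {psm.peptide!r} maps to both target and decoy proteins"
                )
            if psm.score > prev.score:
                prev.score = psm.score
    return list(best.values())


def estimate_qvalues(peptides: Sequence[ScoredPeptide]) -> list[ScoredPeptide]:
    """Fill in target-decoy q-values (in place) and return the list.

    Implemented as: sort unique scores descending, accumulate decoy/target
    counts, FDR at each threshold, then a cumulative minimum from the lowest
    threshold upward so q is monotonically non-increasing in score.
    """
    if not peptides:
        raise ValueError("empty peptide list")
    if not any(not p.is_decoy for p in peptides):
        raise ValueError("no target peptides")

    scores = np.array([p.score for p in peptides], dtype=float)
    decoy = np.array([p.is_decoy for p in peptides], dtype=bool)

    # unique thresholds, descending; ties share one threshold
    order = np.argsort(-scores, kind="stable")
    thresholds, inverse = np.unique(-scores, return_inverse=True)
    # thresholds ascending in -score == descending in score
    n_thr = len(thresholds)
    decoy_counts = np.zeros(n_thr)
    target_counts = np.zeros(n_thr)
    np.add.at(decoy_counts, inverse, decoy)
    np.add.at(target_counts, inverse, ~decoy)
    cum_decoys = np.cumsum(decoy_counts)
    cum_targets = np.cumsum(target_counts)
    fdr = np.minimum(1.0, cum_decoys / np.maximum(1.0, cum_targets))
    # q(threshold i) = min FDR over thresholds at or below i's score
    q_at_thr = np.minimum.accumulate(fdr[::-1])[::-1]
    for i, pep in enumerate(peptides):
        pep.q = float(q_at_thr[inverse[i]])
    del order
    return list(peptides)


def filter_fdr(
    peptides: Sequence[ScoredPeptide], alpha: float = 0.01
) -> list[ScoredPeptide]:
    """Accept target peptides with q <= alpha; decoys are never returned."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    for p in peptides:
        if p.q is None:
            raise ValueError(f"q-value not computed for peptide {p.peptide!r}")
    return [p for p in peptides if not p.is_decoy and p.q <= alpha]


def filter_psms(
    psms: Sequence[PSMRecord], accepted: Iterable[ScoredPeptide]
) -> list[PSMRecord]:
    """Keep only PSMs whose peptide survived the FDR filter."""
    keep = {p.peptide for p in accepted}
    return [psm for psm in psms if psm.peptide in keep]
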