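# Methods

This note documents the statistical procedures, the synthetic-data model,
the defaults that matter, and the places where the design was genuinely
open and a choice had to be made.

## Identification filtering

Search-engine output is consumed as a PSM table (spectrum, peptide,
protein accessions, score, decoy flag, 8 reporter intensities); native
engine formats, spectra and mass recalibration are out of scope. PSMs are
collapsed to distinct peptides keeping the best (maximum) score — the
simplest defensible rule; a peptide appearing in both target and decoy
context violates the composite-database construction and is an error.

Q-values follow the standard target-decoy estimator: with
FDR(t) = #{decoys ≥ t} / max(1, #{targets ≥ t}), the q-value of a peptide
with score s is min over t ≤ s of FDR(t), capped at 1. Tied scores share
one threshold, making the result independent of input order and q
monotonically non-increasing in score. The default peptide-level filter
is q ≤ 0.01. The original workflow computed PSM p-values from parametric
score-distribution models; target-decoy q-values are the field-standard
equivalent and need no distributional assumption. No protein-level FDR is
applied on top.

## Quantification and differential abundance

Only peptides mapping to exactly one protein accession contribute
(unique-peptide rule); per protein, each reporter channel is the sum of
its PSM intensities, and proteins with fewer than `min_peptides`
(default 1) distinct peptides are dropped. Zero intensities are replaced
by half the smallest nonzero intensity of the matrix before logging — the
conventional half-minimum floor for empty reporter cells.

Channels are median-centered in log2 space: every channel is shifted so
its median equals the median of the channel medians. This removes global
loading/labeling differences, is idempotent, and exactly undoes a uniform
channel scaling. It assumes regulation is roughly balanced across
proteins; when a simulation plants strongly one-sided regulation
(e.g. 10% of proteins up, none down), centering itself deflates the
estimated log2FC by about 0.1 — we therefore benchmark the differential
estimator on the generator's loading-balanced output directly, while the
pipeline keeps centering on by default because real experiments do have
loading differences.

Per protein the two-group model on log2 intensities gives
log2FC = mean(log2 B) − mean(log2 A) (A = green/immature, B = red/ripe).
The pooled residual variance s² (df = n_A + n_B − 2) is shrunk toward the
across-protein mean variance s₀²:

    s̃² = (d₀·s₀² + df·s²) / (d₀ + df),   d₀ = 4 (configurable)

and the contrast is tested two-sided against t(df + d₀). This is a
deliberately simple shrinkage target — the across-protein mean rather
than a fitted inverse-gamma prior — chosen for transparency; a plain
per-protein t-test is available (`moderate=False`). Multiplicity is
handled by Benjamini–Hochberg across proteins.

Regulation calls: UP if q ≤ α and log2FC > 0, DOWN if q ≤ α and
log2FC < 0, else NONE, with α = 0.05 by default (the source study never
states its cutoff; this is the conventional one). **No fold-change
magnitude threshold is used**: co-isolation interference compresses
isobaric ratios toward 1 by an amount that varies with sample complexity
and acquisition settings, so a fixed cutoff would discard reproducible,
well-supported small ratios while keeping noisy large ones.

## PTS classification

PTS1 detection is accept-list driven: the shipped table
(`data/motifs.yaml`) combines the classical [SA][KR][LMI]-style family
with non-classical tripeptides observed on genuine peroxisomal matrix
proteins (ANL, ASL, TNL, SSV, SAK, SNM, PKL, PRL, HKL, QKL), each with a
confidence tier (canonical / verified / putative). A generic consensus
regex would miss the non-classical signals, which is exactly the
interesting part of a fruit peroxisome; the list is data, not code, and
which tripeptides count as canonical beyond the observed set is a
convention, not a fact.

PTS2 is the nonapeptide R[LIQV]-x₅-H[LF], scanned over frames starting in
the first 40 residues (cleavable N-terminal presequences fall inside this
window; the window is configurable). The first (most N-terminal) match
wins. The non-canonical pattern DVx5QM seen in annotation strings is
accepted by the notation parser but not by the sequence scanner — letting
D start a frame would flood false positives.

Precedence: a C-terminal PTS1 outranks a PTS2 match; sequence-scan
evidence outranks transferred annotation. Internal PTS1-like signals
(catalase QKL) are never discovered by scanning; they enter through
annotation strings ("QKL (internal)").

## Mining by ortholog transfer

A quantified query protein is peroxisomal iff its ortholog ID appears in
the reference list. Transfer is one-directional (query → reference);
reciprocal-best-hit hygiene is the ortholog map producer's job, since the
map is an input, not a computation. Membrane entries take the compartment
verdict outright (a PMP may well end in an accept-list tripeptide by
chance). A reference ID listed under both compartments is an error rather
than a silent pick. Mining is monotone: removing a reference entry can
only remove rows, never reclassify survivors.

The packaged 57-row pepper table is rebuilt by exactly this logic minus
the spectra: notation parsing + compartment + regulation column. Its
partition is 49 matrix (36 PTS1, 8 PTS2, 5 no-PTS) + 8 membrane, and its
regulation column tallies to 20 UP / 16 DOWN / 21 NONE — the package
reports what the rows yield and hard-codes no totals.

## GO enrichment and redundancy reduction

Annotations are propagated to ancestors (true-path rule) before counting.
Per term with at least one foreground hit, p = P(X ≥ k) under the
hypergeometric law with population N (background), n successes (term
genes in background) and K draws (foreground); BH within each namespace.

Redundancy reduction replaces semantic-similarity pruning with a
deterministic, dependency-light rule: among significant terms (q ≤ α), a
term is dropped when a significant ancestor or descendant with smaller p
annotates an almost identical foreground set (Jaccard ≥ 0.7 by default);
p ties resolve toward the deeper term, so a chain of equally-significant
nested terms keeps only its most specific member. A term with no
significant relatives is never dropped.

## The synthetic experiment

The generator emulates the statistical structure of an 8-plex two-stage
comparison, not its physics (no m/z peaks, isotope envelopes or retention
times):

* **Proteome** — random sequences of 150–600 uniform residues;
  peroxisomal proteins (default 25% of the proteome, apportioned
  36:8:5:8 over PTS1/PTS2/no-PTS/membrane by largest remainder, the
  partition of the mined pepper table) get their motif planted: a
  tripeptide sampled from the accept-list appended C-terminally, or a
  pattern-conforming nonapeptide written into the first 40 residues.
  Accidental motifs are scrubbed from proteins that must not carry them
  (C-terminal accept-list tripeptides, stray PTS2 frames), so planted
  category labels are exactly recoverable by the scanners. Every protein
  gets an AGI-style ortholog ID; only peroxisomal ones enter the
  reference list.
* **Reporters** — per peptide and channel,
  I_true = base·2^(±f/2 + ε), ε ~ N(0, noise_sd), with f the protein's
  true log2FC (sign by condition), base log-normal (log2 mean 20, sd 1.5).
  Defaults: noise_sd 0.25, 4+4 replicates, true log2FC a point-mass mix
  0.6·δ(0) + 0.2·δ(+1) + 0.2·δ(−1) — about half the proteome modulated,
  as in the emulated study; point masses are assigned to exact
  largest-remainder counts by default so planted totals are
  deterministic.
* **Co-isolation** — observed = (1−c)·I_true + c·B with B common to all 8
  channels of a spectrum: a co-isolated background peptide contributes
  equally to every reporter, which is the mechanism of ratio compression.
  B is the global mean true intensity times a log-normal jitter; for true
  ratio R and background at the channel mean this gives the closed-form
  observed ratio ((1−c)R + c·m)/((1−c) + c·m), m = (R+1)/2 — at c = 0.5,
  R = 4: 13/7 ≈ 1.857, i.e. |log2FC| shrinks from 2.0 to ≈ 0.893. The
  study reports no compression magnitude, so c has no empirical anchor
  and defaults to 0 except where compression is under study.
* **Scores** — decoys and false targets draw Gumbel(0, 1), true targets
  Gumbel(7, 1); decoy:target ratio 1. Only the separation matters. The
  separation is chosen so that a 1% peptide FDR filter retains essentially
  all true peptides: with a small shift (e.g. Gumbel(2,1)) the Gumbel
  tails give an asymptotic decoy/target ratio of e⁻² ≈ 0.135, FDR(t)
  never approaches 0.01, and the only "accepted" region is the handful of
  targets above the maximum decoy — a finite-sample artifact where the
  realized error is badly anti-conservative. A generator whose 1% filter
  accepts almost nothing emulates no usable experiment; modern engines
  with recalibrated scores separate far better. FDR-calibration runs use
  a 70/30 true/false target mixture (false targets share the decoy null),
  a conventional search mismatch rate.

What passing on simulated data does **not** show about real data:
peptide detectability biases, missing reporter cells, isotope-impurity
cross-talk, batch/run effects, shared-peptide protein inference (beyond a
synthetic injection flag), and ortholog-mapping errors are all absent
from the generator.

## Problem sizes and numerical choices

Benchmark runs use 500 proteins for differential recovery, 20 replicates
of 1,000 targets + 1,000 decoys for FDR calibration, 200 proteins per
contamination level for the compression curve, and 400 proteins (25%
peroxisomal) end-to-end — sizes at which the measured quantities are
stable to the third decimal across seeds while the whole suite runs in
seconds. Degenerate inputs are handled explicitly: zero residual variance
with zero contrast gives p = 1 (flagged); an all-zero channel is an
error; empty mined lists summarize to zeros. All randomness flows from a
single integer seed; identical configuration gives byte-identical output
files.

## Known limitations

* The moderation prior (mean-variance target, d₀ = 4) is cruder than a
  full empirical-Bayes fit; with very few proteins s₀² is itself noisy.
* Median centering biases estimates under strongly asymmetric regulation
  (measured ≈ −0.12 at 10% one-sided regulation; see above).
* The PTS1 accept-list is a curated convention; organisms with divergent
  receptor specificity need their own table.
* Redundancy reduction uses graph relatedness + Jaccard, not semantic
  similarity; it prunes more conservatively on sparse annotation sets.
* Whole-study figures that depend on the deposited raw data and on
  database releases (total identifications, ortholog coverage, GO
  namespace tallies) are outside what desk-scale simulation can or
  should reproduce.
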