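# peroxmine

Mining an organellar proteome out of whole-tissue isobaric-tag (iTRAQ
8-plex) shotgun proteomics — built around the peroxisome of ripening sweet
pepper (*Capsicum annuum*) fruit, but generic in its parts.

Plant peroxisomes cannot easily be purified from fruit tissue, so their
protein complement is best obtained indirectly: quantify the *whole* fruit
proteome across ripening stages (immature green vs ripe red, 4 biological
replicates each on one 8-plex), then pull out the peroxisomal subset by
ortholog transfer against the well-curated Arabidopsis peroxisomal
proteome, and classify each hit by its import route — a C-terminal PTS1
tripeptide (PEX5 cargo), an N-terminal PTS2 nonapeptide (PEX7 cargo), a
matrix protein without a recognizable signal, or a membrane protein
(PMP). `peroxmine` implements that entire analysis as a tested pipeline,
plus a synthetic-data generator that reproduces its statistical structure
(known fold changes, decoy PSMs, co-isolation ratio compression) so every
stage is verifiable against planted truth.

## What the pipeline computes

1. **Peptide-level FDR (target-decoy).** For a score threshold *t*,
   FDR(*t*) = #{decoys ≥ *t*} / max(1, #{targets ≥ *t*}); a peptide's
   q-value is the minimum FDR over all thresholds that would accept it.
   Peptides pass at q ≤ 0.01 by default.
2. **Protein quantification.** Unique peptides only; reporter intensities
   summed per protein; channels median-centered in log2 space.
3. **Differential abundance.** Per protein, the two-group linear model on
   log2 intensities gives log2FC = log2(B) − log2(A) (A = green,
   B = red). The residual variance s² is moderated toward the
   across-protein mean variance s₀²,
   s̃² = (d₀·s₀² + d·s²)/(d₀ + d) with prior df d₀ = 4, and the contrast
   is tested against t(d + d₀); Benjamini–Hochberg q-values across
   proteins. Regulation is UP/DOWN at q ≤ 0.05 with **no fold-change
   cutoff** — co-isolation interference compresses isobaric ratios toward
   1, so magnitude thresholds discard well-supported small ratios.
4. **Peroxisome mining.** A quantified protein is kept iff its ortholog
   (AGI locus code) is in the reference peroxisomal list. Membrane entries
   classify by compartment; matrix entries by scanning the query sequence
   (PTS1 accept-list, then the PTS2 pattern R[LIQV]x₅H[LF] within the
   first 40 residues), falling back to the reference's annotated PTS
   notation, else "matrix, no PTS".
5. **GO enrichment.** One-sided hypergeometric test after true-path
   propagation, BH within namespace, and a deterministic redundancy
   reduction: a significant term is dropped when a significant
   ancestor/descendant with smaller p covers nearly the same foreground
   genes (Jaccard ≥ 0.7).

The mined pepper table shipped with the package (57 proteins transcribed
from the study's result tables) partitions into 49 matrix proteins
(36 PTS1 + 8 PTS2 + 5 without PTS) and 8 membrane proteins.

## Worked example

Simulate a 200-protein experiment (25% peroxisomal, default category mix
36:8:5:8, 4+4 replicates, log2 noise sd 0.25) and run the full pipeline:

```bash
peroxmine simulate --n-proteins 200 --frac-perox 0.25 --seed 7 --outdir sim/
peroxmine run --psms sim/psms.tsv --design sim/design.yaml \
    --proteome sim/proteome.fa --orthologs sim/orthologs.tsv \
    --reference sim/perox_ref.tsv --ontology sim/ontology.obo \
    --annotations sim/annotations.tsv --outdir out/
```

prints

```
simulated 200 proteins (planted counts: {'total': 50, 'matrix': 43, 'membrane': 7, 'pts1': 32, 'pts2': 7, 'no_pts': 4}) -> sim/
INFO peroxmine.pipeline: FDR filter: 1217/2434 peptides accepted at alpha=0.01
INFO peroxmine.pipeline: quantified 200 proteins
INFO peroxmine.pipeline: mined 50 peroxisomal proteins: {'total': 50, 'matrix': 43, 'membrane': 7, 'pts1': 32, 'pts2': 7, 'no_pts': 4, 'up': 9, 'down': 10, 'none': 31}
INFO peroxmine.pipeline: enrichment: 4 terms tested
{"total": 50, "matrix": 43, "membrane": 7, "pts1": 32, "pts2": 7, "no_pts": 4, "up": 9, "down": 10, "none": 31}
```

All 2,434 target peptides arrive with an equal number of decoys; exactly
the targets survive the 1% FDR filter. The mined counts equal the planted
counts — every planted targeting signal is recovered and no background
protein leaks in. Roughly 40% of proteins carry a true ±1 log2FC by
default; 19 of the 20 regulated peroxisomal proteins are called at
q ≤ 0.05 here.

The published pepper table can be rebuilt without any simulation:

```bash
peroxmine run-fixture
# {"total": 57, "matrix": 49, "membrane": 8, "pts1": 36, "pts2": 8,
#  "no_pts": 5, "up": 20, "down": 16, "none": 21}
```

## Layout

```
src/peroxmine/
  types.py       domain types (PSMs, design, quant, mined entries)
  io.py          FASTA / TSV / YAML readers and writers
  fdr.py         target-decoy q-values and the peptide FDR filter
  quant.py       aggregation, normalization, moderated differential fit
  motifs.py      PTS1/PTS2 scanners and notation parsing
  mining.py      ortholog intersection and category assignment
  enrichment.py  GO enrichment + redundancy reduction
  simulate.py    synthetic experiment generator with planted truth
  pipeline.py    stage orchestration and the packaged-table runner
  cli.py         `peroxmine` command-line interface
  data/          motif accept-list config; the 57-row pepper table
```

See `docs/methods.md` for the statistical model, simulator assumptions,
parameter defaults and known limitations.
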