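# Methods

## Overview

`inophase` detects A-to-I RNA editing on individual nanopore direct-RNA
reads. The method's premise is that inosine leaves two footprints in
re-squiggled nanopore data: a shift of the z-normalized current mean at
the edited adenosine and its neighbours (offsets −3..+1), and
systematic base-calling errors concentrated at offsets −1..+1. The
pipeline turns the second footprint into per-read training labels
(no per-molecule ground truth exists in real data), trains a small
fully connected network on window-level signal features, and aggregates
per-read probabilities into site-level editing ratios and per-molecule
phasing patterns.

Assumptions: one alignment per read, forward strand only, 0-based
transcript coordinates, and event tables containing per-position
`norm_mean`, `norm_std` and dwell from a re-squiggling step that is
outside the package's scope.

## Site discovery

Sites come from short-read (Illumina-style) pileups of an
editing-competent treatment and an editing-free control. A transparent
frequency caller (alt support ≥ `min_alt_reads` = 5 and alt fraction of
depth ≥ `min_alt_fraction` = 0.05; the most-supported non-reference
base wins, ties broken G > T > C since A→G is the editing signature)
replaces a full variant-calling model: the statistical machinery inside
general-purpose callers is not what is under study here, and an
in-repository caller makes the filter rules exactly testable. The four
site rules then require: A→G in *every* treatment replicate, A→G in
*no* control replicate, absence from a user-supplied genomic-SNP set,
and depth ≥ `coverage_site` = 50 with editing ratio ≥ `ratio_site` =
0.1 in all treatment replicates. The editing ratio uses the A/G
dichotomy `nG/(nA+nG)` rather than full depth, matching the two-state
model of the edited base; the SNV caller's alt fraction uses full
depth. T→C variants (editing on the antisense strand) are reported by
`call_antisense_sites` for description only.

## Signal comparison

For each site and offsets −5..+5, the current means of treatment and
control reads are compared with the two-sided two-sample KS test; a
test is emitted only where both samples have ≥ `coverage_ks` = 30
reads. The asymptotic p-value is used: at the coverage floor of 30 it
is adequate, and the profile is interpreted through its median
−log10 p per offset, not through single-test significance. Replicate
read sets of one condition are pooled before testing.

A caveat that matters for validation: the two-sample KS statistic is
discrete (D lives on a lattice of spacing ~1/n), so its p-values are
only approximately uniform under the null at moderate depth, whichever
method computes them. A uniformity check of control-site p-values is
therefore meaningful only when the lattice is fine relative to the
check's resolution; the bundled KS experiment uses 10 control
adenosines × 11 offsets (110 tests) at 400 reads per sample, where the
lattice spacing (~0.0025) is two orders of magnitude below the
resolution of a KS uniformity test on 110 values (~0.16).

## Read labeling via systematic errors

A candidate systematic error at a position is the most-supported
non-reference base in the treatment sample. It passes when (a) it has
any treatment support (dominance is by construction), (b) it is absent
from control (`n_err_ctrl` = 0, which also covers positions missing
from the control table, flagged `ctrl_missing`) *or* its treatment
error ratio `n_err/depth` is ≥ `ase_fold` = 2 times the control ratio,
and (c) it has ≥ `ase_min_reads` = 5 supporting reads with error ratio
≥ `ase_min_ratio` = 0.1.

A site is usable for labeling when it carries a passing error of the
editing-consistent type at at least one of offsets −1 (A→G), 0 (A→G)
or +1 (A→G or C→T). Requiring all three offsets simultaneously is
exposed as `ase_require_all` but off by default: the enumerated offsets
are alternatives in practice because the +1/−1 errors depend on the
local reference base. Sites with another editing site within
`site_spacing_exclude` = 3 nt are excluded so neighbouring
perturbations cannot contaminate labels. A read covering −1..+1 is
I-type iff its called base matches a qualifying error at any of those
offsets, else A-type; control-sample reads are labeled `control` and
are never I-type.

I-type labeling is precise but deliberately incomplete: an edited read
without any miscall is labeled A-type. Under the default simulator
error model the expected fraction of edited reads carrying at least one
qualifying miscall is ≈ 0.4–0.57 depending on window context, which the
measured labeling recall matches. Precision, not recall, is what the
training set needs.

## Features

Per (read, site), offset-major over the 6-mer window −3..+2, family
order Mean, STD, Length, Base within each offset, then the optional MD
block: current mean (z-units), current SD (z-units), dwell/
`length_scale` (dwell is a raw-sample count; the scale of 100 keeps the
feature near unit magnitude), one-hot *called* base, and five mean
deviations between adjacent window positions. The full default set has
6 × (1+1+1+4) = 42 dimensions. The one-hot encodes the called base
because the editing-correlated miscalls are exactly the discriminative
signal the labels exploit; encoding the reference base (available via
`use_called_base = False`) would erase them. MD is defined on the five
window-adjacent mean pairs; it is a derived contrast of Mean and is
kept for ablation studies. Pairs whose read does not cover the whole
window are skipped and counted, never zero-padded.

## Classifier

`ReadEditingClassifier` is a fully connected network with hidden widths
1024, 512, 64 (ReLU) and one sigmoid output read as the editing
probability. The stated single-output "softmax" of the architecture it
reimplements is degenerate; the sigmoid is the equivalent two-unit
softmax. The first 1024-wide layer is a learned layer applied to the
42-dimensional input — a 1024-dimensional raw input would not match the
feature space.

Training: stratified 80/20 split (`train_fraction` = 0.8); inverted
dropout 0.5 on hidden activations; Adam (lr 1e−3, β = 0.9/0.999),
batch 256; binary cross-entropy weighted by inverse class frequency
(`class_weight="balanced"`), since labeled sets need not be balanced;
early stopping on held-out loss with patience 5 and `min_delta` = 1e−4,
up to `max_epochs` = 50, restoring the best weights. The held-out 20%
serves both early stopping and the reported `heldout_auc_`; the mild
optimism this can introduce is irrelevant at the effect sizes involved
and keeps the data budget simple. All arithmetic is float32 and fully
determined by `random_state` (two fits on the same data and seed give
bit-identical weights). Loss, optimizer and schedule are this package's
choices where the original description leaves them open.

Serialization is a JSON container holding the float32 weights as exact
decimal values, the hyperparameters, a SHA-256 parameter hash, and the
feature-layout descriptor; predictions survive save/load bit for bit,
and a layout mismatch at prediction time is an error, not a warning.

AUC is computed with midrank tie handling (the normalized Mann–Whitney
U statistic) via scikit-learn; the test-suite checks it against an
exhaustive pair-counting oracle.

## Aggregation and phasing

A read is called edited at probability ≥ `call_prob` = 0.9. Sites with
fewer than `site_min_reads` = 30 reads are abandoned and carry no
verdict; otherwise a site is edited when the predicted ratio is ≥
`site_edited_ratio` = 0.1. Benchmark sets use the short-read ratios:
completely edited means strictly > 0.9, unedited means exactly 0;
everything between is excluded. Phasing restricts to reads with
predictions at every listed site (no imputation — phasing claims
require direct observation on one molecule), tabulates binary patterns
in sorted-position order, and reports the observed co-editing fraction
next to the product of the per-site marginals as the independence
reference.

## The simulator

`simulate_reads` emulates exactly the structure the method consumes:

* baseline current mean per position from a fixed 6-mer context table
  (standard-normal values seeded by the k-mer itself, so the "pore
  model" is a stable property of the generator across runs and seeds),
  with unit-SD per-read noise — z-normalized signal is approximately
  unit scale, and the method depends on shifts, not absolute pore
  physics;
* edited reads shifted by `headline_shift` = 1.0 SD scaled by the
  offset profile (−3, −2, −1, 0, +1) → (0.2, 0.3, 0.5, 1.0, 0.4). The
  real shift magnitude in SD units is not quantified by the published
  figures; 1.0 SD at the site is this package's calibration choice,
  exposed in the spec object;
* editing-correlated miscalls on edited reads with probabilities 0.4
  (A→G at 0), 0.15 (A→G at −1), 0.15 (A→G or C→T at +1, applied only
  where the reference base allows), over a baseline miscall rate of
  0.01 per position for all reads (uniform over the three alternative
  bases);
* dwell ~ geometric with mean 10 samples (only relative dwell matters
  to the classifier); `norm_std` ~ Gamma(5, 0.1), independent of
  editing — the simulator encodes no editing signal in the SD or dwell
  channels;
* per-read editing status independent Bernoulli per site, or drawn from
  an explicit multi-site pattern distribution whose marginals must
  match the per-site ratios;
* `short_read_pileup` produces the Illumina-style table used for site
  discovery: binomial A→G counts at the true ratio, a small uniform
  error rate elsewhere, and none of the nanopore systematic errors.
  Running site discovery on nanopore-derived pileups instead would call
  the systematic −1/+1 miscalls as spurious neighbouring "sites" and
  trigger the adjacency exclusion — a conflation the real workflow
  avoids by using short reads.

Outputs are byte-deterministic given the spec and seed. What the
simulator does *not* model: raw sample-level squiggle, pore state and
drift, homopolymer-dependent segmentation error, alignment and
re-squiggle artifacts, quality scores, reverse-strand reads, isoform
ambiguity, and any correlation between editing and expression. Passing
tests therefore establish that the pipeline's logic and statistics are
correct under the stated generative assumptions — not that the
classifier's synthetic AUC transfers to real flowcell data.

## Default study conditions

The bundled end-to-end experiment simulates 25 single-site transcripts
(length 160) at treatment coverage 250 and control coverage 200 with
true editing ratio 0.8 — about 5,000 truly edited treatment reads and
5,000 control reads. Ratio 0.8 keeps the −1/+1 error ratios
(0.8 × 0.15 = 0.12) above the 0.1 discovery floor so that I-type labels
arise from a mixture of offsets rather than only the site itself. The
null variant keeps the editing structure but removes its observable
consequences (zero shift, no editing-correlated miscalls); systematic-
error discovery then correctly finds nothing, so the null pipeline
trains on simulator truth labels, whose class-conditional feature
distributions are identical — the held-out AUC measures pure chance.

## Known limitations

* Per-read recall at the 0.9 call threshold is bounded by the
  information in a single molecule: an edited read with no miscall
  carries only ~1.2 SD of combined mean-shift evidence, for which even
  the Bayes-optimal posterior rarely reaches 0.9. Under the default
  generator the classifier recovers roughly the miscall-bearing
  fraction of edited reads, so model-predicted site ratios and phasing
  pattern fractions systematically underestimate true editing at
  intermediate ratios. Oracle-label experiments isolate the
  aggregation/phasing logic from this ceiling; the acceptance report
  states both numbers.
* The discovery thresholds are tuned for depth ≥ 50 short-read and
  ≥ 30 nanopore coverage; behaviour at lower depth is undefined by
  design (sites are abandoned, not guessed).
* The KS profile reports raw p-values; no multiple-testing correction
  is applied, matching its descriptive role.
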