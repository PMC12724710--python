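# Methods

## Overview

`glycophos` implements the statistical core of an integrated
glycoproteome–phosphoproteome analysis for a glycoengineering study design:
two cell lines — wild type (WT) and a glycoengineered line (AI) built to
suppress core fucosylation and GlcNAc branching while enhancing α2,6
sialylation — each profiled untreated (serum-starved) and treated
(30-minute serum re-stimulation) in biological triplicate, across three
TMT-style intensity layers (global proteins, intact glycopeptides,
phosphosites). Because the real deposited MS data are not bundled, a
first-class synthetic-data generator reproduces the statistical structure
of such a study so every stage runs and is validated end to end.

## Synthetic data model

Latent log2 intensities are Gaussian per feature:

    y_gj = b_g + o_j + beta_cl,g * AI_j + beta_serum,g(line_j) * treated_j + e_gj

with feature baselines `b_g ~ N(baseline_log2_mean=20, baseline_log2_sd=2)`
(raw intensities ~10^6, typical of MS exports), sample offsets
`o_j ~ N(0, sample_shift_sd=0.2)` emulating loading/labeling differences,
and replicate noise `e_gj ~ N(0, noise_log2_sd=0.5)`. The noise scale is a
free parameter of the emulation (real replicate variances are
feature-dependent); 0.5 log2 units corresponds to a ~35–40% CV, on the
conservative side for biological triplicates.

Planted effects:

* **glyco layer** — AI-vs-WT shifts are driven by glycan class:
  fucosylated −1.5, sialylated +1.5, branched −1.5 (additive when a
  composition belongs to several classes), and +2.0 for the two engineered
  target glycoforms N4H5F0S2G0 (bi-antennary complex, two sialic acids, no
  fucose) and N3H6F0S1G0 (hybrid, one sialic acid). Compositions are drawn
  from a fixed ~20-entry catalogue spanning high-mannose, neutral complex,
  fucosylated, sialylated, doubly-modified, branched and GalNAc forms.
* **phospho layer** — a fraction (default 10%) of sites is
  serum-responsive with treated−untreated shift `serum_amplitude_log2=1.5`
  in WT, multiplied by `ai_blunting_factor=0.3` in AI. All responsive sites
  carry the same signed shift, which makes the planted amplitude directly
  recoverable as a group-mean difference.
* **global layer** — 10% of proteins carry a ±1.0 cell-line shift with
  random sign.

Missingness is MNAR-dominated: a cell is missing with probability
`sigmoid(-mnar_strength * z - 2)` where `z` is the standardized latent
log2 intensity (≈12% at the median intensity, →50% two SD below), plus 2%
MCAR. Matrices are emitted on the raw scale (2^latent) so the
preprocessing chain is exercised. A single integer seed determines all
draws; a ground-truth table records the planted log2FCs per feature.

What the generator does **not** emulate: peptide/protein identification
error, reporter-ion interference and ratio compression, feature-dependent
variance heterogeneity beyond the variance-prior structure, batch/plex
effects beyond a scalar sample offset, and time-course kinetics. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to every artefact of real MS data.

## Preprocessing

Stage order: clean → log2 → median-center → detection filter → impute.

* **clean** collapses duplicate feature ids (keeping the row with the
  highest total detected intensity) and converts zero/negative/non-finite
  entries to missing — an exported zero means "not detected".
* **median-center** subtracts each sample's median of observed log2 values
  (median-only; no MAD scaling).
* **detection filter** keeps features observed in ≥ `ceil(0.70 * n)`
  samples, evaluated on the pre-imputation mask (the only non-circular
  choice).
* **imputation** is a transparent, seeded three-component ensemble:
  (a) feature-space kNN (k=10, Spearman-correlation distance between
  feature profiles; ranks computed with row-median placeholder fill,
  imputed values taken only from observed donor cells; the donor pool is
  capped at the 4000 most complete features for tractability),
  (b) a left-censored draw N(q1_sample − 0.5, 0.3·sample SD) for cells of
  features entirely undetected within a replicate group (the MNAR
  signature), and (c) the feature's observed median. Each missing cell
  receives the mean of the applicable estimates; observed cells are never
  modified and the detection mask is preserved as provenance.

QC reports per-feature CVs within replicate groups on the raw scale,
sample×sample Spearman correlations on log2 values, per-sample intensity
quantiles and per-feature detection rates.

## Moderated statistics

Per feature, ordinary least squares against a shared design matrix gives
coefficients, residual variance s² and df d = n − p. Variances are shrunk
toward a pooled prior by treating s² as scaled-inverse-chi-square with
hyperparameters (d0, s0²):

    s~² = (d0·s0² + d·s²) / (d0 + d)

Hyperparameters come from moment matching on e = log s² − ψ(d/2) +
log(d/2): the trigamma equation ψ′(d0/2) = var(e) − mean ψ′(d/2) is solved
by Newton iteration; when the right side is non-positive the prior is
degenerate (d0 = ∞, s0² = mean of the variances, matching Bioconductor
limma's `fitFDist`). Moderated t uses s~² with d0 + d degrees of freedom;
the omnibus moderated F over the three non-intercept coefficients of the
2×2 factorial (intercept + cell line + condition + interaction, treatment
coding with WT/untreated reference) ranks features for integration. The
implementation is validated against limma (`lmFit`/`eBayes` via Rscript)
to ~1e−8 and against closed-form reductions (d0=0 → ordinary t; k=1 → t²).

Pairwise contrasts are fit on the relevant sample subset (e.g. starved
samples only for the baseline AI-vs-WT comparison), matching how the
figures pair conditions. Significance = BH FDR < 0.05 and |log2FC| > 0.58
(~1.5-fold). The engineered-enzyme validation uses a Welch two-sample t
between AI and WT starved samples with a one-sided p in the expected
direction (knock-ins up, knock-outs down).

## Glycan classes

Compositions are parsed from the N_H_F_S_G_ shorthand (GlcNAc, hexose,
fucose, Neu5Ac, GalNAc). Predicates: sialylated S>0, fucosylated F>0,
branched N>4; starred mutually exclusive variants (S>0∧F=0, F>0∧S=0);
target flags equal the two exact engineered compositions. Class abundance
ratios are computed on raw, detection-filtered, un-imputed intensities
with missing-as-zero (class total / total of all glycopeptides, per
sample) and compared AI vs WT with Welch's t. Branched membership overlaps
the other classes (only the starred classes are exclusive). Class-level
log2FC distributions summarise the significant baseline glycopeptides.

## Integration and response categories

The top 500 features per layer by moderated F (FDR < 0.05; ties broken by
feature id) are completeness-filtered (≥70% on the pre-imputation mask),
row-z-scored and biclustered (Euclidean distance, complete linkage,
deterministic leaf order). Constant rows are dropped with a warning. The
pathway heatmap groups rows by pathway label (supervised, sorted labels)
and clusters within groups only; z-scoring uses the sample subset passed
by the caller (all stimulation samples for the pathway view).

Serum-response categories over the union universe of both within-line DE
tables: WT* (significant in WT only), AI*, Both, NS — a strict partition.
Protein collapse uses the any-site rule: a protein is significant in a
line iff at least one of its sites is; the rule is recorded in the output
metadata.

## Over-representation analysis

Hypergeometric upper-tail test (P(X ≥ k)) of each direction's significant
gene list against GMT collections, BH-corrected within each (cell line,
direction) stratum, filtered to adjusted p < 0.05 with non-zero overlap.
The universe defaults to all genes detected in the tested layer after
preprocessing (configurable; this choice materially affects p-values and
is recorded with the results). The display rule unions each line's top-20
terms per direction and attaches the partner line's row, marking missing
partners as not significant.

## Network modules

STRING-export edge lists (0–1 or 0–1000 score dialects auto-detected) are
thresholded at confidence ≥ 0.4 (inclusive), restricted to genes carrying
significant baseline glycopeptides or significant serum-response
phosphosites for the given cell line, and reduced to the largest connected
component (ties by the lexicographically smallest member). MCODE follows
the canonical algorithm with the study's parameters (node score cutoff
0.1, degree cutoff 2, k-core 2; haircut on, fluff off): vertex weight =
k_max × density of the highest k-core of the closed neighbourhood;
seeds processed in decreasing weight (ties by node id, only weights > 0);
expansion adds unused neighbours with weight ≥ 0.9 × seed weight; haircut
trims each module to its 2-core and modules without a 2-core are
discarded. Modules are disjoint and ranked by density × size. Note a
consequence of the canonical weighting: two equally dense cliques joined
by a single bridge merge into one module, because bridge endpoints carry
the same weight as clique-internal nodes. Node annotations record the
backing layer (glyco/phospho/dual), the number of significant modified
features, and the signed log2FC of the maximum-magnitude feature.

## Pipeline and determinism

`run_all` executes data → preprocess → modstats → glycan → integrate →
enrich → network, writing TSV/JSON/GraphML outputs and a manifest with a
SHA-256 per file and the full parameter snapshot. One global seed fans out
to per-stage seeds by hashing the stage name, so stages rerun in isolation
reproduce the full-run results. Outputs are byte-identical across reruns
with the same config and seed; stage timings go to the log stream rather
than the manifest so the output directory itself is reproducible. In
synthetic mode the gene-set collection and interaction edge lists are also
generated (seeded) since no external services are queried.

## Problem sizes and numerical choices

Default generator sizes are 1000 global / 800 glyco / 1500 phospho
features over 12 samples — ample for stable prior estimation (hundreds of
features suffice) while keeping a full run around a second. Validation
experiments use the sizes their statistics require: 5000 draws for prior
recovery, 2000 features for the null-FDR bound, 100 seeded replicates of a
500-site phospho layer for the blunting comparison, 50 random ≤12-node
graphs for the MCODE brute-force check. Tolerances: exact-algebra checks
at 1e−10; limma agreement at 1e−8 (two independent trigamma-inverse
Newton solvers); hyperparameter recovery within 15% (sampling error at
5000 features); detection-threshold ceilings use a 1e−9 epsilon guard
against float artefacts (0.7×12 must count as 8.4 → 9, not 8).

## Known limitations

* The imputation ensemble is a documented stand-in with auditable
  components, not a re-implementation of any published ensemble imputer;
  its row-median component attenuates fold-changes of features with
  group-censored cells (visible as recovered amplitudes slightly below the
  planted values).
* ORA p-values depend strongly on the universe definition; with the
  detected-gene universe they are not comparable to web-service results
  computed against genome-wide domains.
* Glycan class logic is purely compositional; linkage isomers (α2,3 vs
  α2,6 sialylation) are indistinguishable.
* The 2×2 factorial assumes a shared within-feature variance across all
  four cells; strong variance heterogeneity between conditions would call
  for weighted fits, which are out of scope.
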