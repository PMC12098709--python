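# Methods

## Site identity and library mapping

A phosphosite is identified two ways, in order of precedence: by host
gene symbol plus the flanking sequence of the phosphorylated residue,
or by gene plus residue type and position. Flank comparison uses the
centered 11 characters (lowercased), so a 15-mer and an 11-mer
describing the same site match; this also makes mapping robust to
isoform-dependent position shifts. When one library site matches
several matrix rows, the first occurrence wins and a warning is
emitted — coverage-weighted disambiguation would be possible but the
situation indicates upstream identifier problems that should be fixed
in the data, not papered over.

Libraries are edge sets deduplicated on (kinase, canonical site key);
merging concatenates provenance tags. Self-sites (substrate gene equal
to the kinase symbol) can be censored; the tumor pipeline refuses
uncensored libraries outright because activating sites on the kinase
itself would leak the gold-standard signal into the scores.

### Library randomization

The negative-control library permutes site labels within multiplicity
classes (sites targeted by exactly c kinases are shuffled among
themselves). This preserves, exactly and by construction, the two
quantities a degree-matched null should hold fixed: every kinase's
target-set size and the multiset of per-site kinase counts. Because
the construction cannot fail, no retry logic exists.

## Scoring methods

All scorers share these conventions:

* sample standard deviations use the n−1 denominator;
* missing values are dropped per column before scoring, so the
  measured-target count m varies by column; cells with m < 5 (the
  `min_targets` default) are NA;
* quantiles use the Hyndman–Fan type-7 (linear interpolation) rule;
* undirected tests (KS, Mann–Whitney, Fisher, χ²) return p-values and
  carry no direction, but the benchmarks multiply scores by the
  perturbation sign, so the −log p score is given the sign of the
  target-vs-background location shift. This sign injection is a
  package choice, not part of the original tests;
* rank tests report −ln p, over-representation tests −log10 p,
  mirroring the conventions of their usual implementations; p-value
  underflow is capped at the smallest positive float and flagged.

Choices worth flagging:

* **zscore (RoKAI-style)** omits the background-mean subtraction that
  KSEA applies — on fold-change data centered near zero the two nearly
  coincide, but zscore is shift-sensitive (and both are exposed).
* **karp** omits the original 10⁶ scaling constant (exposed as
  `karp_scale`); ranks are unaffected.
* **lm_rokai** solves (AᵀA + λI)x = Aᵀy with no intercept on the raw
  column values. The inputs it sees (log fold-changes or
  median-centered intensities) are already near zero; fitting the raw
  response keeps the natural reductions — a single kinase's activity
  is the mean of its targets, disjoint kinases decouple into
  independent fits. λ defaults to 0.1; λ = 0 is allowed only when the
  design has full column rank.
* **mlm** drops exact-duplicate membership columns (kinases with
  identical measured target sets) with a warning; the surviving
  coefficient then equals the univariate fit on the merged set.
* **viper** is a two-tail rank-enrichment approximation (mean normal
  score of the targets, permutation-normalized), not the full
  three-tail mode-of-regulation model.
* **pca** runs across all columns at once per kinase on target rows
  measured in every column, and returns per-column PC1 coordinates
  oriented to correlate positively with the per-column target mean.
  The variance explained by PC1 is kept as metadata: a single
  per-kinase variance number cannot feed per-experiment benchmarks, so
  the coordinates are the score.
* permutation methods (`norm_mean`, `ptmsea`, `viper`) draw their
  nulls from a generator seeded per column from the config seed, so
  runs are bitwise reproducible.

## Perturbation benchmark

Scores of each annotated experiment are multiplied by the perturbation
sign (inhibition/knockout −1, activation/overexpression +1) and
divided by the sample SD of the experiment's finite scores.
Experiments whose annotated kinases all fall under the min-target rule,
and zero-spread experiments, are excluded with warnings. Multi-target
annotations (e.g. multi-specific inhibitors) contribute one
true-positive cell per annotated kinase.

* **Down-sampled AUROC**: all finite (experiment, kinase) cells are
  flattened; per repeat, |TP| true negatives are drawn without
  replacement and a midrank (Mann–Whitney U) AUROC computed; 1000
  repeats; the point estimate is the distribution median. No
  per-kinase averaging is applied at this stage — each TP cell counts
  once.
* **Scaled rank**: rank of the annotated kinase (midranks for ties,
  descending scores) divided by the number of finite scores; averaged
  per kinase first, then across kinases, so frequently perturbed
  kinases do not dominate.
* **P_Hit(k)**: indicator of rank ≤ k, aggregated the same two-level
  way, for k ∈ {5, 10, 20}.

Concordance between runs (method/library combinations) is summarized
by per-experiment Pearson and Spearman correlations over shared finite
kinases and the Jaccard index of the top-10 up- and downregulated
sets, averaged across experiments.

## Tumor benchmark

Gold-standard construction per cohort and kinase: the basis vector is
the kinase's protein row, or — for the activating-site basis — the
best-covered annotated activating site (when a kinase has several
qualifying sites, the one with most finite measurements is used, so a
(kinase, sample) pair can never carry both labels). Vectors with fewer
than 30 finite values or variance < 0.1 are dropped; the rest are
z-scored (n−1, the same convention as everywhere else) and samples with
z > z\* labeled GS+, z < −z\* GS−. Named presets map tail mass to the
one-sided normal quantile: 5% → 1.645, 2.5% → 1.96, 10% → 1.282,
15% → 1.036. The GS− rule is the mirror image of GS+ (bottom tail),
giving disjoint sets by construction.

Evaluation: site rows are median-centered within the cohort,
activities inferred per sample with a self-site-censored library,
kinases with fewer than 30 finite scores dropped, each kinase row
z-scored across samples. GS pair scores are pooled across kinases and
cohorts; per repeat ⌊0.8·n⌋ pairs are subsampled without replacement
from each class and a midrank AUROC computed (1000 repeats, median
reported). With `frac=1` the distribution degenerates to the exact
full-data AUROC.

## Normalization

Sites are paired with their host protein's row by gene symbol; sites
without a measured host protein, or with fewer than `min_meas` (30)
paired finite observations, are removed. `subtract` takes site −
protein per sample. The regression strategies return residuals of
site ~ intercept + protein with the stated pooling: one global model,
one per host protein, or one per site row. Intercepts are included in
all variants — without them the residuals would retain a mean offset
that the downstream median-centering would have to absorb. A site
whose host protein is constant across the paired samples cannot be
regressed per-site and falls back to subtraction, flagged and counted.

## Synthetic data

The generators produce the structure the benchmarks assume, nothing
more.

* **Library**: per-kinase target counts drawn uniformly from a range;
  each assignment reuses an already-claimed site with probability
  `overlap_prob`, else claims a fresh site — exact degrees, approximate
  overlap fraction, and a hard error when the site pool is exhausted.
* **Perturbation study**: background values N(0, σ²); the perturbed
  kinase's targets shifted additively by sign·Δ·σ; entries masked
  missing uniformly at random. Defaults — 20 kinases, 500 sites,
  10–25 targets per kinase, Δ = 3, σ = 1, 10% missingness, 20
  experiments (one perturbed kinase each, random sign) — define the
  default study conditions.
* **Tumor cohort**: kinase protein ~ N(0,1); true activity =
  ρ·protein + √(1−ρ²)·latent with ρ = 0.9 by default; site value =
  host-protein baseline (unit weight) + mean activity of its targeting
  kinases + N(0, σ²) with σ = 0.5; one activating site per kinase
  reads out activity (not protein) plus noise, exercising the premise
  that activating-site levels track activity more directly than
  protein abundance does. Default cohort: 50 kinases, 200 samples.

What the generators deliberately do not model: intensity-dependent
missingness, peptide-level ambiguity and multi-phosphorylated
peptides, inter-site correlation beyond shared kinases, batch
structure, or heavy-tailed noise. A method that excels here has been
shown to recover a clean additive signal through the correct library —
a necessary condition, not proof of performance on real cohorts, where
library incompleteness and correlated biology dominate.

## Problem sizes and numerics

The default fixtures (20×500 perturbation study, 50-kinase/200-sample
cohort, 1000 benchmark repeats) were chosen as the smallest regimes in
which the benchmark statistics stabilize — the subsampling
distributions are tight and the control/method gap is unambiguous.
Degenerate inputs resolve to NA rather than errors wherever a single
kinase/column is affected (zero background SD, empty target sets,
no residual degrees of freedom, zero-variance PCA blocks); whole-input
problems (self-site leakage, empty libraries, malformed tables) raise.
Ties use midranks throughout. All randomness flows from explicit
seeds; two runs with the same seed are bitwise identical.
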