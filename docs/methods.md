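# Methods

This note documents the models, parameter choices, numerical conventions
and limitations behind `dielarray`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Study design model

A diel experiment is a list of samples, each a (time point, replicate)
pair. Time points carry a clock hour, hours since the start, a day
index, and a phase label of the form `L{h}` / `D{h}` — hours into the
light or dark period — with a leading day number from the second
light–dark cycle on (`2L6` is 6 h into day 2's light period). Two
conventions fix phase arithmetic unambiguously:

* the sunrise instant is the *end* of the dark period (`D12` for a 12 h
  night), and sunset is `L{daylight}`;
* a new day index opens every 24 h after the first sunrise, so a
  10-point, 3 h design with a 12 h day reads
  `L3 L6 L9 L12 D3 D6 D9 2D12 2L3 2L6`.

`make_design` starts sampling one interval after sunrise, matching field
campaigns that begin shortly after dawn. Daylight hours are an input;
no solar geometry is computed.

## Synthetic-data generator

The generator exists so that every downstream stage can be tested
against ground truth. It emulates, with defaults chosen to match the
open-ocean study conditions:

* 10 time points at 3 h intervals (~27 h) with duplicate samples;
* genes carried by 4–6 probes of 60 nt;
* a diel subpopulation (default 20%) following
  `baseline + amplitude·cos(2π(t − peak)/24)` at clock hour `t`, peak
  phases uniform on the 24 h clock, default amplitude 1.5 log2 units
  against innovation noise sd 0.5 (a 3× amplitude-to-noise ratio);
* AR1-correlated noise per gene and replicate series (default
  φ = 0.3), initialized from the stationary distribution
  (variance σ²/(1−φ²)) so there are no burn-in transients;
* a floor population (default 15% of genes at log2 level 1 versus a
  bulk baseline of 8 ± 1) emulating targets absent from the sample.
  This fraction deliberately exceeds the detection stage's noise decile
  (10%) so the bottom decile of each sample is genuinely floor-level —
  on real arrays the noise floor is the mass of non-hybridizing probes;
* an ERCC-style ladder, `log2 intensity = intercept + slope·log2(aM)`,
  twelve 2-fold steps from 4.7 aM, whose least concentrated member is
  the detection bound;
* probe expansion `intensity = 2^(gene level + affinity + noise)` with
  one affinity offset per probe held constant across samples — the
  additive probe effect that median polish assumes;
* sinusoidal environmental covariates (temperature, oxygen,
  chlorophyll, PAR clipped at zero) on the same clock, and a
  piecewise-linear potential-density profile whose mixed-layer depth is
  known exactly.

What the generator does **not** emulate: scanner spatial artifacts, dye
chemistry, batch effects across arrays, cross-hybridization bleed-through
into intensities, or non-Gaussian heavy-tailed noise. Passing tests
therefore demonstrate correctness of the algorithms under the stated
noise model, not robustness to every failure mode of real arrays. The
AR1+sinusoid form is itself an assumption made for testability.

## Platform screening

Cross-hybridization screening aligns each probe into every reference
sequence of a *different* sublineage (both strands) with edlib's infix
alignment; identity is computed over the alignment span with gaps
counted as mismatches, and the aligned fraction over the probe length.
Hits require ≥95% identity over ≥95% of the probe; thresholds are
inclusive by default with a `inclusive=False` strict variant. Bases `N`
match nothing. Clustering is greedy and length-sorted (ties by id):
each probe joins the first cluster whose founder it matches at ≥95%
identity over the full probe, unaligned overhang counting against
identity. Probes in clusters spanning multiple sublineages or genes are
rejected unless their gene symbol is whitelisted (conserved genes such
as *nifH*).

## Normalization

Quantile normalization maps every sample onto the mean order-statistic
vector; ties within a column share the mean of the reference values they
span, making the transform order-independent and idempotent (at the
cost of exact distribution equality in tied columns). Linear
intensities are quantile-normalized first and log2-transformed second;
no background correction is applied — the detection stage handles
background through the noise floor.

Median polish sweeps rows (probes) first, then columns, up to
`max_iter = 10` sweeps or until the total absolute residual changes by
less than `tol = 0.01`. Gene level in sample *s* = overall + column
effect *s*. Single-probe genes pass through as their own log2 series.

## Detection

Per sample, the noise floor is the dimmest `floor(0.10·G)` genes (≥2):
`μ` their median, `σ` their sample sd (a MAD variant is selectable).
SNR = (level − μ)/σ; the per-sample flag is strict `SNR > 5`. A gene is
detected iff SNR exceeds the threshold in ≥1 sample (`min_snr_samples`
flag) **and** it beats the least concentrated spike in strictly more
than 3 samples, by raw intensity or by predicted log2 count. The count
model regresses log2 concentration on log2 intensity over all
spike × sample pairs (concentration is proportional to count for a
fixed spike volume, so the shared constant cancels in comparisons). A
constant bottom decile raises an error directing the caller to perturb
or switch the spread estimator rather than silently dividing by zero.

## Diel calling

Replicates are averaged onto the regular time grid before scoring (the
background generator uses the same grid length). The Fourier score is
`F = |Σ xᵢ e^{−iωtᵢ}|` on the standardized series. The AR1 fit uses
lag-1 autocovariance with 1/n divisors on the demeaned series, φ clipped
to (−0.999, 0.999), innovation variance γ₀(1−φ²).

Each gene contributes one surrogate per background dataset, drawn from
its *own* fitted AR1 and scored identically. The raw FDR at threshold
*F* is `mean_b #{background ≥ F} / #{observed ≥ F}`, clipped to [0,1];
each gene then receives the minimum raw estimate over thresholds that
still include it (q-value convention), which makes the estimate
non-increasing in the score. Tied scores share one FDR. The
classification is invariant to any common positive rescaling of
observed and background scores, so the score normalization convention
cannot affect calls. Defaults: 1000 background datasets, FDR < 0.25.

Peak and trough labels: replicate means per time point, then day means
per clock label (`L6` with `2L6`), argmax/argmin with ties broken to the
earliest label in timeline order.

Diel profiles are clustered on 1 − Pearson distance with centroid
linkage. Cluster support is the fraction of bootstrap resamples of the
time points in which the same leaf set reappears as a node of the
re-computed tree; genes are assigned to maximal non-root nodes with
support ≥ 0.95. This is an ordinary bootstrap support, not the
multiscale-bootstrap "approximately unbiased" p-value — a deliberate
simplification; supports are comparable but not numerically identical
to AU values.

## Comparison statistics

Welch, one-sample and Fisher tests are delegated to scipy; the
one-tailed tests default to "greater". The two-sided Fisher p uses the
probability-mass rule. Standardized levels are medians of within-sample
z-scores over the site's detected genes. Pathway matrices convert
per-column pathway medians (over detected gene × sample cells) to
empirical quantiles `(rank−1)/(n−1)` with mean ranks for ties, rounded
to the nearest 5% — invariant to any monotone transform of a column,
which is what justifies mixing array intensities and sequencing counts
in one display. Pathways detected in no more than one third of a
column's samples are dropped. Peak shifts are minimal circular
distances between label positions on the 24 h light–dark clock
(≤ 12 h); "maintained" means a shift of exactly 0 h.

## Environmental analysis

Mixed-layer depth is the first pressure at which σθ reaches its
(interpolated) 10 dbar value + 0.03 kg m⁻³, linearly interpolated
between the bounding records; an unreached threshold returns the
deepest pressure with a flag. NMDS uses scikit-learn's non-metric MDS
(2-D, Euclidean gene-by-gene distances, multiple seeded random starts,
normalized Kruskal stress-1); identical points short-circuit to a
zero-stress origin embedding. envfit regresses each centered variable
on the centered coordinates; r² is the squared multiple correlation and
p = (1 + #{permuted r² ≥ observed})/(n_perm + 1) with 999 permutations,
the add-one correction preventing p = 0. The ordination points are
genes by default; the pairing of per-sample environmental data with
gene points (via per-gene correlation summaries, as in the pipeline
stage) is configurable because the canonical wiring of per-cast CTD
data onto a gene ordination is genuinely open — sample-point
ordinations are supported by passing the transposed matrix.

## Pipeline

A run is described by one YAML-serializable config (thresholds, seeds,
stage toggles, optional time-point subset for sensitivity reruns). All
randomness derives from one master seed split per stage via
`SeedSequence.spawn`, so identical config + seed reproduces every output
byte-for-byte; each output header carries a hash of the analysis
parameters (I/O paths excluded). A time-point subset rerun restricts
the design order-preservingly and repeats every stage on the subset.

## Problem sizes

The test suite and acceptance script run on synthetic fixtures of
300–500 genes, 10 time points × 2 replicates, 200–1000 background
datasets and 999 permutations — sizes at which every stochastic check is
stable across seeds while the whole suite stays fast. The all-noise FDR
check uses 500 genes × 5 seeds at φ ∈ {0, 0.3}.

## Known limitations

* The ratio FDR is a plug-in estimator; with few genes or few
  background sets it is noisy (a warning fires below 10 sets).
* Centroid linkage on correlation distances can produce inversions
  (non-monotone merge heights); supports are still well-defined on leaf
  sets.
* The cross-hybridization screen optimizes edit distance, which for
  heavily gapped alignments is not exactly the maximum-identity local
  alignment; at the 95% identity threshold on 60-mers the difference is
  immaterial.
* Detection treats the spike ladder as sharing the gene intensity
  scale; probe-affinity differences between spike and gene probes are
  not modelled.
* No absolute transcripts-per-cell quantification is attempted.
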