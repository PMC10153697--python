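# dielarray

Analysis of diel (24-hour) gene expression in targeted microarray
metatranscriptomes, built around the study system of *Candidatus*
Atelocyanobacterium thalassa (UCYN-A), an uncultivated N₂-fixing
cyanobacterial endosymbiont whose sublineages (A1, A2, A3) are probed by
a custom expression array sampled over light–dark cycles at sea.

The package is for researchers analyzing probe-level time-series
intensities from targeted arrays (or comparable count data): it covers
probe quality control, normalization, spike-in-calibrated gene
detection, periodicity calling, cross-habitat comparison statistics and
environmental covariate analysis, with a synthetic-data generator so
every stage can be validated against known ground truth.

## What it computes

**Normalization.** Probe intensities are quantile-normalized across
samples, log2-transformed, and summarized per gene by Tukey median
polish of the probe × sample block (the robust multi-array-average
convention): the gene's transcript level in sample *s* is the overall
effect plus the sample-*s* column effect.

**Detection.** A gene is detected when its signal-to-noise ratio

    SNR = (level − median(bottom decile)) / sd(bottom decile)

exceeds 5 in at least one sample, *and* it beats the least concentrated
ERCC spike-in in strictly more than 3 samples — by raw log2 intensity or
by predicted transcript count from an OLS model of log2 concentration on
log2 intensity (either comparison suffices).

**Diel calling.** Each detected gene's replicate-averaged, standardized
series *x* is scored against the diel harmonic at ω = 2π/24 h:

    F = √[ (Σᵢ xᵢ cos ω tᵢ)² + (Σᵢ xᵢ sin ω tᵢ)² ]

Significance comes from per-gene AR1 surrogates (fitted lag-1
autocorrelation φ, stationary start): the FDR at score *F* is the mean
number of background scores ≥ *F* over background datasets divided by the
number of observed scores ≥ *F*, monotonized in the q-value convention.
Genes with FDR < 0.25 are diel genes; they get peak/trough phase labels
(L3…D12 style, with days merged) and correlation-distance cluster
assignments with bootstrap support.

**Comparison & environment.** Cross-site standardized levels (median of
within-sample z-scores), detection overlap, Welch and one-tailed
t-tests, Fisher's exact test of diel status by habitat, pathway quantile
matrices on a 5% grid (which lets intensities and read counts share one
scale), circular peak-shift tables, mixed-layer depth from a σθ offset
of 0.03 kg m⁻³ relative to 10 dbar, non-metric MDS with Kruskal stress,
and envfit-style environmental vector fitting with permutation p-values.

## Worked example

```python
from dielarray import make_design, detect_genes, FourierDielModel
from dielarray.normalize import quantile_normalize, median_polish_summarize
from dielarray import synth

design = make_design(n_timepoints=10, interval=3, n_replicates=2,
                     sunrise_hour=6.0, daylight=12.0)
truths = synth.make_truths(400, frac_diel=0.2, amplitude=1.5, seed=1)
expr_true = synth.simulate_expression(design, truths, noise_sd=0.5, seed=2)
probes, annotation = synth.expand_to_probes(expr_true, truths, seed=3)
ercc = synth.spike_ercc(design, noise_sd=0.1, seed=4)

expr = median_polish_summarize(quantile_normalize(probes),
                               annotation["gene_id"], design)
detection = detect_genes(expr, ercc, snr_threshold=5, min_samples=3)
print(f"{len(detection.detected)} of {expr.data.shape[0]} genes detected")

model = FourierDielModel(expr.sel_genes(detection.detected),
                         period=24.0, fdr_threshold=0.25)
results = model.fit(n_background=1000, seed=5)
print(results.summary())
```

prints

```
359 of 400 genes detected
Fourier/AR1 diel periodicity analysis
==============================================
genes scored:           359 of 359
period (h):             24
background datasets:    1000
FDR threshold:          0.25
diel genes:             87 (24.2% of scored)
median |phi| (AR1):     0.280
seed:                   5
diel peak labels (top): L12: 14, L6: 12, L9: 12, D9: 12
```

The 41 undetected genes are exactly the fixture's floor-level population
(targets effectively absent from the sample); the 87 diel calls recover
all 78 planted diel genes (amplitude 3× the noise sd) with an empirical
false-discovery fraction of 0.10, inside the 0.25 target. `results.results_frame()` returns the per-gene table
(`Fourier_score`, `Fourier_FDR`, `Diel`, `Diel_cluster`, peak and trough
labels) ready to write as TSV.

The same pipeline runs from the shell:

```sh
dielarray simulate --out fixture/ --n-genes 400 --seed 1
dielarray run --fixture fixture/ --out run1/ --seed 1
dielarray mld --ctd profile.csv
```

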