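# Methods

## Scope and data model

The package operates on beta-value matrices: CpG probes in rows, samples in
columns, entries in [0, 1] (fraction of methylated signal), `NaN` for
missing measurements. It deliberately starts *after* array preprocessing —
IDAT parsing, normalization and detection p-values are out of scope; inputs
are exported beta matrices (450K/EPIC convention) or targeted
pyrosequencing percent measurements (converted as beta = percent / 100).
Sample classes come from a closed vocabulary: PSC (pluripotent), ENDO,
MESO, ECTO (the three germ layers), ENDOMESO (a combined
endoderm/mesoderm class, useful because directed endoderm and mesoderm
differentiation can be epigenetically very similar), and OTHER.

## Quality and probe filters

* Sample QC removes samples whose summed medians of the methylated and
  unmethylated channel intensities fall strictly below 20 (a sample at
  exactly 20 is kept). The magnitude of the threshold presupposes log2-scale
  medians; the intensity-summary file should record its scale rather than
  rely on a silent assumption. The medians themselves are supplied
  externally (computing them is part of the excluded IDAT stage).
* Probe filtering removes sex-chromosome (X/Y) probes, non-CpG probes
  (`ch`/`rs` classes) and SNP-associated probes. Probes missing from the
  annotation are dropped conservatively, with a logged count: an
  unannotated probe cannot be certified clean.
* Platform intersection restricts to a supplied probe universe (e.g. the
  CpGs shared by the 450K and EPIC arrays), preserving probe order; an
  empty intersection is an error.
* Most-variable selection keeps the k probes (default 10,000) with the
  largest across-sample variance, using the unbiased (n−1) estimator over
  non-missing entries; probes with fewer than two observations get −∞ and
  are never chosen; ties break lexicographically by probe ID so results are
  deterministic and invariant to sample order.

## Marker selection

For a target class against all other labeled samples, each probe gets
`diff_means` (mean beta in target − mean in rest, signed) and `var_sum`
(unbiased within-target + within-rest variance); probes with any missing
value in either group are excluded (complete-case — on a handful of
markers, imputation would dominate the result). The selection score is

    score = diff_means² − a · var_sum,   a > 0,

whose zero contour is the parabola `var_sum = diff_means²/a` in the
(difference, combined-variance) plane: probes inside the parabola (large
separation, small spread) score positive. The score is monotone increasing
in |diff_means| at fixed variance and strictly decreasing in variance at
fixed difference. When `a` is not supplied it is calibrated by a 1-D scan
over a log-spaced grid (10⁻² to 10³), choosing the value that maximizes the
score gap between the k-th and (k+1)-th ranked probe — the steepness at
which the selected panel separates most cleanly from the runner-up; the
chosen value is logged and recorded in the emitted signature metadata.
This is a transparent single-parameter reimplementation of the
"high difference in means, low within-group variance" criterion used by
CimpleG-style CpG classifiers, not a bit-exact port of any package. Ties in
score break by larger |diff_means|, then probe ID.

Orientation (hyper/hypermethylated vs hypo in the target class) is set from
the sign of `diff_means` at selection time, or re-derived for an existing
signature by comparing target-class means against PSC-sample means
(`orient_signature`); exact ties are flagged as ambiguous. The packaged
default panel carries the published CpG IDs; since per-CpG directions for
the germ-layer panels are not published, those orientations default to
"hyper" with `orientation_verified: false` metadata and a loud warning when
scored — they must be re-derived from a labeled reference dataset before
differentiation scores are interpreted.

## Differential methylation

The dual rule flags a probe as relevantly changed between two groups when
|Δ mean beta| ≥ 0.2 AND Benjamini–Hochberg adjusted p ≤ 0.05. The default
test is an empirical-Bayes moderated t test: per-probe pooled variances
(df = n₁+n₂−2) are shrunk toward a scaled inverse-chi-square prior whose
parameters (d₀, s₀²) are fitted across probes from the moments of log s²
(method of moments on the log-F distribution, Smyth 2004; the trigamma
equation is inverted by Newton iteration), and the moderated t has
df = d + d₀. With homogeneous true variances the fit drives d₀ large and
the test approaches a common-variance z test. A plain Welch t test is
available via `method="welch"`; at n of ~6 per group it is noticeably more
vulnerable to underestimated per-probe variances. Degenerate probes with
zero variance in both groups get p = 1 when the means are equal (no
evidence) and p = 0 when they differ (the difference is exact). BH
adjustment runs across all tested probes.

Note on the global-null behavior: with m independent null probes, the
probability that BH at α = 0.05 rejects at least one is ≈ α (Simes), so
over many datasets a few percent of all-null experiments will flag ≥1 probe
even with the Δ ≥ 0.2 guard; the dual rule controls the FDR, not the
family-wise error across experiments.

## Scores

Pluripotency score: sum over the PSC panel of the oriented methylation
`m(β) = 1 − β` for hypo markers (the published panel; `β` directly for a
hypothetical hyper marker); range [0, m] for m markers, [0, 3] for the
default panel. No "pluripotent" cutoff is imposed — thresholds are not
settled for these scores — but callers can apply their own. A missing
marker beta aborts the score with an error naming the probe: a 2-of-3 sum
is not comparable to the 0–3 scale, so there is no silent renormalization
(in batch scoring the affected score becomes NaN with a flag).

Differentiation scores: per marker CpG, `m(β_sample) − m(β̄_PSC)` with the
orientation-aware `m` above, where `β̄_PSC` is the mean beta of
undifferentiated PSC reference samples; exactly 0 for the reference itself,
bounded in [−1, 1], signed (a sample can be *less* methylated toward a
lineage than the PSC mean; values are reported raw, not clipped). The
lineage aggregate is the arithmetic mean of the panel's per-CpG scores —
a transparent, scale-preserving summary; per-CpG values are always kept
alongside.

## Deconvolution

The reference matrix holds mean beta values of the marker CpGs per class,
built from a labeled selection dataset: `full` mode uses the
PSC/ENDO/MESO/ECTO panels (12 CpGs × 4 classes), `endomeso` mode the
PSC/ENDOMESO/ECTO panels (9 CpGs × 3 classes; whether ENDO/MESO CpGs
should additionally inform that mode is genuinely open, so the composition
is exposed as a mode rather than hard-coded). Reference cells can be
replaced by targeted pyrosequencing class means where measured
(`adjust_reference_with_pyro`), with per-cell provenance recorded —
pyrosequencing and BeadChip measurements of the same CpGs agree closely,
and an assay-matched reference removes residual platform offsets.

Per sample, Lawson–Hanson active-set NNLS solves `min_{f≥0} ‖R f − b‖₂`
over the usable (non-missing) marker rows; missing rows are dropped rather
than imputed, and a sample with fewer usable rows than classes is flagged
under-determined (NaN estimates) without failing the batch. Raw
coefficients are reported alongside fractions normalized to sum to one —
the fit itself is unconstrained in scale, which keeps the residual (RMS
deviation between observed and reconstructed marker betas) interpretable as
fit quality; an all-zero solution yields uniform fractions with a
`degenerate` flag. The predicted class is the arg-max fraction
(lexicographic on ties, flagged). Because early germ-layer specification is
a continuum rather than a defined endpoint, fractions are a surrogate
measure of early fate decisions, not an absolute cell-type census.

## Synthetic data

The generator emulates the structure this toolkit consumes. Per-probe
baseline betas are drawn from Beta(0.5, 0.5) — bimodal, as real methylomes
concentrate near 0 and 1 — and shared across classes. Planted markers shift
their class's mean by exactly the effect size (default 0.6, the scale of
the separations the real panels show): the direction is away from the
nearer boundary and the marker's baseline is rescaled into the sub-interval
where the shift fits, so the planted gap never loses magnitude to the
[0, 1] bounds and the recorded orientation is exact. Measurement noise is
additive Gaussian (default sd 0.03, array-scale replicate noise), clipped
to [0, 1]; additive noise keeps mixtures exactly linear so recovery targets
are well-posed, and a mean/sd-matched Beta noise model is available for
robustness checks. Mixtures are `profiles @ fractions + noise` with
fraction vectors on the simplex (uniform Dirichlet draws available) —
the equal-DNA-per-cell linear-mixing approximation. Identifiability is
checked by construction (profile matrix restricted to markers has full
column rank). Everything is bit-reproducible for a fixed seed.

What the generator does *not* emulate: probe-type chemistry biases, batch
effects, correlated probes, cell-line-specific baselines, and the
discrepancy between directed-differentiation and embryoid-body methylation
dynamics. Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated noise model, not performance on any particular
real dataset.

## Problem sizes and numerical choices

Default test/validation workloads are sized for interactive runs: 100
seeded selection runs at 1,000 probes × 40 samples, 100-mixture recovery
panels at 12 markers, 100 null differential-methylation runs at 2,000
probes × 12 samples — each completes in seconds while leaving the
stochastic margins far from their thresholds. NNLS correctness is checked
against a brute-force 0.01-resolution simplex grid search on exact
mixtures, where the two-grid-step tolerance (0.02 per coordinate) isolates
solver disagreement from quantization. Floating-point ties in rankings are
always broken by probe ID; variance estimators are unbiased (ddof=1)
throughout; file round-trips preserve six decimals.

## Known limitations

* The selection criterion is a declared stand-in for the CimpleG
  procedure; rankings agree in spirit (difference vs within-variance) but
  not necessarily probe-for-probe.
* Germ-layer orientations ship unverified (see above) and small panels are
  inherently sensitive to single-CpG outliers.
* The moderated test assumes exchangeable per-probe variances around a
  common prior; strong variance heterogeneity with few probes weakens the
  moderation.
* Deconvolution assumes the reference classes span the sample; cell types
  outside the vocabulary load onto the nearest profiles.
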