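# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `rhythmage`.

## Cosinor rhythmometry

**Model.** Single-component cosinor with a fixed period τ (default 24 h,
configurable; no period scanning, no multi-harmonic fits, no detrending
across multi-day collections). The cosine is linearised to
`y = M + b_c·cos(ωt) + b_s·sin(ωt)` with `ω = 2π/τ` and fit by OLS;
`A = √(b_c² + b_s²)`, `φ = (τ/2π)·atan2(b_s, b_c) mod τ`. The acrophase is
reported as hour-of-day of the fitted peak in `[0, 24)`, with the nadir at
`φ + τ/2 mod τ`. Multi-day collections enter with their times wrapped
modulo τ, which is equivalent for a fixed-period fit.

**Zero-amplitude test.** Partial F-test of the cos/sin pair,
`F = ((RSS₀ − RSS₁)/2)/(RSS₁/(n − 3))` against `F(2, n−3)` with RSS₀ from
the intercept-only model. This is the classical single-component cosinor
test; it is exact under i.i.d. Gaussian errors and its calibration is
verified by simulation (2000 null replicates at n = 24: KS uniformity and
binomial type-I bounds, see `tests/test_acceptance.py`).

**Degenerate inputs.** Fewer than 4 observations or times that coincide
modulo τ are design errors. A constant series is reported with `A = 0,
p = 1`; a zero-residual fit with non-zero amplitude with `p = 0`
(threshold: RSS₁ ≤ 1e−12·max(RSS₀, 1)/n).

**Combined multi-subject model.** One fixed-effects linear model with
subject × (1, cos, sin) interactions — 3m parameters for m subjects — and
per-subject-intercepts-only null; joint zero-amplitude `F(2m, n−3m)`.
A fixed-effects rather than mixed model is used because the target designs
have ~3 subjects, far too few to estimate variance components. With m = 1
the fit reduces exactly to the single-series cosinor (the top-level
MESOR/amplitude are per-subject means and the acrophase their circular
mean, so the reduction is identity).

**Genome-wide screen.** Per-CpG cosinor p-values computed vectorised from
one shared design matrix; the significant set is taken at *unadjusted*
p < α (α = 0.05 default), the convention for oscillating-site counts.
Clock-level analyses additionally report Bonferroni adjustment across the
number of clocks (`p_adj = min(1, m·p)`).

## Clock engine

Three predictor families: linear (`g⁻¹(intercept + Σ wᵢβᵢ)` with `g` the
identity or the piecewise Horvath age transform
`F(x) = log(x+1) − log(a+1)` for `x ≤ a`, `(x−a)/(a+1)` otherwise,
`a = 20` by default), average (mean beta over the clock set), and rate
(per-site estimated cumulative divisions
`(βᵢ − β0ᵢ)/(δᵢ(1 − β0ᵢ))`, floored at 0 per site and averaged). The rate
form is one standard reading of division-rate estimators; users loading
real published parameter sets should validate against the original
derivations. Betas are validated to [0, 1] with 1e−9 tolerance.

Missing clock CpGs: default policy is `error`; `drop` omits missing sites
(average/rate renormalise by averaging over present sites; the linear
family simply omits the terms — no weight renormalisation, since linear
weights are not exchangeable); `impute` substitutes 0.5. The missing count
is always reported.

Only toy/demo coefficient files ship with the package; published
coefficient sets are loadable from the documented CSV format but are not
redistributed.

## Deconvolution

Discriminating sites are chosen per cell type by the gap between that
type's reference beta and the mean of the other types, split evenly
between hyper- and hypo-methylated sites. Proportions solve
`min‖Rw − β‖₂, w ≥ 0, Σw = 1` — the simplex constraint is enforced by the
solver, not by post-hoc normalisation. The solver is an NNLS warm start
(sum constraint as a heavily weighted row) polished by SLSQP with
`ftol = 1e−16`; on well-conditioned panels it agrees with an exhaustive
simplex grid search at step 0.001 and recovers noiseless mixtures to
≤ 1e−6. The equality constraint reflects panels assumed to span the
sample; `sum_to_one=False` relaxes it to `Σw ≤ 1`. Rank-deficient
reference submatrices are rejected with advice to select more sites.

## Cell-count adjustment and contrasts

Intrinsic age residuals: OLS of epigenetic age on
`[1, chronological age, selected proportions]`. The default covariate set
is all estimated cell types minus the one with the largest mean
proportion — including the full simplex is exactly collinear with the
intercept and is rejected with an instructive error. Constant covariates
(chronological age in a single-subject series; proportions in purified
fractions) are dropped automatically with a log notice, which also makes
the purified-cell-fraction case well-defined: there adjustment cannot and
does not remove an intracellular oscillation. Tests are two-sided at
α = 0.05, with Bonferroni across clocks where several clocks are
contrasted. The paired two-timepoint contrast is a paired Student's t on
per-donor differences (default times 12.75 h and 16.25 h); all-zero
differences give `t = 0, p = 1`, zero within-pair variance with non-zero
mean gives `p ≈ 0`.

## Synthetic circadian methylome generator

**What it emulates.** (i) Whole-blood betas as convex mixtures of
cell-type reference methylomes; (ii) 24-h oscillation of the mixture
proportions with antiphasic subtypes (NK peaking at noon, B/CD4+ T at
midnight in the default schedule, amplitudes 0.04–0.05 on the proportion
scale — the magnitude of circadian leukocyte-count variation); (iii) a
minority of CpGs with *intracellular* oscillation, added to designated
cell-type profiles before mixing (default fraction 5%, beta amplitude
0.05); (iv) age-trend CpGs with ±0.002 beta/year slopes; (v) measurement
noise, Gaussian on the logit scale (default sd 0.05, i.e. ≲ 0.0125 beta
units at β = 0.5), back-transformed and clipped to [1e−6, 1−1e−6]. The
logit-normal choice respects the [0, 1] support and mimics the shrinking
variance of array measurements near 0 and 1.

**Proportion schedule.** Truncated-cosine-then-renormalise: raw
proportions `base + amp·cos(ω(t − acro))` are clipped at 0 (with a
warning) and divided by their sum, guaranteeing simplex validity for any
schedule; a softmax parameterisation was rejected because it would distort
the stated base proportions. Schedules require `amp ≤ base` so clipping is
a safety net, not the mechanism.

**Reference panels.** Each cell type gets planted marker CpGs, half
hyper- and half hypo-methylated in that type versus the rest (uniform on
[0.85, 0.98] vs [0.02, 0.10]); remaining CpGs are drawn from a bimodal
Beta mixture shared across types with per-type jitter of sd 0.01. The
two-sided markers make the site-selection example exact and the mixture
identifiable.

**Designs.** The default design is one subject sampled every 3 h for 72 h
(24 samples), a dense single-donor circadian collection; the multi-subject
variant is three subjects sampled every 3 h over 24 h (9 points each).
Default residual neutrophil fraction in the neutrophil-depleted schedule
is 0.15 (exposed as a knob, realistically 10–20%).

**Toy clocks.** Linear toy clocks solve min-norm least squares so each
pure cell type maps exactly to a chosen target age (default pattern: NK
older than the mixture, B and CD4+ T younger); rate clocks are built by
NNLS with ground state 0 and are exact when the non-negative fit is; the
average family uses greedy site selection and is approximate by nature
(an average of betas cannot hit arbitrary targets). Seeds fix all outputs
bit-for-bit; sub-generators derive from the study seed by fixed offsets.

**What it does not emulate.** No probe chemistry (Type I/II), no batch or
chip effects, no IDAT-level intensities, no realistic genome-wide
correlation structure between CpGs, no inter-individual variation in
reference profiles. Passing tests therefore demonstrate correctness of
the estimators under the stated generative model, not performance on any
particular array dataset.

## Experiment problem sizes

The seeded experiment battery (`rhythmage.experiments`) uses deliberately
compact problems — 300–1000 CpGs, 24–50 samples, 40–200 replicates — which
gives the mechanism experiments ≥ 5× signal-to-noise margins while keeping
the full battery under a minute on one CPU. The mechanism experiment
plants its intracellular oscillators on clock CpGs *disjoint* from the
deconvolution marker sites: oscillators on marker sites would masquerade
as composition change and be absorbed by the adjustment, which is itself a
caveat worth knowing when interpreting real intrinsic-age corrections.

In the multi-subject recovery experiment at amplitude = 3× noise sd and 9
points per subject, normal theory puts the acrophase standard error at
≈ 0.6 h, so "all three subjects within 1 h" holds in ≈ 74% of replicates;
the corresponding test asserts the replicate rate against its 99.9% lower
binomial bound (0.55) together with a median-error bound, rather than a
single-draw assertion.

## Known limitations

* Cosinor p-values on adjusted residuals reuse the nominal `F(2, n−3)`
  reference without accounting for the degrees of freedom consumed by the
  adjustment regression; with 24 samples and ~6 covariates this is mildly
  anti-conservative, and the calibration experiments bound the effect.
* The average-family toy clock is approximate (see above).
* The deconvolution solver is iterative (SLSQP); its 1e−6 agreement with
  the exact QP solution is verified on well-conditioned panels, not
  guaranteed for pathological references.
* Percent overlaps are reported rounded half-up to one decimal with full
  precision retained internally.
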