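# Methods

## The estimation problem

*Pennatula rubra* colonies anchor in soft sediment by a peduncle of length
`lp`; only the rachis (length `lr = lt − lp`, where `lt` is total length)
and its pinnately arranged polyp leaves are visible to a camera. Video
surveys therefore cannot measure length or weight directly, but the number
of polyp leaves `n` can be counted from imagery and is tightly linked to
colony size. The package's models predict physical quantities from `n`:

| model | form | predictor | default coefficients |
|---|---|---|---|
| rachis length (mm) | `a·n + b` | max-side count | `2.6, −1.1` |
| total length (mm) | `a·n + b` | max-side count | `5.8, 8.1` |
| fresh weight (g) | cubic in `n` | mean-side count | `−0.0013, 0.076, −1.170, 5.342` |
| fresh weight, refined (g) | cubic in `n` + `0.039·lr` term | mean-side count + rachis | `2.28e−4, −0.023, 0.826, 0.039, −9.182` |
| dry weight (g) | cubic in fresh weight | measured `wf` | `0.062, −0.412, 1.134, −0.416` |

Two side-count conventions coexist deliberately: colony *size* scales with
the longer, undamaged side (max of the two counts), while *weight* reflects
total polyp tissue (mean of the two counts, possibly half-integral).

The cubic form for weight follows from a simple shape argument: if the 2-D
outline of a colony is enveloped by a second-order curve along the rachis,
the enclosed area — and hence the weight — integrates to a third-degree
polynomial in rachis length, and so (by the linear size law) in `n`.

**A note on the fresh-weight leading coefficient.** The cubic is sometimes
quoted with leading coefficient −0.013, which yields ≈ −122 g for a typical
22-leaf colony — physically impossible and inconsistent with the refined
surface model (≈ 2.47 g at `n = 22`, `lr = 56.1` mm) and with observed mean
weights near 2.4 g. With −0.0013 the cubic gives 2.54 g at `n = 22`,
consistent with everything else; the package uses the sign-corrected value
as its default and treats all coefficients as configuration, never
constants.

**Validity threshold.** Too few small colonies support the weight cubic, so
predictions at `n ≤ 15` return "not applicable" rather than a number; the
biomass pipeline substitutes an exact 0 there (small colonies contribute
negligibly to field biomass) and reports the zeroed fraction so users can
judge the approximation.

## Fitting and error conventions

Fits are ordinary least squares in the stated basis (the fitting criterion
is absolute squared error), while goodness of fit is reported as the RMS
*relative* error `e = sqrt((1/M) Σ ((x̂ᵢ − xᵢ)/xᵢ)²)` — the field's metric,
since survey applications care about proportional accuracy across sizes.
Both are computed; they are not interchangeable, and on data whose true
weight law depends only on `n` the richer surface model can show a slightly
*larger* relative error than the cubic even though its RSS is necessarily
no worse (the nested-model guarantee the tests assert). The cubic
fresh-weight model's stored error is evaluated only over training pairs
above the validity threshold, mirroring how the model is used. Rank-deficient
designs raise an explicit error — notably the surface basis
`{n³, n², n, lr, 1}` when rachis length is an exact linear function of `n`.

Linear fits expose the OLS slope standard error and a t-based confidence
interval, used by the parameter-recovery checks.

## Moment statistics

Leaf-count samples are summarised by four moments with small-sample bias
corrections: corrected SD `σ` (divisor M−1), uncorrected SD `σ′` (divisor
M), skewness `G1 = [√(M(M−1))/(M−2)] · m₃/σ′³`, and *non-excess* kurtosis
`k = (M−1)/((M−2)(M−3)) · [(M+1)·m₄/σ′⁴ − 3(M−1)] + 3` (a large normal
sample gives k ≈ 3). Degenerate samples report shape moments as undefined
rather than infinite. Survey comparisons report `|Δmean|/mean_ref` and
`|Δskew|/|skew_ref|` with the ROV sample as reference, plus shared-bin
integer histograms.

## The synthetic population generator

No raw colony measurements are deposited for dense *P. rubra* fields, so the
generator emulates the study conditions and makes every downstream stage
testable. Defaults:

* **leaf-count law**: max-side counts with mean 22.0, SD 3.7, skewness −1.3,
  kurtosis 5.6 (the trawl-sample calibration targets). No named distribution
  carries exactly these four moments, so a Fleishman cubic polynomial of a
  standard normal is used, rounded to integers and clamped at ≥ 4 leaves
  (the clamp value is a package guess; no minimum count is documented).
  Two numerical refinements matter:
  - rounding and the left-tail clamp pull the shape moments toward zero
    (≈ −6% skewness, −10% kurtosis uncompensated), so the transform
    parameters are pre-adjusted by a damped Newton iteration on the exact
    (quadrature-evaluated) moments of the discretized variable;
  - normal deviates are drawn by stratified inversion (one uniform per
    equal-probability stratum, randomly permuted), which preserves the exact
    marginal law and full seedability while concentrating the four *sample*
    moments well inside 5% of the targets for m ≥ 5000 — something i.i.d.
    sampling cannot guarantee per seed, kurtosis being tail-dominated.
* **lengths**: rachis follows the linear law with multiplicative Gaussian
  noise at relative SD 0.118; the peduncle line is the difference of the
  total- and rachis-length laws with relative SD 0.106; draws are resampled
  until positive; total = rachis + peduncle by construction.
* **weights**: fresh weight is the cubic of the mean-side count times a
  mean-one lognormal factor with RMS relative deviation 0.46 (σ² = ln(1+r²)),
  floored at 0.01 g — the printed cubic is non-positive around 10–12 leaves,
  which the generator logs as a calibration warning; dry weight is the cubic
  of fresh weight times a 0.192-level lognormal factor, kept strictly inside
  (0, fresh). Noise levels are the reported model errors, placed
  multiplicatively because those errors are relative; lognormal keeps
  weights positive.
* **side asymmetry**: with probability 0.1 one side (chosen at random) loses
  1–3 leaves — mechanical damage and predation are occasional, so a ~10%
  incidence is assumed; no measured rate exists.
* **trawl selectivity**: each colony is retained with logistic probability
  `expit(0.8·(n − 15))`. L50 = 15 leaves aligns the net's knife-edge with the
  weight model's validity threshold; steepness 0.8/leaf gives a soft edge
  (92% retention at n = 18). Infinite steepness degenerates to the exact
  rule `n > L50`.
* **ROV miss model**: the first and last polyp leaves are small and easily
  missed on video, so each of the two terminal leaves is independently
  uncounted with probability 0.8 — calibrated once so the ROV-observed mean
  is ≈ 90% of the post-selectivity trawl-sample mean at large m,
  reproducing the ~10% mean shift seen between the two survey methods.

All stochastic operations consume one explicitly passed
`numpy.random.Generator`; identical configuration and seed give bit-identical
populations, tables and reports.

What the generator does *not* emulate: spatial structure of the field,
contraction/water-content dynamics, count-dependent observation difficulty,
any real dependence of weight on rachis length beyond the leaf count, or
correlated measurement errors. Passing tests therefore demonstrate the
correctness and calibration of the estimation chain, not the field accuracy
of the models on new populations.

## The pipeline

A full run generates (or loads) the measured sample, fits all model
families, summarises both leaf-count distributions, predicts per-colony
weights for the ROV set, and scales to total biomass
`ŵ_tot = ŵ_mean · δ · S`. Density δ may be supplied directly or derived as
trawl count / swept area (both paths are labelled in the report). Defaults
mirror the study conditions: population 4000, trawl sample 168 colonies,
ROV set 207, area 41,000 m², selectivity enabled. The dry-weight model is
fitted on a 54-colony calibration subset chosen deterministically as evenly
spaced fresh-weight order statistics, restricted to colonies with fresh
weight ≥ 1 g and dry weight ≥ 0.01 g: near the 0.01 g balance resolution
the relative-error metric measures the instrument, not the biology.

With selectivity on, the validation error (ROV-predicted mean vs
trawl-measured mean weight) is negative in essentially every replicate,
at ≈ −20% under default conditions: the catch over-represents heavy
colonies, exactly the mechanism proposed for the field observation that
imaging-based weight prediction under-reads trawl-measured means by ~22%.

## Numerical choices and limitations

* Moment feasibility requires kurtosis > skewness² + 1; infeasible targets
  (and Fleishman systems with no real solution) fail before sampling.
* The rounding/clamping compensation falls back to the uncompensated
  transform, with a warning, if its Newton iteration leaves the feasible
  region (it converges in a handful of iterations for the defaults); it is
  skipped entirely when the target SD < 0.5, where rounding dominates and
  the law degenerates to a point mass.
* Negative length or weight predictions (model extrapolation) warn and are
  clamped to zero where downstream sums require non-negativity.
* Problem sizes in tests and the acceptance script — 20,000 counts for
  calibration, 168/207-colony surveys, 100-replicate direction checks —
  match the study's scale and run in seconds.
* Bootstrap uncertainty on `ŵ_tot` is a documented extension, not
  implemented: the procedure produces a point estimate.
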