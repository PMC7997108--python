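# Methods

This note documents the statistical model, the processing chain, the
synthetic data generator and the numerical choices behind `sersils`,
in the spirit of the methods documentation of mature analysis packages.

## Study design being analyzed

A collaborative trial crosses SERS *methods* (substrate form × metal ×
excitation; six by default: cAg@532, cAg@785, cAu@785, sAg@532,
sAg@785, sAu@785) with participating laboratories. Each laboratory
measures a calibration series (levels `C0…C8`, known concentrations)
and a test series (levels `X1…X5`, treated as unknowns), with 3
replicates per sample for colloidal substrates (one per colloid batch)
and 9 for solid substrates (3 spots × 3 substrates). Each laboratory ×
method combination is one *dataset*; the dataset is the unit of
acceptance/rejection, and accepted datasets contribute one prediction
per test level to the per-method residual pool.

## Preprocessing chain

Order is fixed: smoothing → down-sampling → range selection → baseline
correction → EMSC normalization.

* **Smoothing**: Savitzky–Golay, window 9 points, polynomial order 2.
* **Resampling**: linear interpolation onto a 1 cm⁻¹ grid over
  400–1800 cm⁻¹ (no extrapolation).
* **Range**: closed interval 400–1800 cm⁻¹.
* **Baseline**: asymmetrically reweighted penalized least squares
  (Whittaker smoother with second-difference penalty, λ = 10⁶ by
  default). Weights follow the arPLS scheme: residuals below the
  current baseline estimate define a noise scale, and points far above
  it get logistic weights → 0. Two refinements matter for
  quantification:
  1. *Shared weight pattern.* Within a dataset the converged weight
     pattern is estimated once, on the pointwise median spectrum
     (intensity-normalized and quantized to float32 so that datasets
     differing only in gain get bit-identical patterns), and the
     resulting fixed weighted smoother is applied to every spectrum.
     With a fixed pattern, baseline removal is a *linear* operator, so
     band areas remain exactly affine in analyte amount; per-spectrum
     reweighting would re-introduce an amplitude-dependent baseline
     bias under the band (measured at ~0.3% of the band area for
     classic fixed-p ALS, enough to distort low-concentration
     predictions by several percent).
  2. *Noise-scale floor.* The logistic slope is bounded by flooring the
     noise scale at 10⁻⁶ of the spectrum maximum; otherwise the weights
     of noise-free spectra become chaotically sensitive to rounding.
  Classic fixed-p ALS (λ = 10⁵, p = 0.01) and iterative-polynomial
  baselines remain available via `PreprocessConfig.baseline_method`.
* **EMSC**: each spectrum is modeled as
  `s ≈ b·ref + Σⱼ hⱼ·Rⱼ + Σₖ aₖ·Pₖ` with Legendre polynomials `Pₖ`
  (degree 2 by default) and corrected as `(s − Σ aₖPₖ)/b`. The
  reference is the pointwise median of the dataset's own
  baseline-corrected calibration spectra, normalized to unit mean on
  the fit region — per dataset, so laboratories stay independent.
  Two safeguards keep the correction quantification-safe:
  * the analyte neighborhood (660–800 cm⁻¹ by default) is excluded
    from the coefficient fit (the correction is still applied to the
    full axis), and
  * a data-driven analyte signature — the difference between the
    highest- and lowest-level calibration medians — is included as a
    *retained* component `R`: it participates in the fit, so analyte
    variation cannot leak into `b`, but it is not subtracted.
  Without these, a normalization against the dataset's own median
  absorbs the analyte amplitude into `b` and flattens the calibration
  (in the limiting case of spectra that differ only in band area, the
  corrected spectra would all collapse onto the reference).

Preprocessing never alters metadata, and all stages are logged in the
dataset provenance.

## Calibration and suitability

The response is the trapezoidal integral over the closed window
715–750 cm⁻¹. Replicate areas are averaged into one response per
standard before the fit (per-replicate fitting is available via
`replicate_handling="all"`; the default is documented, the choice was
genuinely open). Calibration is inverse, unweighted OLS of
concentration on area — predictions come directly from the line, and
the observed heteroscedasticity of real SERS responses is reported,
not modeled. Suitability requires `r² ≥ 0.6` and overall-regression
F-test `p ≤ 0.01` (for a straight line the F statistic equals the
squared slope t). Predictions are never clipped: values outside the
calibration range or below zero are flagged, not altered.

Note that with only 5 calibration points, `r² = 0.6` corresponds to
F = 4.5 and p ≈ 0.12, so near the r² boundary the p-value condition
dominates the gate; from ~10 points upward the two conditions flip
together at r² ≈ 0.6.

## Figures of merit

For pooled residuals `e`, `BIAS = mean(e)`, `RMSEP = sqrt(mean(e²))`,
`SEP = sqrt(Σ(e−BIAS)²/(n−1))`. The denominators make
`RMSEP² = BIAS² + SEP²·(n−1)/n` an exact identity, verified to 1e-12
relative on every computed FoM set. The n−1 convention for SEP is
supported by published method tables in which SEP exceeds RMSEP —
arithmetically impossible if both shared the n denominator.

Residuals are normalized by the *calibration* reference range before
pooling (laboratories may calibrate over different ranges); the
residual *plots* are rescaled by the *test-set* reference range — the
two ranges are carried separately. The bias t-test runs on the
normalized pooled residuals (equivalent to the raw-scale test whenever
a method's laboratories share one range). Quartiles use linear
interpolation between order statistics; 1.5 × IQR fences flag outliers
that remain in all FoMs. Report tables print FoMs as whole percent and
workflow percentages to one decimal, both rounded half-up.

## Synthetic generator

Per spectrum:

    I(ν) = g·[ B(ν) + M(ν) + (1 + δ)·A(c)·V(ν) ] + ε(ν)

* `V`: unit-area 50/50 pseudo-Voigt, center 733 cm⁻¹, FWHM 14 cm⁻¹.
* `A(c) = amp·c·K/(K+c)`: amp = 30 counts·cm⁻¹/µM; K = 400 µM by
  default gives the mild saturation curvature seen in real calibration
  curves (K = ∞ for a linear response).
* `M`: fixed concentration-independent "matrix" bands (citrate-like
  background features at 960/1090/1395/1580 cm⁻¹). Real SERS spectra
  always carry such invariant structure; it is what makes the EMSC
  scale identifiable. A generator without it would make multiplicative
  normalization against the dataset median degenerate.
* `B`: smooth fluorescence baseline, quadratic in the scaled axis,
  (250, −120, 60) counts by default.
* `g ~ N(1, 0.15)`: laboratory gain. It multiplies the whole optical
  signal (fluorescence, matrix and analyte alike), as a
  throughput/detector factor does — this is what EMSC removes.
* `δ ~ N(0, 0.25)` per replicate, *analyte band only*: SERS enhancement
  fluctuation (adsorption, hot-spot statistics). Deliberately not
  shared with the matrix bands, so it is invisible to EMSC and drives
  the residual spread, as replicate variability does in practice.
* `ε ~ N(0, 2 + 0.01·A(c))` per point: detector noise with a
  concentration-proportional component, reproducing the increase of
  prediction spread with concentration.
* Optional contaminant bands (inside and outside the analyte window,
  parafilm-like) added to all spectra of a dataset with configurable
  probability, to exercise the integrity screen.

Concentrations default to nine log-spaced calibration levels over
1–100 µM and five log-spaced test levels over 2–80 µM (inside the
calibration range; the actual study concentrations are not published in
the main text, and the FoMs are range-normalized, so the scale choice
is immaterial). Each dataset draws from a stream keyed by (seed,
method index, lab index): generation is bit-reproducible and
order-independent. A truth record (gains, per-spectrum band areas,
test concentrations) accompanies every collection.

At the default study scale (6 methods × 8 labs) the generator emits 48
datasets / 4032 spectra; a full pipeline pass takes a few seconds.

**What the generator does not emulate:** wavenumber miscalibration
between instruments, cosmic-ray spikes, photodegradation drift,
laboratory-specific background *shapes* (only a common shape with
laboratory gain), non-Gaussian outlier processes, and heteroscedastic
structure beyond the proportional-noise term. Passing recovery tests on
synthetic data therefore validates the numerics and the statistical
conventions of the pipeline, not its robustness to every artifact of
measured spectra.

## Numerical choices

* Whittaker systems are solved with a symmetric banded Cholesky solver
  (`scipy.linalg.solveh_banded`); ALS iterations stop when the weight
  pattern is stable, arPLS when the weight vector changes by < 1e-6.
* EMSC uses `numpy.linalg.lstsq`; `|b|` below 1e-9 of the
  spectrum/reference scale ratio raises a degeneracy error (e.g. a
  constant spectrum against a structured reference).
* Band integration requires the axis to cover the closed window; grid
  points inside the window are integrated trapezoidally.
* The calibration fit uses closed-form simple-regression formulas with
  the F p-value from `scipy.stats`; the test suite cross-checks slope,
  r² and F against statsmodels OLS as an independent route.
* A zero-variance residual vector with nonzero mean yields an infinite
  bias t statistic, flagged significant.
* Half-up rounding goes through `decimal.Decimal` (banker's rounding
  would bias the printed percentages).

## Problem sizes used in the shipped checks

The automated checks run the full study scale for the noise-free
recovery (48 datasets, 4032 spectra, exact to ~1e-14), 1000 random
residual vectors for the decomposition identity, 100 random draws for
the EMSC oracle, 1000 pure-noise calibrations for the suitability
gate, and 10⁴ replicates for the bias-test type-I rate; estimator
recovery of an injected 12% normalized SEP uses 8 laboratories × 5
test levels per method, judged at 3 Monte-Carlo standard errors.

## Known limitations

* Nonlinear calibration models are out of scope by design; saturating
  synthetic responses are still fit with a straight line, exactly as
  the protocol prescribes, and show up as bias at the range ends.
* The contaminant screen is a correlation test against user-supplied
  reference spectra (threshold 0.9) — a reproducible surrogate for the
  expert inspection used in practice; it cannot discover contaminants
  it has never been shown. The dataset-level rejection rule (> 50% of
  spectra flagged) is a package convention.
* ISO 5725 repeatability/reproducibility variance components (s_r/s_R
  ANOVA) are not computed; the pipeline pools residuals instead.
* Limits of detection/quantification and internal-standard
  normalization are not implemented.
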