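# Methods

This note documents the models and numerical choices behind `ftirstress`,
what the synthetic generator does and does not emulate, and the design
decisions taken where the published description of the assay left the
procedure open.

## Spectral preprocessing

**Grid.** The working grid is 4000 → 400 cm⁻¹ stored descending. The
default spacing is 2 cm⁻¹ (1801 points): the assay's stated 4 cm⁻¹
*resolution* is an interferometric setting, not an export point spacing,
and 2 cm⁻¹ is a typical export density. Spacing is configurable; every
point count used in SI normalization is derived from the actual grid,
never hard-coded.

**Quality test.** The assay screens spectra by signal-to-noise in the
2100–1900 cm⁻¹ interval, where cell spectra carry no bands. The published
description names only the threshold (4000) and the window, not the
formula; we define SNR = (max − min of the full spectrum) / RMS of
residuals after a linear detrend of the window. This definition is
computable on any spectrum, monotone in the noise level, and returns an
infinite sentinel (unconditional pass) when the window is noise-free.
Failing spectra are excluded with a logged warning, not a hard error, the
way an operator would discard a bad replicate. Threshold and window are
config options.

**Rubberband baseline.** The baseline is the lower convex hull of the
(wavenumber, absorbance) points — the shape of a rubber band stretched
beneath the spectrum — evaluated by linear interpolation between hull
vertices and subtracted. The "64 points" parameter is interpreted as a cap
on the number of hull support points: when the hull has ≤ 64 vertices (the
usual case for fingerprint-like spectra) this is exactly the plain lower
hull, the corrected spectrum is non-negative and touches zero at ≥ 2
points, and the operation is idempotent. If the hull has more vertices
(e.g. a broadly convex spectrum), vertices are pruned greedily by least
added area; the pruned baseline can then exceed the data by a small amount
at removed vertices, which is the price of honouring the support-point
cap. The hull is computed by Andrew's monotone chain; tests check it
against an O(n²)-style supporting-line oracle.

**Vector normalization.** Mean-centring followed by scaling to unit
Euclidean norm (the common OPUS-style convention); plain L2 scaling is
available via `center=False`. Output is mean-0, norm-1, and the operation
is idempotent.

**Atmospheric compensation** is deliberately not implemented: it is
instrument-specific, and the synthetic spectra contain no CO₂ / water
vapour bands. The pipeline structure leaves it as an implicit no-op
between acquisition and the quality test.

## Stress indexes

SI_w = ED_w / (n_total / n_w), where ED_w is the Euclidean distance between
the stressed and control intensity vectors restricted to window w, n_w the
window's point count and n_total the point count of the **whole** recorded
spectrum (not the union of windows). For the whole-spectrum window the
divisor is 1 and the SI is the plain distance (GSI). Window bounds are
inclusive at both ends; adjacent windows therefore share their boundary
point (1500, 1200, 900 cm⁻¹), matching the printed interval definitions at
a cost of ≤ 1 point per window.

Distances are computed between replicate-averaged stressed and control
spectra. Replicate-level SIs are retained for two purposes: (i) the
reported spread `si_sd` is the standard deviation of index-paired
replicate SIs (stressed replicate *i* vs control replicate *i*), which is
exactly zero for a control compared with itself; (ii) calibration fitting
uses per-replicate points — each stressed replicate against the control
mean, with control replicates contributing near-zero-SI points at RC = 0.
Averaging SIs per replicate instead of averaging spectra first would
differ slightly under noise; spectra-first is the default because the
assay averages conditions, and the replicate-level alternative is what the
fitting path exposes.

## Dose models

**Primary models** RC = a·SI² + b·SI + c are ordinary least-squares
quadratics with R² = 1 − SS_res/SS_tot on the fitted points. Fits use
replicate-level points: with one averaged point per dose level a
three-level fit would be saturated (R² ≡ 1), which contradicts the
published R² values below 1; replicate-level fitting is therefore the
default, with ≥ 3 distinct SI values required.

**General models** are weight-normalized combinations over W1–W4 and
optionally the whole spectrum. Weight strategies: `manual` (verbatim),
`best_r2` (all weight on the best-R² window), and `grid` — exhaustive
search over the simplex in steps of 0.1 minimizing the summed squared
prediction error across dose levels, with ties broken toward fewer nonzero
weights and then toward higher-R² windows. The grid search is the
constructive reading of "weights assigned according to the R² values"; it
reproduces one-hot and 0.1/0.1/0.8-style optima exactly when they are
optimal at 0.1 resolution.

**Classification.** CRC = ⌊RC/25 + ½⌋, i.e. RC/25 rounded half-up, with
negative predictions logged and classed 0. The published formula
("RC/25 + ½, rounded to the nearest integer on a 1–2–4 quartile scale") is
ambiguous; round-half-up of RC/25 is the unique standard rounding
consistent with 23 of the 24 published quartile labels, including the
cells that plain nearest-integer rounding of RC/25 + ½ would misclass. The
24th label is internally inconsistent in the source table itself: the
resistant strain's whole-spectrum prediction 80.84 is printed as class 4,
yet ⌊80.84/25 + ½⌋ = 3, and no monotone rounding rule reproduces both that
cell and the others (the value 80.84 is confirmed by the correlation and
t-test printed alongside it). The desk check (`verify_table2`) reports the
cell as non-matching rather than special-casing it.

**Evaluation.** Pearson correlation and a two-sample, pooled-variance,
two-sided Student t-test between the predicted and expected dose triples.
The two-sample form is used because it reproduces every published p-value
at 2 dp, whereas a paired test does not (e.g. it gives ≈ 0.82 where 0.97
is published). Predictions enter correlation and t-test unclamped;
clamping happens only inside classification.

**Viability.** M = (1 − Cv/Ct) × 100, clamped to [0, 100] with the raw
value retained for diagnostics; replicate counts are averaged before the
ratio and the standard error of M comes from the delta method. Growth
during the assay (Cv > Ct) is clamped to 0 with a logged note.

## Synthetic experiments

The generator emulates the statistical structure the analysis assumes:

- **Control fingerprints**: sums of Gaussian bands at standard yeast
  assignments (CH stretches, amide I/II, mixed-region and phosphate bands,
  carbohydrate C–O, a small typing-region band), a gentle smooth baseline
  drift, and i.i.d. detector noise (σ = 5 × 10⁻⁵ absorbance, giving
  SNR ≳ 20 000 — comfortably past the 4000 quality cut).
- **Replicate variability**: multiplicative band-amplitude jitter between
  replicates (biological/sampling variation, smooth in wavenumber). This
  is deliberately separate from detector noise: a single i.i.d. noise
  source cannot both pass the SNR > 4000 quality test (which caps
  per-point noise near 2.5 × 10⁻⁴) and produce the published
  between-replicate spectral variability of 2.5 × 10⁻² — the replicate
  variability of real cell spectra is dominated by sample-to-sample
  structure, not detector noise. The jitter scale (6% per band) was
  calibrated once so that the between-replicate GSI spread of the default
  configuration lands near the published value (measured ≈ 1.5–1.6 × 10⁻²,
  within the factor-2 band).
- **Dose response**: per strain, band amplitudes within each window are
  modulated with alternating sign, centers shift by a fraction of the band
  width and widths broaden, all scaled by the window's response strength
  times the saturating power law (RC/100)^γ with γ < 1. The alternating
  signs make the perturbation a *shape* change that vector normalization
  cannot cancel; the concave SI(RC) makes the inverse RC(SI) convex and
  well approximated by a quadratic over the tested range — the minimal
  structure under which the quadratic primary model is the right model.
  Response strengths were chosen so the assay operates at a realistic
  dynamic range (GSI at full dose ≈ 0.37–0.60 depending on strain, i.e.
  25–40× the replicate spread).
- **Archetypes**: the three default profiles mirror the published panel —
  resistant (low mortality, low response), intermediate (low mortality,
  highest response), sensitive (highest mortality, lowest response) — with
  mortality from a logistic survival curve normalized to the control and
  viable counts drawn Poisson around base_count × survival.

What the generator does **not** emulate: atmospheric CO₂/H₂O lines, Mie
scattering and instrument drift, strain-specific typing-region structure,
and any chemical identity of the individual inhibitors (the dose axis is
the abstract relative-concentration scale). Passing the synthetic recovery
tests therefore demonstrates the correctness and statistical behaviour of
the analysis chain under the assay's assumed structure, not the field
performance of the assay on real stillage.

A separate direct sampler (`quadratic_si_points`) draws (SI, RC)
calibration points exactly from a stated quadratic by root inversion; it
exists so coefficient recovery can be tested to 10⁻⁶ without the spectral
pipeline in between (the spectral route is validated instead by R² > 0.999
of noiseless fits and by held-out dose-class recovery). Quadratics with
negative curvature have a maximum reachable dose; the sampler raises if
asked for a dose beyond it, and such calibrations are tested on dose
ranges their inverse covers.

## Problem sizes and determinism

The default validation experiment uses 3 strains × 4 dose levels × 3
replicates on the 1801-point grid, the scale of the original design. The
held-out recovery study runs 100 seeded experiments with one extra
replicate each (~30 s on one CPU); reported match rates pool the 900
held-out (strain, level) predictions. Every stochastic path takes an
explicit seed or `numpy.random.Generator`; a fixed seed reproduces spectra,
counts and all serialized tables byte-for-byte (output floats are written
with 9 significant digits).

## Known limitations

- The published absolute SI scale is not reproduced: on mean-centred
  unit-norm spectra the GSI is bounded by 2, whereas the published
  calibration implies window SIs up to ≈ 3.6, so the original distances
  were evidently computed on a different intensity scaling. All structure
  of the method (normalization by point-count ratio, quadratic inversion,
  weighting, classification) is scale-covariant, so this affects only the
  numerical range of coefficients, not behaviour.
- The support-point cap of the rubberband correction can leave small
  negative residuals when it actually prunes (hulls with > 64 vertices);
  this does not occur for fingerprint-like spectra.
- `best_r2` and `grid` weighting are calibrated in-sample across three
  dose levels; no cross-validation or uncertainty on predicted RC is
  provided, matching the scope of the original assay.
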