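# Methods

## The geometric model

The RV cavity is idealized as a generalized cone: a basal cross-section
swept toward the apex under a linear scale factor
`s(z) = 1 − (1 − α)·z/L`, `z ∈ [0, L]`, `α ∈ (0, 1]`. The basal section is
a disc of radius `βD/2` (`β = 1 + p₀`) minus a rhombus with diagonals
`p₀D` (along the four-chamber x-axis) and `q₀D` (perpendicular), placed so
its +x vertex touches the circle. Two exact consequences drive everything
else:

* **Chord identity.** The cavity chord along the x-axis at the base is
  `(β − p₀)·D = D` for every admissible `(α, p₀, q₀)`. The "measured"
  four-chamber basal diameter therefore equals the model parameter `D`
  exactly, and the long-axis section is a trapezoid `(D, αD, L)`.
* **Volume coefficient.** `V = k·D²·L` with
  `k = (1 + α + α²)(πβ²/12 − p₀q₀/6)`.

The admissible region requires the rhombus to stay inscribed in the circle,
`1 + q₀² ≤ (1 + p₀)²`; crescent geometries where the bite exits the disc
are out of scope.

The proportions behind the clinical constant 1.21 are not uniquely
determined by the constant; this package fixes `α = 0.3`, `q₀ = 0.9` and
calibrates `p₀` (Brent root-bracketing on `[0, 3]` plus Newton polish) so
that `k = 1.21` to machine precision, giving `p₀ ≈ 0.970`. This family is
*one consistent realization*, not a reconstruction of the original
derivation: any statement tied to the specific `(α, q₀)` choice (e.g. the
apical width of the long-axis trapezoid) should be read as a property of
this phantom family only. Calibration to machine precision (rather than a
loose root tolerance) is deliberate: the formula-vs-geometry exactness
tests separate formula error from discretization error, and any residual
in `k` would contaminate that separation.

**Outflow tract.** The RVOT is modelled as a half-cylinder patch attached
outside the basal circle on the +y side over `z ∈ [0, 0.3·L]`, sized so it
contributes a prescribed fraction `f` of the *total* volume
(`V_total = k·D²·L / (1 − f)`). It never intersects the y = 0 measurement
plane, so four-chamber measurements — and hence the formula — see exactly
`1 − f` of the true volume. Only the volume share is anatomically
constrained (up to ~19% in adults); the patch's placement and shape are
modelling conveniences.

**Units.** cm for lengths, mL (= cm³) for volumes throughout. Point
membership uses a closed boundary (points on the surface belong to the
solid, the subtracted rhombus is open).

## Synthetic cohorts

`CohortConfig` defaults describe an adult CMR referral cohort:

| parameter | default | meaning |
|---|---|---|
| `dd_mean ± dd_sd` | 4.2 ± 0.6 cm | diastolic basal diameter |
| `ld_mean ± ld_sd` | 7.7 ± 1.1 cm | diastolic baso-apical length |
| `fd_mean ± fd_sd` | 0.167 ± 0.05 | fractional diameter shortening (→ Ds ≈ 3.5) |
| `fl_mean ± fl_sd` | 0.156 ± 0.05 | fractional length shortening (→ Ls ≈ 6.5) |
| `bsa_mean ± bsa_sd` | 1.99 ± 0.2 m² | body surface area (sampled directly) |
| `male_fraction` | 0.70 | sex ratio |
| `slice_thickness`, `pixel_size` | 0.8 cm, 0.1 cm | short-axis grid |
| `noise_sd` | 0.1 cm | observer noise per linear measurement |
| `rvot_f` | Uniform(0, 0.19) | RVOT volume fraction |
| `alpha_ed_mean`, `alpha_es_mean` | 0.16, 0.08 | true-taper means (see below) |
| `alpha_jitter_sd`, `q0_jitter_sd` | 0.03, 0.05 | per-subject shape jitter |
| observer-2 bias | +0.15 cm on diameters | systematic caliper placement |

Contraction is modelled through `(fD, fL)` rather than sampling systolic
dimensions marginally, so end-systole is correlated with end-diastole as in
physiology, and with identical ED/ES shapes and no RVOT the true EF is
exactly `100·(1 − (1−fD)²(1−fL))` (≈ 41.4% at the means). BSA is drawn
directly (its mean chosen so the mean EDV and EDV index are mutually
consistent); no height/weight model is attempted. Non-physical draws are
truncated at fixed floors with a logged warning, never resampled, so a seed
always maps to the same cohort; measurements are floored at 0.1 cm.

**The calibration-mismatch mechanism.** A fixed coefficient calibrated on
one modality does not transfer perfectly to another: in practice the
formula with k = 1.21 overestimates volumes relative to disk summation even
though it cannot see the outflow tract. The generator reproduces this by
drawing each subject's *true* shape around taper means below the
calibration family's α = 0.3 — `alpha_ed = 0.16` (true k ≈ 1.03) and
`alpha_es = 0.08` (true k ≈ 0.94), the systolic mismatch being stronger
because the contracted ventricle is more tapered. The net realistic-scenario
biases are then: formula volumes high (1.21/k_true beats the 1 − f RVOT
loss), formula EF low (ESV inflated proportionally more than EDV). These
means were chosen once from the target bias magnitudes (≈ +5% EDV, +16%
ESV); the ideal scenario (`CohortConfig.ideal()`) instead sets both means
to 0.3 with zero jitter, noise and RVOT, making every stage exact up to
rasterization error.

The observer-noise SD (0.1 cm) and observer-2 diameter bias (+0.15 cm) are
free calibration knobs of the generator, not clinically measured facts;
they produce intra-/interobserver ICCs and mean differences of realistic
magnitude.

**What the generator does not emulate:** real MR signal, contouring
ambiguity at the basal slices, papillary muscles and trabeculation,
breathing/motion artifacts, congenital geometries. Passing tests
demonstrate the estimator's behaviour *on the geometric model and its
stated bias mechanisms*, not segmentation performance on real images.

## Discretization

Short-axis masks sample point membership at pixel centres on the mid-plane
`z = (i + 0.5)·t` of each slice, `i = 0 … ceil(L/t) − 1` (mid-plane
sampling, no partial-volume averaging — matching thin-slice contouring
practice and keeping an analyzable error bound). A mid-plane beyond the
apex contributes an empty mask; the resulting ≤ half-slice apical deficit
is documented, not corrected. The basal slice is index 0 at the tricuspid
plane: synthetic stacks are generated already cropped at the base, which
abstracts away the clinical problem of identifying the basal slice.
Disk summation is the plain `Σ area·t` (no trapezoidal/Simpson end
corrections, matching the clinical method). At the clinical grid
(t = 8 mm, 1 mm pixels) the volume error on this family is ≤ 3% (typically
≈ 1%); at t = 1 mm / 0.5 mm pixels it is ≤ 0.5%. Error under refinement is
assessed sweep-wise (max/mean over phantoms): an individual coarse run can
beat its refined counterpart when apical and in-plane errors cancel by
chance.

Four-chamber measurements read the long-axis mask with the basal row's
column extent as diameter and the base-to-last-nonempty-row extent as
length, each accurate to one pixel.

## Statistics

* **Pearson r** with the t-transform p-value (n − 2 df), via scipy.
* **Bland–Altman**: differences taken `standard − formula`; limits
  `bias ± 1.96·SD` (SD with n − 1). p-values are reported, never used to
  gate anything; no multiple-testing correction is applied.
* **ROC/AUC**: Mann–Whitney concordance with ties counting ½; the standard
  error and normal 95% CI (clipped to [0, 1]) from the DeLong
  placement-value decomposition. Candidate cut-offs are the observed
  values; the criterion is `> c` for higher-is-positive markers and `≤ c`
  otherwise. The Youden point maximizes `J = sens + spec − 1` with ties
  broken toward higher sensitivity, then the lower cut-off.
* **ICC**: two-way random effects, absolute agreement, single measure —
  ICC(A,1) — from the ANOVA mean squares, with the F-based 95% CI
  (Satterthwaite df). Absolute agreement is the variant appropriate for
  method/observer agreement because it penalizes systematic offsets; the
  implementation is cross-checked against pingouin in the tests. Mean
  squares that are pure float roundoff (identical raters) are snapped to
  zero so duplicated ratings give ICC = 1 exactly.
* Degenerate inputs (n = 2, single-class labels, zero variance) yield null
  inferential cells; the report is still emitted.

In the study pipeline the standard method defines the reference labels
(enlarged EDV/ESV index, reduced EF, strict sex-specific thresholds
123/104 and 59/48 mL/m², 42/46%), and the formula method's continuous
values are the ROC scores. EF is never clamped: a negative EF from noisy
measurements is passed through (with a warning) because clamping would
distort the agreement statistics. The reliability sub-study re-analyzes
the first 30 subjects (observer 1 twice, observer 2 once), mirroring
common practice.

## Problem sizes and determinism

Default problem sizes: Monte-Carlo volume checks use 10⁶ points per
phantom (SE ≈ 0.25 mL at cohort-mean size); noise-inflation checks use
10⁴ replicates; ICC parameter recovery uses 10⁴ virtual subjects;
end-to-end scenarios use n = 50 (ideal) and n = 70 (realistic). Every
random stage draws from a `numpy` `SeedSequence` derived from one master
seed; reruns with the same configuration are value-identical, and each
output file records the SHA-256 of its generating configuration.

## Known limitations

* The shape family is one realization consistent with k = 1.21; inference
  about the *true* anatomical proportions behind the constant is not
  possible from the constant alone.
* The RVOT patch is volumetrically faithful but geometrically crude; no
  phase-dependent RVOT contraction is modelled (the appendage fraction f
  is shared by ED and ES, so RVOT exclusion alone does not bias EF).
* Published patient-level statistics (r ≈ 0.76–0.80, AUC ≈ 0.84–0.90)
  depend on an inaccessible cohort; the realistic scenario reproduces the
  direction and rough magnitude of the biases, not those exact values.
* Mask grids are noise-free and perfectly registered; observer variability
  enters only through the linear measurements.
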