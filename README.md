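# rvquant

Simplified right-ventricular (RV) volumetry on synthetic phantoms, with the
complete method-comparison statistics used to validate it.

## The problem

Measuring RV volume and function on cardiac MR is the clinical reference,
but the standard workflow — manually contouring the endocardial border on
every slice of a short-axis stack and summing the discs — is slow and
observer-dependent, and the basal slices near the tricuspid valve are
notoriously hard to contour. A much faster alternative needs only **two
linear measurements in the four-chamber view**: the basal diameter at the
tricuspid valve (`Dd` in diastole, `Ds` in systole) and the baso-apical
length (`Ld`, `Ls`). Modelling the RV cavity as a *truncated cone minus a
truncated rhomboid pyramid* gives the cone–pyramid formula (CPF)

```
EDV = 1.21 · Dd² · Ld        ESV = 1.21 · Ds² · Ls        (cm → mL)
EF  = (EDV − ESV) · 100 / EDV  (%)
```

`rvquant` is for methodologists who want to study this estimator
quantitatively: it builds the geometric solid behind the constant 1.21,
generates virtual patient cohorts with controllable bias mechanisms,
quantifies each virtual patient with both the formula and standard
disk-summation volumetry, and runs the full agreement analysis
(Pearson correlation, Bland–Altman limits, ROC/AUC with Youden-index
cut-offs, intraclass correlation) — all without any patient data.

The key design point is that every stage has a closed-form oracle: the
solid's volume is exactly `k·D²·L` with
`k = (1+α+α²)(πβ²/12 − p₀q₀/6)`, `β = 1+p₀`, and the four-chamber chord of
the solid equals `D` by construction, so formula error, rasterization
error, and statistical bias can each be isolated and tested.

Two realistic bias mechanisms are built into the cohort generator:

* **RVOT exclusion** — an outflow-tract appendage holding up to 19% of the
  cavity volume that four-chamber measurements cannot see;
* **calibration mismatch** — per-subject true shapes whose coefficient
  differs from the fixed 1.21, emulating a coefficient calibrated on a
  different modality/population (this is what makes formula volumes run
  *high* and formula EF run *low* against disk summation, as observed
  clinically).

## Worked example

```python
import rvquant as rq

# recover the shape family consistent with the printed constant
shape = rq.calibrate_shape(alpha=0.3, q0=0.9, target_k=1.21)
print("calibrated p0 =", round(shape.p0, 4), " k =", rq.shape_coefficient(shape))

geom = rq.PhantomGeometry(shape=shape, D=4.2, L=7.7)   # cohort-mean phantom
print("analytic volume:", round(rq.analytic_volume(geom), 2), "mL")
print("formula volume: ", round(rq.cpf_volume(4.2, 7.7), 2), "mL")
mc = rq.monte_carlo_volume(geom, n=1_000_000, seed=0)
print(f"Monte Carlo:     {mc.volume:.2f} ± {mc.standard_error:.2f} mL")

out = rq.run_study(rq.StudyConfig.realistic(n=70, seed=0))
print(out.report.summary())
```

prints

```
calibrated p0 = 0.97  k = 1.21
analytic volume: 164.35 mL
formula volume:  164.35 mL
Monte Carlo:     164.39 ± 0.24 mL

RV method comparison (n = 70 subjects)

Agreement (standard vs formula method; difference = standard - CPF)
  RV-EDV index, mL/m2         76.7 ±  26.4  vs    80.6 ±  26.6   Δ =   -3.9 ±   7.3   r =  0.962
  RV-ESV index, mL/m2         41.8 ±  14.9  vs    48.2 ±  15.8   Δ =   -6.5 ±   3.9   r =  0.969
  RV-EF, %                    45.4 ±   6.8  vs    39.8 ±   7.9   Δ =    5.6 ±   4.9   r =  0.789
...
```

Reading this: the calibration solves for the rhombus long-diagonal fraction
`p0 ≈ 0.97` that makes the solid's geometric coefficient equal 1.21
exactly; on that solid the formula is exact (164.35 mL for the cohort-mean
phantom, confirmed by Monte-Carlo integration within its standard error).
In the realistic scenario the formula *over*estimates indexed volumes by a
few mL/m² and *under*estimates EF by ~5 percentage points relative to disk
summation — the net effect of the calibration mismatch outweighing the
excluded outflow tract — while correlation between methods stays strong
(r ≈ 0.96 for volumes). The report also carries ROC cut-offs for detecting
enlarged/dysfunctional ventricles and intra-/interobserver ICCs of the
formula method.

The same study runs from the shell:

```
rvquant run --scenario realistic --n 70 --seed 0 --out study/
rvquant simulate --seed 1 --n 20 --out data/       # cohort + masks + measurements
rvquant quantify --data data/                      # both methods from files
rvquant compare --results data/results.csv --measurements data/measurements.csv --out cmp/
```

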