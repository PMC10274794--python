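# Methods

## Osmotic model

A cell at equilibrium with its medium satisfies `Ψ_C = Ψ_M`, with
`Ψ_C = P − Π_C` and `Ψ_M = −Π_buffer`, so turgor is the osmotic excess
`P = Π_C − Π_buffer`. On sub-minute timescales solute content is constant
and cells adjust by water exchange only. A protoplast bears no turgor
(`P = 0`), so `Π_proto = Π_buffer`: it is an ideal osmometer whose volume
is linear in the inverse of the total external osmolyte concentration,

    V(C_total) = m0 / C_total + b0 ,

with `m0` (µm³·mol/L) proportional to the apparent number of osmotically
active particles and `b0` (µm³) the non-osmotic volume. Because the
growth-medium osmolarity `C0` is common to intact cells and protoplasts,
it cancels in `P = Π_C − Π_buffer`, and turgor follows from the *added
sorbitol* concentration at the isotonic point alone:

    P = c_iso · R · T ,

with `R = 8.314 J/(mol·K)` and `T = 303.15 K` by default (30 °C cultures;
configurable). Unit bookkeeping: mol/L → mol/m³ (×1000), Pa → MPa (/10⁶),
so 0.40 mol/L ↦ 1.008 MPa. Ideality of sorbitol is assumed throughout (no
osmotic-coefficient or activity corrections).

## The three isotonic readouts

**Volume.** Each condition×replicate protoplast population is reduced to a
central statistic (median by default; the median is robust to the skewed,
asynchronous cell-size distribution — the mean is available). These
summaries are regressed on `1/C_total` by unweighted OLS (statsmodels),
one point per condition×replicate. The intact-cell target is the mean of
per-replicate summaries, its spread their sample SD. Inversion:
`C_total,iso = m0/(V_intact − b0)`, `c_iso = C_total,iso − C0`. The error
combines the fit covariance of `(m0, b0)` and the intact-volume spread,
each propagated to concentration units by the first-order delta method and
added in quadrature (a bootstrap oracle in the test suite agrees with the
delta error within 20%). Degenerate inputs rejected: fewer than three
distinct concentrations, zero total concentration, a target at or below
`b0`, or an inversion below the medium baseline (reported as a
"hypotonic" diagnostic).

**Intensity.** Cytoplasmic-marker concentration is an intensive property,
assumed cell-cycle invariant, so no per-cell size correction is applied.
Per-cell ROI means are background-corrected and divided by the mean
corrected intensity of intact cells imaged on the *same slide*, which
cancels any slide-level gain exactly. Per-condition means of the
normalized values are fitted by OLS against sorbitol concentration and the
line inverted at 1.0. The true response is `V_intact/V(C_total)`, which is
convex in `C`; the regression is therefore meant to be local, and a
concentration window can restrict it to conditions bracketing the intact
level (the function default uses all conditions; the default synthetic
scenario sets a four-condition window, 0.18–0.52 mol/L). An inversion
outside the fitted window is flagged, not rejected. The target uncertainty
entering the error combination is the squared SEM of the normalized intact
population (per-slide self-normalization makes the between-replicate
variance of normalized intact means identically zero, so the sampling
error of the calibration target is the meaningful term).

**Nanorheology.** Per-track time-averaged MSD uses all overlapping pairs,
`MSD(kΔt) = ⟨(x_{i+k}−x_i)² + (y_{i+k}−y_i)²⟩`, for lags k = 1…10 at the
10 ms frame interval; tracks shorter than 11 frames are excluded with a
logged count. The ensemble-mean MSD over the first 10 lags is fitted to
`MSD = 4 D_eff τ` through the origin; the SEM comes from the spread of
per-track slopes. Across sorbitol conditions the Phillies law
`D_eff = D0·exp(−β(C + C0))` is fitted with `D0 = 13.56 µm²/s` (the
Stokes–Einstein value for a 40-nm sphere in water, used as a fixed named
constant) and `C0` fixed to the medium concentration, leaving β as the
single parameter. The default fit linearizes in log space (a
through-origin regression of `ln(D/D0)` on `−(C+C0)`); a nonlinear
linear-space option (scipy `curve_fit`) agrees within 1% on noiseless
data. Inversion: `c_iso = ln(D0/D_eff,intact)/β − C0`, with β variance and
the intact SEM combined by the delta method. `D_eff ≥ D0` is rejected as
unphysical.

**Cross-method averaging.** The per-method pressures are averaged
arithmetically; the reported error is the sample SD (n−1) across methods,
which requires at least two methods. The same rule applied on the
concentration scale gives the average isotonic concentration. Full
precision is kept internally; tables round concentrations to two decimals
and pressures to two significant figures for display only.

## Wall mechanics

For a rod-shaped cell with homogeneous, isotropic thin wall, the lateral
force balance gives the elastic strain `ε = ΔP·R/(Y·h)`, hence
`Y = ΔP·R/(h·ε)` ((MPa·µm)/nm → a factor 1000) and wall tension
`T = ΔP·R` (MPa·µm = N/m exactly). Both are homogeneous of degree one in
turgor. Absolute moduli require user-supplied geometry; cross-species
comparisons need only ratios (`scale_young`): double radius, double
thickness, half turgor and equal strain halve the modulus and conserve
tension. No orthotropic or tip-growth extensions.

## Synthetic data: what it emulates and what it does not

`StudyScenario` fixes one ground truth — the intact cell's total internal
osmolarity — from which all three generators derive their observables, so
each pipeline can be scored against a known isotonic sorbitol
concentration (`internal − baseline`). Defaults define a fission-yeast-like
study: medium baseline 0.30 mol/L (rich-medium ballpark; the real value is
strain/medium specific and must be supplied for real data), sorbitol grid
0.10–0.60 mol/L in 6 steps, 2 replicates, 100 cells or 1000 tracks per
condition (totals, split across replicates), intact median volume 100 µm³,
non-osmotic fraction 0.30, lognormal cell-to-cell volume CV 25%
(resembling asynchronous size distributions), intensity measurement CV 5%
with slide factors {0.85, 1.15} and additive background, tracks of 500
frames at 100 fps with 0.03 µm localization noise, and a Phillies β chosen
so intact tracers diffuse at the reference wild-type mobility of
0.40 µm²/s. Three scenario factories place the per-method truths at
0.40 / 0.37 / 0.43 mol/L.

In the zero-noise limit the generators satisfy their governing laws
exactly (BVH linearity, inverse-volume intensity with normalized value 1.0
at the isotonic condition, `4Dτ` MSD, Phillies exponential), which the
test suite asserts to machine precision. What the generators do *not*
emulate: osmotic-shock transients and regulatory volume responses,
photobleaching and flat-field structure, vacuole exclusion, anomalous
(subdiffusive) tracer motion, tracking/linking errors, or any stress
response during protoplast preparation (a scenario with unchanged internal
osmolarity stands in for that control). Passing recovery tests therefore
demonstrate correctness of the estimators under the stated statistical
structure, not robustness to those experimental artefacts.

## Numerical choices and known limitations

- **Seeding.** Generators draw from `numpy.random.default_rng([seed, k])`
  with a distinct stream tag `k` per generator; identical seeds give
  bit-identical tables.
- **Localization noise** adds a static `4σ²` MSD offset; with the
  through-origin fit at 10 lags this inflates every condition's `D_eff` by
  the same additive amount (~0.013 µm²/s at σ = 0.03 µm). Because the
  method *matches* intact cells to the protoplast curve, the bias largely
  cancels in `c_iso` (≈0.3% residual on the default scenario). An optional
  free-intercept MSD fit absorbs the offset explicitly.
- **Sampling limits of the volume method.** The inversion amplifies
  intact-volume error by `dC/dV = C_total,iso/(V_intact − b0)` (≈0.01
  mol/L per µm³ at the defaults). With 100 cells per condition and a 25%
  volume CV, the sample-median route carries a per-study SD of ~0.03 mol/L
  on `c_iso` (≈8% of the default truth); the estimator is unbiased and the
  scatter shrinks as `1/√n` (SD ≈ 0.009 mol/L at 2000 cells/condition).
  Studies needing per-run precision better than ~10% from volumes alone
  should measure substantially more than 100 cells per condition —
  undersampling of asynchronous distributions is the known weakness of
  this method, and the intensive (intensity) and high-n (rheology)
  readouts do not share it.
- **Two-point linear fits** have no residual degrees of freedom; their
  parameter covariance is reported as zero rather than undefined.
- **Ties and degeneracies.** All-equal concentrations, empty populations,
  too-short tracks, zero slopes and out-of-range intact mobilities raise
  explicit errors; non-positive corrected intensities and short tracks are
  excluded with logged counts rather than failing the run.
- **Reported `n`.** Estimates carry the number of protoplast cells or
  tracks used, since evidence thresholds (hundreds of cells, thousands of
  tracks) are part of the method's credibility.
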