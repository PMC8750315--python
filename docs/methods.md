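# Methods

## The measurement model

A uniform-field drift tube holds an ion swarm in a buffer gas under a
static field E = V/L. The drift velocity is K·E with K the mobility, so
the time spent inside the tube of length L is L²/(K·V); the recorded
arrival time adds a voltage-independent transit time t₀ spent in the
transfer optics and detector:

    t_d(V) = t₀ + L² / (K·V).

Mobility is reported as the *reduced* mobility, normalised to standard
pressure and temperature,

    K₀ = K · (P[torr]/760) · (273.15/T),

and kinetic theory (Mason–Schamp, two-temperature theory at low field)
ties K₀ to the momentum-transfer collision cross section Ω:

    Ω = (3 z e / 16 N₀) · sqrt(2π / (μ k_B T)) · 1/K₀,

with μ = m₁·m_B/(m₁+m_B) the ion/gas reduced mass, z the charge count,
N₀ the gas number density at 1 atm/273.15 K (Loschmidt constant,
2.687 × 10²⁵ m⁻³) and T the drift-gas temperature. `physics` implements
both relations with CODATA 2018 constants and exposes the algebraic
inverse K₀(Ω). Assumptions: low-field (thermal) regime, ideal gas, no
ion heating or clustering — standard for drift tubes run near 4 torr
and ~1700 V over 78 cm.

Note on constants: a common printed variant of the Mason–Schamp
prefactor carries an elementary charge of 1.602 × 10⁻¹⁶ C; the
physically correct value is 1.602176634 × 10⁻¹⁹ C and only the latter
reproduces consistent CCS/K₀ tables, so that is what the package uses
throughout. Similarly 273.15 K is used where 273.2 K sometimes appears
(< 0.02% difference).

## Stepped-field route (`multifield`)

Drift times at ≥ 3 distinct voltages (the reference protocol uses eight,
1000–1700 V) are regressed by ordinary least squares on 1/V. The slope
s = 1000·L²/K (ms·V) yields K and hence K₀; the intercept is t₀. The
regressor is 1/V rather than 1/E — equivalent up to the constant L, and
voltages are what the acquisition software records. OLS is unweighted:
arrival-time noise is approximately homoscedastic across the ladder. A
Theil–Sen variant (`robust=True`) is available for gross outliers; its
slope is the median of pairwise slopes, immune to a single bad apex.
Fits this linear should have r² ≳ 0.999; lower values are flagged in
reports (threshold `R_SQUARED_WARN_THRESHOLD`, configurable). A
non-positive slope (drift times not shrinking as voltage rises) is a
hard error, since it almost always means mis-labelled input.

## Single-field route (`singlefield`)

At a fixed voltage the drift model makes t_d linear in γ·Ω, where
γ = √μ/z carries the entire mass-and-charge dependence of Mason–Schamp.
Calibrant ions of known CCS fix slope β and intercept t_fix by OLS;
unknowns invert to Ω = (t_d − t_fix)/(β·γ). The module supports both
external calibrant sets and self-calibration from the same panel's
stepped-field results (both workflows are used in practice; the package
does not presume either). The two-route agreement statistic is the
population standard deviation of the pair over its mean,
100·|a−b|/(a+b): half the relative spread. The population (n) divisor,
not the sample (n−1) divisor, is the convention that reproduces
published agreement tables of this kind, and it is what the package
implements.

## Peak picking (`spectra`)

Drift peaks are very nearly Gaussian, so apexes are refined by a
three-point parabola through the log-intensities around each local
maximum — exact for a Gaussian, closed-form, and accurate to a small
fraction of the 0.01 ms grid (the test suite bounds the noiseless bias
at grid/100). When a sample in the triplet is non-positive the parabola
falls back to raw intensities. The noise scale is the MAD (scaled to
sigma) of the first and last deciles of the trace, where drift peaks do
not sit; the baseline is the median of the same samples, and heights
and S/N thresholds are measured above it. Ties in height break toward
the earlier apex, making output ordering deterministic. Degenerate
inputs: a flat trace returns no peaks (not an error); a noiseless trace
makes the S/N infinite, returned as a sentinel with a warning.

## Validation calculus (`validate`)

* **Linearity** — unweighted OLS of mean area per level against
  concentration; parameter CIs from the t distribution with n−2 degrees
  of freedom; r² ≥ 0.991 is the report's acceptance flag. A 1/x²
  weighting option exists because calibration ranges spanning two
  orders of magnitude otherwise let the top level dominate.
* **LOD/LOQ** — 3.3·c/m and 10·c/m from a reference concentration and
  its *measured* signal-to-noise ratio. Published LOD/LOQ pairs
  produced this way are generally not in the exact 3.3:10 ratio because
  each is measured at its own S/N; the package therefore takes per-
  quantity inputs, with the ICH residual-SD route (3.3·s/slope) behind
  `lod_from_fit`/`loq_from_fit` as the no-extra-measurement fallback.
* **Precision** — %RSD with the sample (n−1) divisor.
* **Recovery** — 100·(measured_total − base)/added. Reports can average
  over spike replicates or use a single replicate; the report records
  which (`recovery_mode`), since published tables rarely say.
* **Matrix effect** — 100·area_matrix/area_solvent.
* **Content** — c·V_elution/m_sample·1000, defaulting to the 200 µL /
  30 mg micro-extraction geometry (factor 20/3). Dimensionally this is
  µg analyte per g sample; assay tables conventionally print the column
  under a "mg/g" heading, and the function reproduces the printed scale
  (the unit label discrepancy is the table convention's, not the
  arithmetic's).

## Synthetic study generator (`simulate`)

What it emulates: Gaussian drift peaks (default FWHM 0.35 ms, a
plausible width for a ~20 ms drift regime; real widths vary with
mobility and gate width) of height 1000 counts on a 20-count baseline
with additive sigma-5 noise, at the kinematically exact drift times of
the compound's true K₀ across the eight-voltage ladder; calibration
areas linear in concentration over 0.05–5 µg/mL with 2% multiplicative
noise (heteroscedastic in absolute terms, as real areas are); spiked
samples whose back-calculated recoveries embed programmed true
recoveries; matrix pairs embedding factors in the 85–96% window.
Default ground truth is the published seven-compound panel (K₀, t₀,
extract concentrations, recoveries), so the demo report has familiar
numbers.

What it does not emulate: chromatographic drift/retention, isotope
patterns, peak asymmetry, detector saturation, inter-day drift,
carry-over, or correlated noise. Passing tests therefore demonstrate
correctness of the *computational* chain under a faithful but idealised
noise model, not robustness to every instrumental pathology.

Randomness is counter-based: the global seed plus stable per-output
tokens (CRC32 of compound/section names) seed independent generator
streams, so adding a compound never perturbs the noise of existing
outputs, and identical scenarios are byte-identical on disk.

A noteworthy emergent behaviour: spiking 0.05 µg/mL onto a base
concentration two orders larger (erianin at 9 µg/mL) divides the area
noise by the tiny added amount, scattering recoveries by tens of
points. Published spike-recovery tables for such panels scatter the
same way, for the same reason; the generator reproduces it without any
dedicated mechanism.

## Open design choices

* **Drift-gas state.** The gas identity, in-tube pressure and the
  temperature entering Mason–Schamp are rarely reported. Defaults are
  nitrogen (28.0134 Da), 3.95 torr and 300 K — standard for commercial
  uniform-field tubes and consistent (within 1%) with the reference
  panel's K₀/CCS pairs; a single fitted temperature of ≈ 303 K brings
  all seven pairs within 0.15%. Source-region gas-heater setpoints
  (hundreds of °C) are not the in-tube temperature and must not be used
  in the equation; T is therefore a free, explicit parameter.
* **Which voltage the fixed-field drift time refers to** is taken as
  1700 V (the stated single-field voltage); the kinematic invariant
  (t_d − t₀)·K₀ ≈ 20.0 ms·cm²/(V·s) holding across all seven reference
  compounds to 0.5% confirms the choice empirically.
* **Problem sizes in tests** (500–1000 replicate fits for Monte-Carlo
  checks, 300 spectra for S/N calibration) were chosen to make binomial
  and median error bands tight relative to the asserted thresholds
  while keeping the whole suite in seconds.

## Known limitations

* Single-charge chemistry is the tested regime; z > 1 is implemented
  (m_B = z·m/z, γ ∝ 1/z) but not exercised against reference data.
* No vendor raw-file or mzML ingestion: the interchange format is CSV
  exported upstream, by design.
* The single-field calibration is strictly linear in γ·Ω; power-law
  calibrations used by some travelling-wave instruments are out of
  scope (this package targets uniform-field drift tubes).
* CCS is reported to 0.1 Å² in report frames; full precision is kept in
  the underlying objects.
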