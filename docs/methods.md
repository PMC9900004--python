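# Methods

## Scope and data model

The package analyses single-dose tissue pharmacokinetics of an orally
administered drug and its metabolite in fish, plus muscle-residue
depletion after extended medicated feeding. The unit of analysis is a
`ConcentrationTimeProfile`: one tissue × one analyte, times in hours
post dose (strictly increasing, ≥ 0), concentrations in µg/kg, with a
per-point below-LOQ (BLOQ) mask. A study holds at most one profile per
(tissue, analyte) key; doses are mg/kg body weight (×1000 to µg/kg
internally). Profiles with fewer than two quantifiable points are
flagged `insufficient` and excluded from AUC/regression work rather
than failing the run.

### BLOQ and time-origin conventions

Assays are silent below their LOQ, so a convention is unavoidable.
Default: BLOQ points before the peak contribute 0 to the trapezoid (the
drug has not appeared yet); BLOQ points after the peak are dropped from
the AUC and from all regressions. An LOQ/2 substitution policy is
selectable (`bloq_policy="loq2"`). For oral dosing, a missing t = 0
sample is assumed to be 0 µg/kg; a numerically-zero reading at t = 0 is
treated as this structural pre-dose zero, not as an assay value to be
LOQ-censored. Every masked point and assumed zero is logged at info
level so derived parameters are auditable.

## Non-compartmental estimation

* **AUC** — linear trapezoid only (the log-linear trapezoid exists
  behind `bloq_policy`-style configuration but is off by default, since
  the linear rule is the one the source studies use). Additivity over
  partitions holds to machine precision and is property-tested.
* **Terminal phase** — OLS of ln C on t. Eligible points are
  quantifiable, positive, and strictly after the observed `T_max`. The
  default selection searches all contiguous windows of ≥ 3 points
  ending at the last eligible point and keeps the best r² (ties to the
  larger window); a fixed-last-n strategy is available. Source reports
  rarely state their window selection, and their printed half-life /
  rate-constant pairs can be mutually inconsistent
  (ln 2 / 0.03489 = 19.9 h against a printed 23.34 h), so this package
  estimates one terminal slope, derives everything from it, and reports
  the fit diagnostics (r², window, n) instead of forcing agreement with
  any published pair.
* **Negative slopes** — a rising tail (common for sparse metabolite
  data; published tables print k_el of −0.0218 and −0.0241 for
  metabolite skin and kidney) is reported with a `negative k_el` flag;
  tail extrapolation and AUC(0–∞) are then withheld. Extrapolated
  fractions above 20 % of AUC(0–∞) are flagged.
* **Half-life family** — `t_1/2 = ln 2 / k_el`; mean lifetime
  `T = t_1/2 / ln 2`; decay constant `λ = 1/T`. The absorption constant
  is reported under the convention `K_a = ln 2 / t_1/2` used in the
  source literature; it is numerically the decay constant, not an
  independently estimated absorption rate, and is labelled as such.
  (Published table footnotes swap the labels of T and λ; the numbers,
  which follow T = t_1/2/ln 2, are what this package implements.)

## Metabolite disposition

AMR, MR and ADR are pure ratio statistics — no enzymatic model. AUC
inputs default to AUC(0–last), matching the AUC(0–128) convention of
the source tables; AUC(0–∞) is selectable. The ADR series is kept per
time point (shared quantifiable grid; 0/0 points skipped); the scalar
summary is the arithmetic mean of the series. Published single-number
ADR values are not reproducible from published peaks alone and their
time-resolved source table is unavailable, so ADR is validated against
closed-form simulator curves instead of golden values.

## Synthetic-data generator

One-compartment, first-order absorption, linear kinetics:

    C_p(t) = Kp · (F·D·ka)/(V·(ka−ke)) · (e^(−ke·t) − e^(−ka·t))

with a first-order metabolite cascade (formation fraction `fm`, rate
`fm·ke·P(t)`, elimination `km`) giving a three-exponential metabolite
curve. Coincident rate constants use exact limit forms (t·e^(−kt) and
t²-type confluent terms), cross-checked in the tests against a matrix
exponential of the cascade, so no parameter perturbation is needed.
Noise is multiplicative lognormal, `C·exp(N(0, σ²))` with
`σ = √ln(1+CV²)`; values below the LOQ are masked BLOQ. Per-profile RNG
substreams derive deterministically from (master seed, CRC32(tissue),
CRC32(analyte)), so datasets are reproducible profile by profile and a
fixed seed yields byte-identical CSV output.

Defaults state the single-dose study design: 15 mg/kg oral dose,
sampling at 0, 2, 3, 4, 6, 8, 12, 16, 24, 32, 48, 64, 96, 128 h, seven
tissues, LOQ 0.5 µg/kg. Where the design leaves parameters open they
are set once to literature-plausible values: F = 0.9 (oral
florfenicol bioavailability in salmonids is reported at 91–99 %),
ka = 0.2 h⁻¹ (absorption half-life ≈ 3.5 h, peak near 11–16 h),
ke = 0.03 h⁻¹ (parent t_1/2 ≈ 23 h as reported in trout tissues),
V = 35 L/kg (apparent, plasma-referenced, so plasma C_max ≈ 270 µg/kg
at 15 mg/kg), fm = 0.14 and km = 0.02 h⁻¹ (metabolite t_1/2 ≈ 35 h and
plasma MR ≈ 0.21), noise CV = 0.15. Tissue partition coefficients are
the ratios of reported tissue-to-plasma peak concentrations
(intestine 19.6 > gill 10.6 > kidney 8.2 > liver 3.6 > skin 2.1 >
muscle 1.6 > plasma 1), which fixes the C_max ordering; exact published
concentrations are *not* generator targets.

What the generator does **not** emulate — and therefore what a green
test does not establish: secondary absorption peaks from gut
reabsorption or enterohepatic recirculation (reported in several fish
species), temperature dependence, tank/pooling structure, and
inter-fish variability beyond the single multiplicative noise term. A
passing recovery test certifies the estimators on single-peak
first-order data only.

## Repeated dosing and residues

Linear kinetics ⇒ superposition: the multi-dose curve is the sum of
time-shifted single-dose curves (once daily for `n_days`, default 30,
then depuration). The steady-state trough accumulation index
1/(1 − e^(−ke·τ)) is property-tested to 1 %. Residue depletion is OLS
of ln(residue) on days after the end of dosing (≥ 3 positive points).
Withdrawal time against the MRL (default 1,000 µg/kg muscle):

* **point** — `(intercept − ln MRL)/(−slope)`;
* **tolerance-95-95** — the time at which the upper one-sided 95 %
  tolerance limit for the 95th percentile of log residues,
  `ŷ(t) + k(t)·s` with `k(t) = t′_{0.95, n−2, δ(t)}·√d(t)`,
  `d(t) = 1/n + (t−t̄)²/Sxx`, `δ(t) = z_{0.95}/√d(t)` (noncentral t),
  crosses ln MRL — the regulatory-style construction, solved by
  bracketing and Brent's method.

Both are reported in whole days rounded up (conservative), and the
tolerance estimate is never earlier than the point estimate. Slopes
that are non-negative within roundoff (≥ −10⁻¹²/day) are flagged and
yield no withdrawal time. Dose groups are analysed independently:
published day-50 residues are not monotone in dose (0.102 µg/kg at 10×
under 1.32 at 1×), so no dose-ordering is ever assumed.

## Numerical choices

* `C_max` ties → first occurrence defines `T_max`.
* Full precision is kept internally; parameter tables are written with
  `%.17g` and read back with round-trip float parsing, so
  write-then-read is lossless.
* Golden-value comparisons use absolute tolerances at the printed
  precision of the source tables (which mix truncation and rounding);
  quantities printed to one decimal carry only ±0.05 of information.
* r² ties in the terminal-window search resolve to the larger window
  via a strict-improvement threshold of 10⁻¹².
* Seeds: one master seed; all substreams derive from it (see above).

## Known limitations

Single-analyte-pair metabolite model; no MRT/Vss moment analysis; no
compartmental fitting; the 95/95 tolerance limit assumes normal log
residuals; withdrawal times extrapolate the fitted line beyond the
sampled window when the MRL crossing lies outside it, and inherit that
regression's assumptions.
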