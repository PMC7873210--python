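# Methods

## The equilibrium model

The package models in vitro assembly of two-component icosahedral cages
(the I53 architecture: 20 trimers, 12 pentamers, 60 identical
trimer–pentamer contacts, 120 monomers) as a multi-component mass-action
equilibrium of the Zlotnick type. Each modeled species
T<sub>3a</sub>P<sub>5b</sub> — *a* trimeric and *b* pentameric building
blocks, *c* contacts, rotational symmetry number *s* — has molar
concentration

    [T_{3a}P_{5b}] = 3^a 5^b ([T]/3e6)^a ([P]/5e6)^b exp(c ΔG_con / RT) / s

with [T], [P] free **monomer** concentrations in μM (so [T]/3·10⁶ is the
free trimer building-block concentration in M), T = 296 K and
R = 1.98720·10⁻³ kcal/(mol·K). Total monomer balances
[T]₀ = Σ 3a·[species]·10⁶ + [T] and [P]₀ = Σ 5b·[species]·10⁶ + [P] close
the system.

Assumptions inherited from the experimental system: only the designed
heteromeric trimer–pentamer interface contributes (no T–T or P–P
association); all contacts share one average energy ΔG_con; the species
set is restricted to the termini of assembly pathways — the complete cage,
three nearly complete ("late") intermediates, and five small ("early")
ones — because intermediates far from the termini are never predicted to
accumulate at equilibrium. Late intermediates co-elute with the complete
cage in SEC (high-MW class); early intermediates co-elute with free
components (low-MW class).

**Sign convention.** ΔG_con is stored as a positive magnitude of a
*favorable* association energy; the Boltzmann exponent is
+c·ΔG_con/(RT). (Quantities of ~3.6–4.1 kcal/mol are conventionally
printed as positive magnitudes inside a formally negative exponent; taken
literally that would make assembly vanishingly unfavorable, so the
favorable orientation is adopted and verified by the monotonicity property
tests: mass fraction non-decreasing in ΔG_con and in total concentration.)

**Species table defaults.** Contact counts and symmetry numbers for the
complete cage (c=60, s=60), T57P60 (c=57, s=3) and T3P5 (c=1, s=1) follow
their published closed-form laws. The remaining six intermediates use the
combinatorial values of the corresponding partial structures (contacts =
edges present, symmetry = rotational order): T60P55 c=55/s=5, T54P60
c=54/s=1, T6P5 c=2/s=1, T3P10 c=2/s=1, T3P15 c=3/s=3, T6P10 c=3/s=1. All
are data, not code: species tables serialize to JSON/YAML and can be
overridden, so other point-group architectures can reuse the engine.

## Numerics

Prefactors like 3²⁰5¹² together with concentration products of order
10⁻¹⁹⁰ and Boltzmann factors of order e³⁶⁷ are unrepresentable separately
in double precision. All species laws are therefore evaluated as sums of
logs, and totals via log-sum-exp; the model is verified against 50-digit
arbitrary-precision direct evaluation (mpmath) to ≤10⁻¹⁰ relative error
and is stable for ΔG_con up to at least 10 kcal/mol and free
concentrations down to 10⁻⁶ μM.

The forward parameterization (grids of free concentrations in, totals and
species out) reproduces 3D partition surfaces. The inverse problem —
given ([T]₀, [P]₀), find the free state — is solved by damped Newton
iteration on (ln [T], ln [P]) with the analytic Jacobian of the log
totals (the totals are posynomials, so the Jacobian entries are
softmax-weighted exponent averages). The iteration is initialized by
bisection on a scale factor along the ([T]₀, [P]₀) ray, which keeps the
Jacobian well conditioned (starting at free = totals lets a single species
dominate both totals, making the Jacobian rows numerically parallel); a
diagonally regularized step handles any residual near-singularity.
Solutions are unique by strict monotonicity of the totals in each free
concentration; mass balance is enforced to 10⁻⁹ relative error, with a
`ConvergenceError` carrying the residuals otherwise. Degenerate inputs
([T]₀ = 0 or [P]₀ = 0) return the all-free state, since no heteromeric
species can form.

Reduction of 3D forward-grid output to 2D curves keeps points within a
1 μM slab of the plane of interest (the equimolar plane, or a constant
component at 50 μM) and averages within bins (0.5 μM default; 0.0625 μM
for the I53-50 equimolar preset). Model predictions at experimental
(t₀, p₀) points are computed with the inverse solver instead of re-binning
a forward grid — equivalent by the conservation guarantee and cheaper —
while the binning path is retained for figure reproduction.

## Signals and normalization

Predicted SEC signals are extinction-weighted monomer totals of each MW
class normalized to the expected signal of a 50 μM equimolar complete
assembly; the low-MW signal is additionally multiplied by the adjustment
factor F_A280 (≈0.89 for I53-40, 0.90 for I53-50), the single place where
the ~10% excess A280 of assembled material (attributed to scattering) is
modeled. Experimental areas are normalized as in the source protocol:
high-MW areas against the mean total signal of six 50 μM equimolar
reference assemblies, low-MW areas against the summed signal of the two
components injected separately (a quantity that equals F_A280 times the
assembled-run total by the definition of the factor). Normalization is
guarded against double application, and ratio uncertainties propagate as
|X/E|·√((σX/X)² + (σE/E)²).

Assembled mass fractions from peaks divide out the adjustment factor
(fraction = high/(high + low/f)) and convert to molar amounts assuming
equimolar stoichiometry in both pools. Monomer-count weighting is the
default basis for mass fractions; a molecular-weight-weighted variant is
available (`mass_fraction_assembled(state, mw_t=..., mw_p=...)`).

## Fitting and cooperativity

ΔG_con is fit by scanning candidates (default 2.5–5.5 kcal/mol at
0.01 kcal/mol, matching the 0.1 kcal/mol reporting precision and the
±0.25 kcal/mol visualization bands) and minimizing the pooled RMSPE
between predicted and replicate-averaged experimental normalized signals,
with percent error defined asymmetrically (experimental value in the
denominator; no symmetrization). Zero experimental values are excluded
with a logged count. A two-stage scan (coarse 0.1 then fine 0.01 around
the coarse minimum) exploits the profile's unimodality on self-generated
data; equimolar and titration datasets are pooled into one RMSPE by
default, separable via configuration. No uncertainty beyond the ±0.25
band and the seeded recovery experiments is attached to the estimate.

Hill analysis regresses log₁₀ Θ/(1−Θ) on log₁₀ L with Θ the assembled
mass fraction and L the total residual free monomer in μM; slope = Hill
coefficient, x-intercept back-transforms to an apparent K_D. Points
outside 0.05 < Θ < 0.95 are excluded as saturated (configurable). Base-10
logs are conventional; the slope is base-invariant. Noiseless model
curves for the simplified species set give Hill slopes approaching the
31 expected for an all-or-none 32-building-block reaction — far steeper
than measured coefficients of real systems, which is the expected
relationship between an equilibrium two-state limit and data.

## Thermal callers

Tm (derivative method): the trace is spline-interpolated onto a 0.1 °C
grid and Tm is the temperature of the central-difference derivative's
extremum after removing the median drift. A cubic spline is used rather
than a quadratic one: a quadratic spline's derivative is piecewise linear
with extrema pinned to its knots, which quantizes the called Tm to about
half the sampling interval (a systematic ~0.2–0.3 °C bias at 1 °C
sampling), while the cubic preserves the sampling-symmetric extremum and
recovers logistic midpoints to 0.1 °C. Traces whose peak derivative does
not exceed the trace's mean slope by 2.5× are rejected as transition-free.

Tagg / threshold method: the threshold line is anchored at the starting
signal plus a fraction of a typical endpoint magnitude and rises with the
average baseline drift; the first crossing (onset semantics) of the
cubically interpolated trace is reported. Presets: SLS — 20% of a
60,000-count endpoint; nanoDSF — 50% of a −4.5 nm or 20% of a −14.2 nm
endpoint shift. The expected ellipticity loss for the I53-50 CD variant
is a configuration scalar (no published value exists). Baseline drift is
pooled per assay by default with a per-curve override, since the pooling
granularity of the source protocol is not specified.

Initial rates are ordinary least-squares slopes of absorbance vs time over
a 100–200 s window, reported relative to a 25 °C control.

## Synthetic data

The generators emulate the study design: component titrations with one
component at 50 μM and the other swept 12.5–150 μM (0.25:1 to 3:1), an
equimolar series spanning the pseudo-critical region, three technical
replicates, six 50 μM equimolar reference assemblies plus separate
component injections, and mean-one multiplicative lognormal replicate
noise at 5% CV (bracketed by the reported adjustment-factor scatter,
0.06/0.89 ≈ 7% and 0.04/0.90 ≈ 4%; additive-vs-multiplicative structure is
not derivable from published information, and multiplicative was chosen as
the natural model for peak-area measurements). All generators are
deterministic under their seed, and datasets carry generating metadata as
CSV header comments.

Reference-assembly injections are emitted as the idealized
complete-assembly signal that the normalization equations assume. Real
50 μM references are themselves equilibrium reactions (~85–92% assembled
at plausible energies), so real normalizations carry a small
incompleteness bias that the synthetic data deliberately excludes — one
of several reasons passing round-trip tests bound implementation
correctness, not agreement with any real instrument. Other real-data
features not emulated: correlated (non-independent) replicate errors,
baseline/integration artifacts in SEC traces, off-pathway aggregates, and
any kinetic limitation (the model, like the analysis it supports, is
purely equilibrium).

Synthetic chromatograms place baseline-separated Gaussian peaks
(assembled ≈ 12 mL, components ≈ 16 mL on a 24 mL column) with areas equal
to the generating peak areas; trapezoidal integration round-trips those
areas to 1%. Melt traces are logistic transitions plus linear drift and
seeded Gaussian noise.

## Known limitations and open points

* **Trimeric voids.** Exhaustive search on the icosahedral face–vertex
  incidence graph shows up to **8** trimers can be removed while every
  pentamer keeps ≥3 contacts (two vertex-disjoint tetrads of faces; the
  counting bound ⌊12·2/3⌋ = 8 is attained). Narrative estimates of "up to
  seven evenly distributed" voids evidently add a placement/symmetry
  constraint beyond this stated graph criterion; the package implements
  the graph criterion and reports the witness subset.
* **Simplified vs inclusive agreement.** At equimolar input the two
  species sets agree to <2% absolute mass fraction everywhere at
  ΔG_con ≥ 3 kcal/mol and to <1% at ≥3.5 kcal/mol; the worst case sits
  exactly at the pseudo-critical midpoint. Claims that intermediates are
  negligible near equimolarity are accurate away from that midpoint.
* The model is equilibrium-only: kinetic trapping, curing time courses
  and hysteresis of dilution are outside its scope.
* Extinction coefficients default to synthetic placeholders
  (ε_T = 20,000, ε_P = 15,000 M⁻¹cm⁻¹ per monomer); real analyses must
  supply system values via configuration.

## Problem sizes

Default test and acceptance workloads are sized for a laptop-class single
core: the intermediate-share scan solves 21 × 20 equilibria (<1 s), the
recovery experiment fits 20 seeded datasets of ~27 concentration points
each with a coarse-then-fine energy scan (~1.5 minutes), and the full test
suite runs in well under five minutes.
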