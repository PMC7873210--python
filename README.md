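# nanocage

Equilibrium thermodynamics of two-component icosahedral protein
nanomaterials: mass-action assembly models, SEC signal normalization,
contact-energy fitting, cooperativity statistics, and thermal-stability
analysis.

## The problem

Designed two-component icosahedral cages of the I53 family assemble from 20
trimeric (T3) and 12 pentameric (P5) building blocks — 120 monomers joined
by 60 copies of a single designed trimer–pentamer interface. In vitro, the
reaction is strikingly cooperative: size-exclusion chromatography (SEC) of
assembly reactions shows essentially only complete cages plus residual free
components. This package implements the quantitative toolkit used to
characterize that behavior:

* a multi-component **Zlotnick-type equilibrium model**, in which each
  partial or complete species T<sub>3a</sub>P<sub>5b</sub> with *c*
  trimer–pentamer contacts and rotational symmetry number *s* obeys

  $$[\mathrm{T}_{3a}\mathrm{P}_{5b}] \;=\; \frac{3^a\,5^b\,
  \left(\tfrac{[\mathrm{T}]}{3\times10^6}\right)^{a}
  \left(\tfrac{[\mathrm{P}]}{5\times10^6}\right)^{b}
  e^{\,c\,\Delta G_\mathrm{con}/RT}}{s}$$

  with [T], [P] the free monomer concentrations in μM, T = 296 K, and
  ΔG<sub>con</sub> the per-contact association energy (stored as a positive,
  favorable magnitude). Total-monomer balances
  [T]₀ = Σ 3a[species]·10⁶ + [T] (and analogously for [P]₀) close the
  system. A *simplified* species set keeps only the complete cage; an
  *inclusive* one adds three late (T60P55, T57P60, T54P60) and five early
  (T3P5 … T6P10) on-pathway intermediates.
* **SEC signal normalization**: predicted signals are extinction-weighted
  monomer totals of each molecular-weight class relative to a 50 μM
  equimolar complete assembly, with an empirical adjustment factor
  F<sub>A280</sub> (≈0.89/0.90) absorbing the ~10% excess absorbance of
  assembled material.
* **Contact-energy fitting** by root-mean-squared-percent-error (RMSPE)
  minimization over a ΔG<sub>con</sub> scan, with the published t₀ ≥ p₀
  restriction available as a system preset.
* **Cooperativity statistics**: assembled mass fractions from peak-area
  ratios, Hill plots (log₁₀ Θ/(1−Θ) vs log₁₀ L; slope = Hill coefficient,
  x-intercept → apparent K_D), and chevron summaries of component
  titrations.
* **Thermal analysis**: Tm by derivative extremum of interpolated melts,
  aggregation/unfolding onsets by threshold-line crossing (SLS and nanoDSF
  presets), and initial-rate regression for residual enzyme activity.
* a seeded **synthetic-data generator** for every stage, so the entire
  pipeline is testable without instrument data.

## Worked example

```python
from nanocage import ThermoParams, default_species_table, solve_equilibrium

table = default_species_table("simplified")
state = solve_equilibrium(t0=100.0, p0=100.0, params=ThermoParams(dg_con=3.6),
                          species_table=table)
print(f"{state.mass_fraction_assembled:.3f}")   # 0.922
print(f"{state.free.free_t:.2f}")               # 7.77 (uM free T monomer)
```

At 100 μM equimolar input and a 3.6 kcal/mol contact energy, 92.2% of the
material is predicted to reside in complete cages, with 7.77 μM of each
component left free — the strongly assembled side of the model's
pseudo-critical transition. The `examples/` scripts walk through each
capability; `python examples/02_fit_contact_energy.py` generates a noisy
synthetic titration at ΔG<sub>con</sub> = 3.6 kcal/mol and recovers

```
best-fit dG_con  : 3.59 kcal/mol (RMSPE 2.7%)
```

i.e. the fit recovers the generating energy within one hundredth of a
kcal/mol at realistic (5%) replicate noise.

## Layout

```
src/nanocage/     architecture, equilibrium, signals, fitting,
                  cooperativity, thermal, synthetic, io
examples/         one narrative script per capability
docs/methods.md   model assumptions, parameters, numerical choices
tests/            pytest suite (unit, property, acceptance)
```
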