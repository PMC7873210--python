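"""Synthetic dataset generators emulating the study's measurement structure.

These generators stand in for raw SEC peak-area tables, chromatograms and
thermal-melt traces.  They run the equilibrium model forward at a chosen
true contact energy, convert species concentrations to normalized SEC
signals (including the low-MW adjustment factor), scale them back to raw
peak areas against explicit reference injections, and apply mean-one
multiplicative lognormal replicate noise.  Every generator is deterministic
under its seed.

The default conditions mirror the study design: component titrations with
one component held at 50 uM and the other varied 12.5-150 uM, equimolar
series across the pseudo-critical region, three technical replicates, six
equimolar 50 uM reference assemblies, and a 5% replicate coefficient of
variation (bracketed by the reported adjustment-factor scatter of ~4-7%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .architecture import SpeciesSpec, default_species_table
from .equilibrium import EquilibriumState, ThermoParams, solve_equilibrium
from .signals import PeakAreaRecord, SignalFactors, predict_normalized_signals
from .thermal import MeltCurve

__all__ = [
    "NoiseModel",
    "gen_reference_injections",
    "gen_cooperativity_dataset",
    "gen_equimolar_series",
    "gen_chromatogram",
    "integrate_chromatogram",
    "gen_melt_curve",
]

#: arbitrary raw-area scale (A280*mL units per unit normalized signal)
RAW_AREA_SCALE = 1000.0

#: default titration grid of the cooperativity design, uM
DEFAULT_VARIABLE_GRID = (12.5, 25.0, 37.5, 50.0, 75.0, 100.0, 125.0, 150.0)

#: default equimolar totals spanning the pseudo-critical region, uM each
DEFAULT_EQUIMOLAR_GRID = (2.5, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0, 37.5, 50.0, 75.0, 100.0)


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise: mean-one multiplicative lognormal at a given CV."""

    cv_multiplicative: float = 0.05
    replicate_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_multiplicative < 0:
            raise ValueError("cv must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def factors(self, rng: np.random.Generator, n: int) -> np.ndarray:
        cv = self.cv_multiplicative
        if cv == 0:
            return np.ones(n)
        sigma = math.sqrt(math.log(1 + cv**2))
        return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n)


def _raw_areas(
    state: EquilibriumState,
    extinction_t: float,
    extinction_p: float,
    factors: SignalFactors,
) -> tuple[float, float]:
    """Raw (high, low) peak areas consistent with the normalization scheme.

    Normalized signals follow the model prediction; raw areas are recovered
    by multiplying with the reference denominators the normalizer will later
    divide by (high: mean total signal of 50 uM equimolar assemblies; low:
    summed separate component injections = f times that total).
    """
    high_n, low_n = predict_normalized_signals(state, extinction_t, extinction_p, factors)
    # the low-MW normalization denominator (separate component injections)
    # is f_a280 times the assembled-run total by definition of the factor
    return high_n * RAW_AREA_SCALE, low_n * factors.f_a280 * RAW_AREA_SCALE


def gen_reference_injections(
    extinction_t: float,
    extinction_p: float,
    factors: SignalFactors,
    noise: NoiseModel,
    rng: np.random.Generator,
    system: str = "synthetic",
    n_assemblies: int = 6,
    n_component_pairs: int = 3,
) -> list[PeakAreaRecord]:
    """Reference injections: equimolar 50 uM assemblies plus separate components.

    Reference assemblies are emitted as the idealized complete-assembly
    signal the normalization equations assume (all material in the high-MW
    peak); real references would carry a small incompleteness bias — see
    the package methods documentation.
    """
    t_ref, p_ref = factors.reference_t0, factors.reference_p0
    high_raw, low_raw = RAW_AREA_SCALE, 0.0
    denom = t_ref * extinction_t + p_ref * extinction_p
    comp_t_raw = factors.f_a280 * RAW_AREA_SCALE * (t_ref * extinction_t) / denom
    comp_p_raw = factors.f_a280 * RAW_AREA_SCALE * (p_ref * extinction_p) / denom
    records = []
    f_hi = noise.factors(rng, n_assemblies)
    f_lo = noise.factors(rng, n_assemblies)
    for i in range(n_assemblies):
        records.append(
            PeakAreaRecord(
                t0=t_ref, p0=p_ref, replicate=i,
                high_mw_area=high_raw * f_hi[i], low_mw_area=low_raw * f_lo[i],
                system=system, series_id="reference_assembly",
                is_reference=True, injection_type="assembly",
            )
        )
    f_t = noise.factors(rng, n_component_pairs)
    f_p = noise.factors(rng, n_component_pairs)
    for i in range(n_component_pairs):
        records.append(
            PeakAreaRecord(
                t0=t_ref, p0=0.0, replicate=i,
                high_mw_area=0.0, low_mw_area=comp_t_raw * f_t[i],
                system=system, series_id="reference_component_t",
                is_reference=True, injection_type="component_t",
            )
        )
        records.append(
            PeakAreaRecord(
                t0=0.0, p0=p_ref, replicate=i,
                high_mw_area=0.0, low_mw_area=comp_p_raw * f_p[i],
                system=system, series_id="reference_component_p",
                is_reference=True, injection_type="component_p",
            )
        )
    return records


def gen_cooperativity_dataset(
    true_dg: float,
    constant_conc: float = 50.0,
    variable_values: Sequence[float] = DEFAULT_VARIABLE_GRID,
    vary: str = "both",
    species_table: Sequence[SpeciesSpec] | None = None,
    extinction_t: float = 20_000.0,
    extinction_p: float = 15_000.0,
    factors: SignalFactors | None = None,
    noise: NoiseModel | None = None,
    system: str = "synthetic",
    include_references: bool = True,
) -> list[PeakAreaRecord]:
    """Synthetic component-titration dataset at a known contact energy.

    One component is held at ``constant_conc`` (uM) while the other sweeps
    ``variable_values``; ``vary`` selects ``"t"``, ``"p"`` or ``"both"``
    series.  Raw peak areas are emitted (ready for ``normalize_peak_areas``)
    together with the reference injections, with multiplicative replicate
    noise.
    """
    if vary not in ("t", "p", "both"):
        raise ValueError("vary must be 't', 'p' or 'both'")
    if species_table is None:
        species_table = default_species_table("inclusive")
    if factors is None:
        factors = SignalFactors(f_a280=0.89, f_a280_sd=0.06)
    if noise is None:
        noise = NoiseModel()
    rng = noise.rng()
    params = ThermoParams(true_dg)
    records: list[PeakAreaRecord] = []
    if include_references:
        records += gen_reference_injections(
            extinction_t, extinction_p, factors, noise, rng, system
        )
    series = ("t", "p") if vary == "both" else (vary,)
    for var in series:
        warm = None
        for v in variable_values:
            t0, p0 = (v, constant_conc) if var == "t" else (constant_conc, v)
            state = solve_equilibrium(t0, p0, params, species_table, initial_free=warm)
            warm = (state.free.free_t, state.free.free_p)
            high_raw, low_raw = _raw_areas(state, extinction_t, extinction_p, factors)
            f_hi = noise.factors(rng, noise.replicate_count)
            f_lo = noise.factors(rng, noise.replicate_count)
            for rep in range(noise.replicate_count):
                records.append(
                    PeakAreaRecord(
                        t0=t0, p0=p0, replicate=rep,
                        high_mw_area=high_raw * f_hi[rep],
                        low_mw_area=low_raw * f_lo[rep],
                        system=system, series_id=f"vary_{var}",
                        injection_type="assembly",
                    )
                )
    return records


def gen_equimolar_series(
    true_dg: float,
    totals: Sequence[float] = DEFAULT_EQUIMOLAR_GRID,
    species_table: Sequence[SpeciesSpec] | None = None,
    extinction_t: float = 20_000.0,
    extinction_p: float = 15_000.0,
    factors: SignalFactors | None = None,
    noise: NoiseModel | None = None,
    system: str = "synthetic",
    include_references: bool = True,
) -> list[PeakAreaRecord]:
    """Synthetic equimolar assembly series ([T]0 = [P]0 sweep), raw areas."""
    if species_table is None:
        species_table = default_species_table("simplified")
    if factors is None:
        factors = SignalFactors(f_a280=0.89, f_a280_sd=0.06)
    if noise is None:
        noise = NoiseModel()
    rng = noise.rng()
    params = ThermoParams(true_dg)
    records: list[PeakAreaRecord] = []
    if include_references:
        records += gen_reference_injections(
            extinction_t, extinction_p, factors, noise, rng, system
        )
    for tot in totals:
        state = solve_equilibrium(tot, tot, params, species_table)
        high_raw, low_raw = _raw_areas(state, extinction_t, extinction_p, factors)
        f_hi = noise.factors(rng, noise.replicate_count)
        f_lo = noise.factors(rng, noise.replicate_count)
        for rep in range(noise.replicate_count):
            records.append(
                PeakAreaRecord(
                    t0=tot, p0=tot, replicate=rep,
                    high_mw_area=high_raw * f_hi[rep],
                    low_mw_area=low_raw * f_lo[rep],
                    system=system, series_id="equimolar",
                    injection_type="assembly",
                )
            )
    return records


def gen_chromatogram(
    state: EquilibriumState,
    extinction_t: float = 20_000.0,
    extinction_p: float = 15_000.0,
    factors: SignalFactors | None = None,
    assembled_center_mL: float = 12.0,
    component_center_mL: float = 16.0,
    peak_sigma_mL: float = 0.5,
    column_volume_mL: float = 24.0,
    points_per_mL: int = 50,
) -> pd.DataFrame:
    """Synthetic SEC chromatogram (elution volume vs A280) for a solved state.

    Gaussian peaks at the assembled and component elution centers with areas
    equal to the state's raw high/low peak areas.  Peaks closer than four
    sigma are rejected (they could not be integrated separately).
    """
    if factors is None:
        factors = SignalFactors()
    if abs(assembled_center_mL - component_center_mL) < 4 * peak_sigma_mL:
        raise ValueError("peaks overlap beyond the separation threshold")
    high_area, low_area = _raw_areas(state, extinction_t, extinction_p, factors)
    vol = np.linspace(0, column_volume_mL, int(column_volume_mL * points_per_mL) + 1)
    def peak(center, area):
        return area / (peak_sigma_mL * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((vol - center) / peak_sigma_mL) ** 2
        )
    a280 = peak(assembled_center_mL, high_area) + peak(component_center_mL, low_area)
    return pd.DataFrame({"volume_mL": vol, "a280": a280})


def integrate_chromatogram(
    trace: pd.DataFrame,
    boundary_mL: float = 14.0,
) -> tuple[float, float]:
    """Trapezoidal (high, low) peak areas split at a valley boundary."""
    vol = trace["volume_mL"].to_numpy()
    sig = trace["a280"].to_numpy()
    early = vol <= boundary_mL
    high = float(np.trapezoid(sig[early], vol[early]))
    low = float(np.trapezoid(sig[~early], vol[~early]))
    return high, low


def gen_melt_curve(
    tm: float,
    amplitude: float = 1.0,
    baseline_drift: float = 0.0,
    noise_sd: float = 0.0,
    assay: str = "cd_mre",
    t_start: float = 25.0,
    t_end: float = 95.0,
    t_step: float = 1.0,
    transition_width: float = 2.0,
    baseline: float = 0.0,
    seed: int = 0,
) -> MeltCurve:
    """Logistic melt trace with linear baseline drift and Gaussian noise.

    signal(T) = baseline + drift (T - t_start) + amplitude / (1 + exp(-(T - tm)/width))
    sampled at ``t_step`` intervals; signed amplitudes give downward
    transitions (e.g. nanoDSF BCM shifts).
    """
    if not (t_start < tm < t_end) and amplitude != 0:
        raise ValueError("tm must lie inside the scan range")
    t = np.arange(t_start, t_end + t_step / 2, t_step)
    s = baseline + baseline_drift * (t - t_start) + amplitude / (
        1 + np.exp(-(t - tm) / transition_width)
    )
    if noise_sd > 0:
        s = s + np.random.default_rng(seed).normal(0, noise_sd, size=t.size)
    return MeltCurve(temperature=tuple(t), signal=tuple(s), assay=assay)
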