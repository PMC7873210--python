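"""Assembly-efficiency statistics: mass fractions, Hill plots, chevron tables.

For a series of equimolar assembly reactions, the assembled mass fraction
Theta and residual free-component concentration L define a Hill plot,
log10(Theta/(1-Theta)) vs log10(L); its slope is the Hill coefficient (a
cooperativity measure) and its x-intercept back-transforms to an apparent
dissociation constant.  Cooperative two-component assembly also produces a
characteristic chevron: plotted against the variable component of a
titration, the residual low-MW signal is V-shaped with its minimum at the
equimolar point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signals import PeakAreaRecord, SignalFactors, propagate_sd

__all__ = ["HillResult", "mass_fraction_from_peaks", "hill_analysis", "chevron_summary"]


@dataclass(frozen=True)
class HillResult:
    """Hill regression summary for an equimolar assembly series."""

    hill_coefficient: float
    apparent_kd: float  # uM, x-intercept back-transformed
    r_squared: float
    points_used: int
    theta_range: tuple[float, float]


def mass_fraction_from_peaks(
    record: PeakAreaRecord,
    factors: SignalFactors,
) -> tuple[float, float, float]:
    """Assembled mass fraction and molar split from one normalized record.

    The low-MW normalized signal is first divided by the adjustment factor
    (undoing the scattering correction so both pools are on the same
    concentration scale), then

        fraction = high / (high + low/f).

    Molar conversion assumes equimolar stoichiometry in both the assembled
    and residual pools.  Returns (fraction, assembled monomer uM, free
    monomer uM).
    """
    if not record.normalized:
        raise ValueError("record must be normalized first")
    if record.t0 != record.p0:
        raise ValueError("molar conversion assumes an equimolar record")
    high = record.high_mw_area
    low = record.low_mw_area / factors.f_a280
    if high + low == 0:
        raise ValueError("record carries no signal")
    frac = high / (high + low)
    total = record.t0 + record.p0
    return frac, frac * total, (1 - frac) * total


def hill_analysis(
    series: Sequence[PeakAreaRecord],
    factors: SignalFactors,
    theta_band: tuple[float, float] = (0.05, 0.95),
) -> HillResult:
    """Hill regression over an equimolar series of normalized records.

    Theta is the assembled mass fraction; L the residual free monomer
    concentration in uM (both components).  Points outside ``theta_band``
    are excluded as saturated (log odds diverge there); at least two usable
    points are required.
    """
    thetas, ls = [], []
    for rec in series:
        frac, _, free_uM = mass_fraction_from_peaks(rec, factors)
        if theta_band[0] < frac < theta_band[1] and free_uM > 0:
            thetas.append(frac)
            ls.append(free_uM)
    if len(thetas) < 2:
        raise ValueError(
            f"only {len(thetas)} points inside the usable Theta band {theta_band}; "
            "series is saturated or too sparse for a Hill regression"
        )
    theta = np.array(thetas)
    log_odds = np.log10(theta / (1 - theta))
    log_l = np.log10(ls)
    fit = stats.linregress(log_l, log_odds)
    if fit.slope == 0:
        raise ValueError("degenerate Hill regression (zero slope)")
    x_intercept = -fit.intercept / fit.slope
    return HillResult(
        hill_coefficient=float(fit.slope),
        apparent_kd=float(10**x_intercept),
        r_squared=float(fit.rvalue**2),
        points_used=len(thetas),
        theta_range=(float(theta.min()), float(theta.max())),
    )


def chevron_summary(
    dataset: Sequence[PeakAreaRecord],
    factors: SignalFactors,
    extinction_t: float = 20_000.0,
    extinction_p: float = 15_000.0,
    equimolar_reference_sd: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Tidy per-series summary of a component-titration (chevron) dataset.

    Groups normalized assembly records by series (one component constant,
    the other varied), reporting the mean and propagated standard deviation
    of the normalized high/low signals versus the variable-component
    concentration, together with the theoretical-yield reference assuming
    quantitative equimolar incorporation of the limiting component.
    ``equimolar_reference_sd`` carries the (high, low) SDs of the equimolar
    normalization reference into the ratio-error propagation.
    """
    records = [r for r in dataset if r.injection_type == "assembly" and not r.is_reference]
    if not records:
        raise ValueError("no assembly records")
    if not all(r.normalized for r in records):
        raise ValueError("chevron summary requires normalized records")
    denom = factors.reference_t0 * extinction_t + factors.reference_p0 * extinction_p
    rows = []
    df = pd.DataFrame(
        {
            "series_id": [r.series_id for r in records],
            "t0": [r.t0 for r in records],
            "p0": [r.p0 for r in records],
            "high": [r.high_mw_area for r in records],
            "low": [r.low_mw_area for r in records],
        }
    )
    for (series_id, t0, p0), grp in df.groupby(["series_id", "t0", "p0"]):
        # which component varies in this series
        t_vals = df.loc[df.series_id == series_id, "t0"].nunique()
        variable = "t" if t_vals > 1 else "p"
        var_conc = t0 if variable == "t" else p0
        limiting = min(t0, p0)
        theo_high = (limiting * extinction_t + limiting * extinction_p) / denom
        theo_low = factors.f_a280 * (
            ((t0 - limiting) * extinction_t + (p0 - limiting) * extinction_p) / denom
        )
        n = len(grp)
        for signal, ref_sd in (("high", equimolar_reference_sd[0]), ("low", equimolar_reference_sd[1])):
            m = grp[signal].mean()
            sd = grp[signal].std(ddof=1) if n > 1 else 0.0
            if m != 0 and ref_sd > 0:
                sd = propagate_sd(m, sd, 1.0, ref_sd)
            rows.append(
                {
                    "series_id": series_id,
                    "variable_component": variable,
                    "variable_uM": var_conc,
                    "t0_uM": t0,
                    "p0_uM": p0,
                    "signal": signal,
                    "mean": m,
                    "sd": sd,
                    "n": n,
                    "theoretical": theo_high if signal == "high" else theo_low,
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["series_id", "signal", "variable_uM"], ignore_index=True
    )
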