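"""Contact-energy fitting by root-mean-squared-percent-error minimization.

The single free parameter of the equilibrium model, the per-contact energy
magnitude dG_con, is fit by scanning a grid of candidate values and
minimizing the RMSPE between model-predicted and experimentally measured
normalized SEC signals:

    percent error = 100 (theoretical - experimental) / experimental
    RMSPE = sqrt(mean(percent error^2))

Model predictions at the experimental (t0, p0) points are computed with the
inverse equilibrium solver; the forward-grid slicing/binning route (keep a
1 uM slab around the plane of interest, average within fixed-width bins) is
retained for figure reproduction and gives the same curves by mass-balance
conservation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .architecture import SpeciesSpec, default_species_table
from .equilibrium import ThermoParams, solve_equilibrium
from .signals import PeakAreaRecord, SignalFactors, predict_normalized_signals

__all__ = ["FitConfig", "FitResult", "slice_and_bin", "rmspe", "fit_dgcon"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Scan range and 3D-to-2D reduction settings for the dG_con fit.

    ``dg_scan`` is (min, max, step) in kcal/mol.  ``slab_width`` (uM) is the
    thickness of the slice kept around the plane of interest when reducing a
    forward grid to a 2D curve; ``bin_width`` (uM) the averaging bin along
    the in-plane coordinate (0.5 for I53-40, 0.0625 for I53-50 equimolar
    fits).  ``restriction`` optionally filters experimental points, e.g.
    ``lambda t0, p0: t0 >= p0`` for I53-50.  ``coarse_step`` enables a
    two-stage scan: coarse pass at this step, then the full-resolution step
    within +/-1.5 coarse steps of the coarse minimum.
    """

    dg_scan: tuple[float, float, float] = (2.5, 5.5, 0.01)
    slab_width: float = 1.0
    bin_width: float = 0.5
    plane: str = "equimolar"
    restriction: Callable[[float, float], bool] | None = None
    coarse_step: float | None = None

    def __post_init__(self) -> None:
        lo, hi, step = self.dg_scan
        if step <= 0 or hi <= lo:
            raise ValueError("invalid dg_scan range")
        if self.slab_width <= 0 or self.bin_width <= 0:
            raise ValueError("slab_width and bin_width must be positive")
        if self.plane not in ("equimolar", "constant_t", "constant_p"):
            raise ValueError(f"unknown plane {self.plane!r}")


@dataclass
class FitResult:
    """Best-fit contact energy with its scan profile and +/-0.25 band curves."""

    dg_best: float
    rmspe_best: float
    rmspe_profile: pd.DataFrame
    band: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_points: int = 0
    n_excluded: int = 0
    boundary_warning: bool = False


def slice_and_bin(
    grid: pd.DataFrame,
    config: FitConfig,
    value_columns: Sequence[str] = ("high_mw_monomer_uM", "low_mw_monomer_uM", "mass_fraction"),
    constant_value: float = 50.0,
) -> pd.DataFrame:
    """Reduce a 3D forward-grid table to a binned 2D curve.

    Keeps grid points within ``slab_width/2`` of the plane of interest (the
    t0 = p0 plane, or the constant-component = ``constant_value`` plane),
    bins the in-plane coordinate at ``bin_width`` and averages every retained
    column per bin.  Empty bins are dropped.
    """
    if grid.empty:
        raise ValueError("empty forward grid")
    t0 = grid["t0_uM"].to_numpy()
    p0 = grid["p0_uM"].to_numpy()
    if config.plane == "equimolar":
        # distance from the t0=p0 plane; in-plane coordinate is the total
        dist = np.abs(t0 - p0) / math.sqrt(2)
        coord = (t0 + p0) / 2
    elif config.plane == "constant_t":
        dist = np.abs(t0 - constant_value)
        coord = p0
    else:
        dist = np.abs(p0 - constant_value)
        coord = t0
    keep = dist <= config.slab_width / 2
    if not keep.any():
        raise ValueError("slab excluded every grid point; widen slab_width")
    sub = grid.loc[keep].copy()
    sub["_bin"] = np.floor(coord[keep] / config.bin_width).astype(int)
    agg = sub.groupby("_bin")[list(value_columns) + ["t0_uM", "p0_uM"]].mean()
    agg.insert(0, "bin_center", (agg.index.to_numpy() + 0.5) * config.bin_width)
    return agg.reset_index(drop=True)


def rmspe(theoretical: Sequence[float], experimental: Sequence[float]) -> float:
    """Root-mean-squared percent error between model and data, in percent.

    Experimental values sit in the denominator (asymmetric by definition);
    zero experimental values are excluded with a warning rather than
    propagating infinities.
    """
    theo = np.asarray(theoretical, dtype=float)
    expv = np.asarray(experimental, dtype=float)
    if theo.shape != expv.shape:
        raise ValueError("theoretical and experimental lengths differ")
    if theo.size == 0:
        raise ValueError("empty input")
    ok = expv != 0
    if not ok.all():
        warnings.warn(f"excluded {int((~ok).sum())} zero experimental values from RMSPE")
    if not ok.any():
        raise ValueError("all experimental values are zero")
    pe = 100.0 * (theo[ok] - expv[ok]) / expv[ok]
    return float(np.sqrt(np.mean(pe**2)))


def _predict_points(
    points: Sequence[tuple[float, float]],
    dg: float,
    species_table: Sequence[SpeciesSpec],
    extinction_t: float,
    extinction_p: float,
    factors: SignalFactors,
    warm: dict[tuple[float, float], tuple[float, float]],
) -> list[tuple[float, float]]:
    params = ThermoParams(dg)
    out = []
    for t0, p0 in points:
        st = solve_equilibrium(t0, p0, params, species_table, initial_free=warm.get((t0, p0)))
        warm[(t0, p0)] = (st.free.free_t, st.free.free_p)
        out.append(predict_normalized_signals(st, extinction_t, extinction_p, factors))
    return out


def fit_dgcon(
    dataset: Sequence[PeakAreaRecord],
    species_table: Sequence[SpeciesSpec] | None = None,
    config: FitConfig | None = None,
    extinction_t: float = 20_000.0,
    extinction_p: float = 15_000.0,
    factors: SignalFactors | None = None,
    band_halfwidth: float = 0.25,
) -> FitResult:
    """Fit dG_con to normalized peak-area data by scanning candidate values.

    For each scanned dG_con, the equilibrium model is solved at every
    experimental (t0, p0) (subject to ``config.restriction``), predicted
    normalized high/low-MW signals are compared with the replicate-averaged
    experimental signals, and the pooled RMSPE over both signals is
    computed.  Returns the argmin with the full profile and model band
    curves at dg_best +/- ``band_halfwidth`` kcal/mol.
    """
    if config is None:
        config = FitConfig()
    if species_table is None:
        species_table = default_species_table("inclusive")
    if factors is None:
        factors = SignalFactors()
    records = [r for r in dataset if r.injection_type == "assembly" and not r.is_reference]
    if not records:
        raise ValueError("no assembly records to fit")
    if not all(r.normalized for r in records):
        raise ValueError("fit requires normalized peak areas")
    if config.restriction is not None:
        records = [r for r in records if config.restriction(r.t0, r.p0)]
        if not records:
            raise ValueError("restriction excluded every record")

    # replicate-averaged experimental signals per concentration point
    df = pd.DataFrame(
        {"t0": [r.t0 for r in records], "p0": [r.p0 for r in records],
         "high": [r.high_mw_area for r in records], "low": [r.low_mw_area for r in records]}
    )
    mean = df.groupby(["t0", "p0"], as_index=False)[["high", "low"]].mean()
    points = list(zip(mean["t0"], mean["p0"]))
    exp_vec = np.concatenate([mean["high"].to_numpy(), mean["low"].to_numpy()])
    nonzero = exp_vec != 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        logger.info("excluding %d zero experimental signals from RMSPE", n_excluded)

    lo, hi, step = config.dg_scan
    warm: dict[tuple[float, float], tuple[float, float]] = {}

    def profile_over(dg_values: np.ndarray) -> np.ndarray:
        vals = np.empty_like(dg_values)
        for i, dg in enumerate(dg_values):
            preds = _predict_points(
                points, float(dg), species_table, extinction_t, extinction_p, factors, warm
            )
            theo_vec = np.concatenate(
                [[h for h, _ in preds], [l for _, l in preds]]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals[i] = rmspe(theo_vec[nonzero], exp_vec[nonzero])
        return vals

    if config.coarse_step is not None and config.coarse_step > step:
        coarse = np.arange(lo, hi + 1e-12, config.coarse_step)
        coarse_prof = profile_over(coarse)
        center = coarse[int(np.argmin(coarse_prof))]
        flo = max(lo, center - 1.5 * config.coarse_step)
        fhi = min(hi, center + 1.5 * config.coarse_step)
        dgs = np.arange(flo, fhi + 1e-12, step)
    else:
        dgs = np.arange(lo, hi + 1e-12, step)
    prof = profile_over(dgs)
    i_best = int(np.argmin(prof))
    dg_best = float(dgs[i_best])
    if np.ptp(prof) < 1e-12:
        logger.warning("flat RMSPE profile; fit is degenerate")
    boundary = i_best in (0, len(dgs) - 1) and (
        abs(dg_best - lo) < step / 2 or abs(dg_best - hi) < step / 2
    )
    if boundary:
        logger.warning("dg_best at scan boundary (%.3f); widen dg_scan", dg_best)

    band: dict[str, pd.DataFrame] = {}
    for tag, dg in (("best", dg_best),
                    ("lower", dg_best - band_halfwidth),
                    ("upper", dg_best + band_halfwidth)):
        if dg <= 0:
            continue
        preds = _predict_points(points, dg, species_table, extinction_t, extinction_p, factors, warm)
        band[tag] = pd.DataFrame(
            {"t0_uM": mean["t0"], "p0_uM": mean["p0"],
             "high_signal": [h for h, _ in preds], "low_signal": [l for _, l in preds]}
        )
    return FitResult(
        dg_best=dg_best,
        rmspe_best=float(prof[i_best]),
        rmspe_profile=pd.DataFrame({"dg_con": dgs, "rmspe": prof}),
        band=band,
        n_points=int(nonzero.sum()),
        n_excluded=n_excluded,
        boundary_warning=bool(boundary),
    )
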