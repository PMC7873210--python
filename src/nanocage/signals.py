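"""SEC A280 peak-signal prediction and normalization.

Model species concentrations are converted to predicted, unitless SEC peak
signals by extinction-weighting the per-component monomer totals of each
molecular-weight class and normalizing against the expected signal of a
50 uM equimolar complete assembly:

    signal_high = ([T]_high e_T + [P]_high e_P) / (50 e_T + 50 e_P)
    signal_low  = F_A280 * ([T]_low e_T + [P]_low e_P) / (50 e_T + 50 e_P)

F_A280 is an empirical adjustment factor (~0.9) accounting for the ~10%
excess A280 signal of assembled material relative to separately injected
components (attributed to scattering); it is the only place that excess is
modeled.  Experimental peak areas are normalized the same way the raw data
were: high-MW (nanomaterial) areas against the mean total signal of 50 uM
equimolar reference assemblies, low-MW areas against the summed signal of
the two components injected separately at 50 uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .equilibrium import EquilibriumState

__all__ = [
    "SignalFactors",
    "PeakAreaRecord",
    "NormalizationMeta",
    "predict_normalized_signals",
    "adjustment_factor",
    "normalize_peak_areas",
    "propagate_sd",
]


@dataclass(frozen=True)
class SignalFactors:
    """Low-MW signal adjustment factor and the normalization reference point.

    ``f_a280`` multiplies predicted low-MW signals (~0.89 for I53-40, ~0.90
    for I53-50); ``f_a280_sd`` is its replicate standard deviation.  The
    reference concentrations define the 50 uM equimolar normalization
    denominator.
    """

    f_a280: float = 1.0
    f_a280_sd: float = 0.0
    reference_t0: float = 50.0
    reference_p0: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.f_a280 <= 1.2):
            raise ValueError("f_a280 outside the physically sensible (0, 1.2]")
        if self.f_a280_sd < 0:
            raise ValueError("f_a280_sd must be >= 0")


@dataclass(frozen=True)
class PeakAreaRecord:
    """One SEC injection: initial concentrations and integrated peak areas.

    ``injection_type`` is ``"assembly"`` for a post-assembly injection (both
    peaks meaningful), or ``"component_t"``/``"component_p"`` for a single
    component injected separately (all signal in the low-MW peak).
    ``is_reference`` marks the 50 uM equimolar assemblies / component
    injections used as normalization denominators.
    """

    t0: float
    p0: float
    replicate: int
    high_mw_area: float
    low_mw_area: float
    system: str = "synthetic"
    series_id: str = ""
    is_reference: bool = False
    injection_type: str = "assembly"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.high_mw_area < 0 or self.low_mw_area < 0:
            raise ValueError("peak areas must be >= 0")
        if self.injection_type not in ("assembly", "component_t", "component_p"):
            raise ValueError(f"unknown injection_type {self.injection_type!r}")


@dataclass(frozen=True)
class NormalizationMeta:
    """Denominators applied during peak-area normalization."""

    high_denominator: float
    low_denominator: float
    n_reference_assemblies: int
    n_component_injections: int


def predict_normalized_signals(
    state: EquilibriumState,
    extinction_t: float,
    extinction_p: float,
    factors: SignalFactors,
) -> tuple[float, float]:
    """Predicted (high-MW, low-MW) normalized signals for a solved state."""
    if extinction_t <= 0 or extinction_p <= 0:
        raise ValueError("extinction coefficients must be positive")
    denom = factors.reference_t0 * extinction_t + factors.reference_p0 * extinction_p
    if denom == 0:
        raise ValueError("zero reference denominator")
    high = (state.t_high_uM * extinction_t + state.p_high_uM * extinction_p) / denom
    low = factors.f_a280 * (
        (state.t_low_uM * extinction_t + state.p_low_uM * extinction_p) / denom
    )
    return high, low


def adjustment_factor(
    component_signals: Sequence[float],
    assembled_signals: Sequence[float],
    component_sds: tuple[float, float] | None = None,
    assembled_sd: float = 0.0,
) -> SignalFactors:
    """Estimate F_A280 from reference injections.

    ``component_signals`` are summed A280 signals (trimer + pentamer) of the
    two components injected separately at 50 uM, one entry per replicate
    pair; ``assembled_signals`` are summed (high + low) signals of 50 uM
    equimolar post-assembly injections.  f = mean(components)/mean(assembled);
    its standard deviation follows from the replicate ratio propagation.
    """
    comp = np.asarray(component_signals, dtype=float)
    asmb = np.asarray(assembled_signals, dtype=float)
    if comp.size == 0 or asmb.size == 0:
        raise ValueError("need at least one replicate of each reference")
    if asmb.mean() == 0:
        raise ValueError("zero assembled reference signal")
    f = comp.mean() / asmb.mean()
    comp_sd = comp.std(ddof=1) if comp.size > 1 else 0.0
    asmb_sd = asmb.std(ddof=1) if asmb.size > 1 else 0.0
    if comp.mean() != 0:
        sd = propagate_sd(comp.mean(), comp_sd, asmb.mean(), asmb_sd)
    else:
        sd = 0.0
    return SignalFactors(f_a280=f, f_a280_sd=sd)


def normalize_peak_areas(
    dataset: Iterable[PeakAreaRecord],
    reference: Iterable[PeakAreaRecord] | None = None,
) -> tuple[list[PeakAreaRecord], NormalizationMeta]:
    """Normalize raw peak areas against the 50 uM reference injections.

    High-MW areas are divided by the mean total (high + low) signal of the
    equimolar reference assemblies; low-MW areas by the summed mean signals
    of the two separate component injections.  References may be embedded in
    ``dataset`` (``is_reference=True``) or passed separately.  Normalizing an
    already-normalized dataset is an error, not a silent no-op.
    """
    records = list(dataset)
    refs = [r for r in (reference if reference is not None else records) if r.is_reference]
    if any(r.normalized for r in records):
        raise ValueError("dataset already normalized; refusing to normalize twice")
    ref_assemblies = [r for r in refs if r.injection_type == "assembly"]
    comp_t = [r for r in refs if r.injection_type == "component_t"]
    comp_p = [r for r in refs if r.injection_type == "component_p"]
    if not ref_assemblies:
        raise ValueError("no reference equimolar assembly injections found")
    if not comp_t or not comp_p:
        raise ValueError("need separate component injections of both components")
    high_den = float(np.mean([r.high_mw_area + r.low_mw_area for r in ref_assemblies]))
    low_den = float(
        np.mean([r.low_mw_area + r.high_mw_area for r in comp_t])
        + np.mean([r.low_mw_area + r.high_mw_area for r in comp_p])
    )
    if high_den == 0 or low_den == 0:
        raise ValueError("zero normalization denominator")
    out = [
        replace(
            r,
            high_mw_area=r.high_mw_area / high_den,
            low_mw_area=r.low_mw_area / low_den,
            normalized=True,
        )
        for r in records
    ]
    meta = NormalizationMeta(
        high_denominator=high_den,
        low_denominator=low_den,
        n_reference_assemblies=len(ref_assemblies),
        n_component_injections=len(comp_t) + len(comp_p),
    )
    return out, meta


def propagate_sd(x_mean: float, x_sd: float, e_mean: float, e_sd: float) -> float:
    """Standard deviation of the ratio f = X/E from the means and SDs.

    StdDev = |X/E| sqrt((sX/X)^2 + (sE/E)^2), the first-order propagation
    used when signals are normalized to a replicate-averaged reference whose
    own scatter must be carried through.
    """
    if x_mean == 0 or e_mean == 0:
        raise ValueError("ratio SD undefined for zero means")
    f = x_mean / e_mean
    return abs(f) * math.sqrt((x_sd / x_mean) ** 2 + (e_sd / e_mean) ** 2)
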