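"""Dataset readers/writers, system presets, and the analysis pipeline.

Peak-area CSV schema (one row per SEC injection):

    system, series_id, t0_uM, p0_uM, replicate, high_mw_area, low_mw_area,
    is_reference, injection_type

Melt-curve CSV: comment headers ``# assay:``, ``# sample:``, ``# ratio:``
followed by ``temperature_C, signal`` columns.

``run_pipeline`` ties normalization, contact-energy fitting and the
cooperativity statistics into one reproducible run driven by a
:class:`RunConfig`; all floats are serialized with 12 significant digits so
read/write round trips are faithful.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd
import yaml

from . import __version__
from .architecture import SpeciesSpec, default_species_table, species_table_from_dicts
from .cooperativity import chevron_summary, hill_analysis
from .fitting import FitConfig, fit_dgcon
from .signals import PeakAreaRecord, SignalFactors, normalize_peak_areas
from .thermal import MeltCurve

__all__ = [
    "PEAK_CSV_COLUMNS",
    "SYSTEM_PRESETS",
    "RunConfig",
    "load_peak_dataset",
    "save_peak_dataset",
    "load_melt_curve",
    "save_melt_curve",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

PEAK_CSV_COLUMNS = [
    "system", "series_id", "t0_uM", "p0_uM", "replicate",
    "high_mw_area", "low_mw_area", "is_reference", "injection_type",
]


def _t0_ge_p0(t0: float, p0: float) -> bool:
    return t0 >= p0


@dataclass(frozen=True)
class SystemPreset:
    """Published per-system analysis defaults."""

    factors: SignalFactors
    bin_width: float
    restriction: Callable[[float, float], bool] | None


#: analysis defaults for the two characterized systems; "custom" supplies none
SYSTEM_PRESETS: dict[str, SystemPreset] = {
    "I53-40": SystemPreset(
        factors=SignalFactors(f_a280=0.89, f_a280_sd=0.06),
        bin_width=0.5,
        restriction=None,
    ),
    # the I53-50 fit considers only points with t0 >= p0 (the cooperative regime)
    "I53-50": SystemPreset(
        factors=SignalFactors(f_a280=0.90, f_a280_sd=0.04),
        bin_width=0.0625,
        restriction=_t0_ge_p0,
    ),
}


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    system: str = "custom"
    data_path: str | None = None
    extinction_t: float = 20_000.0
    extinction_p: float = 15_000.0
    factors: SignalFactors | None = None
    species_model: str = "inclusive"
    species_table: list[SpeciesSpec] | None = None
    dg_scan: tuple[float, float, float] = (2.5, 5.5, 0.01)
    coarse_step: float | None = 0.1
    output_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.system not in ("custom", *SYSTEM_PRESETS):
            raise ValueError(f"unknown system {self.system!r}")
        preset = SYSTEM_PRESETS.get(self.system)
        if self.factors is None:
            self.factors = preset.factors if preset else SignalFactors()

    @property
    def restriction(self) -> Callable[[float, float], bool] | None:
        preset = SYSTEM_PRESETS.get(self.system)
        return preset.restriction if preset else None

    @property
    def bin_width(self) -> float:
        preset = SYSTEM_PRESETS.get(self.system)
        return preset.bin_width if preset else 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text())
        if "factors" in obj and obj["factors"] is not None:
            obj["factors"] = SignalFactors(**obj["factors"])
        if obj.get("species_table"):
            obj["species_table"] = species_table_from_dicts(obj["species_table"])
        if "dg_scan" in obj:
            obj["dg_scan"] = tuple(obj["dg_scan"])
        return cls(**obj)


def load_peak_dataset(path: str | Path) -> list[PeakAreaRecord]:
    """Read and validate a peak-area CSV into records.

    Schema violations are reported with the offending row number; comment
    lines (``#``) carry provenance metadata and are skipped.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PEAK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                PeakAreaRecord(
                    t0=float(row.t0_uM),
                    p0=float(row.p0_uM),
                    replicate=int(row.replicate),
                    high_mw_area=float(row.high_mw_area),
                    low_mw_area=float(row.low_mw_area),
                    system=str(row.system),
                    series_id=str(row.series_id),
                    is_reference=bool(row.is_reference),
                    injection_type=str(row.injection_type),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} row {i + 2}: {exc}") from exc
    return records


def save_peak_dataset(
    records: Sequence[PeakAreaRecord],
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write records to the peak-area CSV schema (12 significant digits)."""
    df = pd.DataFrame(
        {
            "system": [r.system for r in records],
            "series_id": [r.series_id for r in records],
            "t0_uM": [r.t0 for r in records],
            "p0_uM": [r.p0 for r in records],
            "replicate": [r.replicate for r in records],
            "high_mw_area": [r.high_mw_area for r in records],
            "low_mw_area": [r.low_mw_area for r in records],
            "is_reference": [r.is_reference for r in records],
            "injection_type": [r.injection_type for r in records],
        }
    )
    path = Path(path)
    with path.open("w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def load_melt_curve(path: str | Path) -> MeltCurve:
    """Read a melt-curve CSV with ``# assay:``-style comment headers."""
    meta = {"assay": "cd_mre", "sample": "", "ratio": ""}
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition(":")
            if key.strip() in meta:
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    if not {"temperature_C", "signal"} <= set(df.columns):
        raise ValueError(f"{path}: expected temperature_C and signal columns")
    return MeltCurve(
        temperature=tuple(df["temperature_C"].astype(float)),
        signal=tuple(df["signal"].astype(float)),
        assay=meta["assay"], sample=meta["sample"], ratio=meta["ratio"],
    )


def save_melt_curve(curve: MeltCurve, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# assay: {curve.assay}\n# sample: {curve.sample}\n# ratio: {curve.ratio}\n")
        pd.DataFrame({"temperature_C": curve.t, "signal": curve.s}).to_csv(
            fh, index=False, float_format="%.12g"
        )


def run_pipeline(
    config: RunConfig,
    records: Sequence[PeakAreaRecord] | None = None,
) -> dict:
    """Normalize, fit the contact energy, and compute cooperativity statistics.

    Records come from ``config.data_path`` unless passed directly.  Returns a
    result bundle (fit result, Hill result where an equimolar series exists,
    chevron table, normalization metadata, JSON-serializable summary); when
    ``config.output_dir`` is set, intermediate tables and the summary are
    persisted there.
    """
    logging.basicConfig(level=config.log_level)
    if records is None:
        if config.data_path is None:
            raise ValueError("no dataset: set config.data_path or pass records")
        records = load_peak_dataset(config.data_path)
    if not records:
        raise ValueError("empty dataset")

    try:
        normalized, norm_meta = normalize_peak_areas(records)
    except ValueError as exc:
        raise ValueError(f"normalization stage failed: {exc}") from exc

    species_table = config.species_table or default_species_table(config.species_model)
    fit_cfg = FitConfig(
        dg_scan=config.dg_scan,
        bin_width=config.bin_width,
        restriction=config.restriction,
        coarse_step=config.coarse_step,
    )
    if config.restriction is not None:
        logger.info("system %s: applying fit restriction on (t0, p0)", config.system)
    try:
        fit = fit_dgcon(
            normalized,
            species_table=species_table,
            config=fit_cfg,
            extinction_t=config.extinction_t,
            extinction_p=config.extinction_p,
            factors=config.factors,
        )
    except ValueError as exc:
        raise ValueError(f"fitting stage failed: {exc}") from exc

    equimolar = [
        r for r in normalized
        if r.injection_type == "assembly" and not r.is_reference and r.t0 == r.p0
    ]
    hill = None
    if len({r.t0 for r in equimolar}) >= 2:
        try:
            hill = hill_analysis(equimolar, config.factors)
        except ValueError as exc:
            logger.warning("Hill stage skipped: %s", exc)
    chevron = chevron_summary(
        normalized, config.factors, config.extinction_t, config.extinction_p
    )

    summary = {
        "version": __version__,
        "system": config.system,
        "dg_best": fit.dg_best,
        "rmspe_best": fit.rmspe_best,
        "n_points": fit.n_points,
        "restriction_applied": config.restriction is not None,
        "f_a280": config.factors.f_a280,
        "dg_scan": list(config.dg_scan),
        "hill": None if hill is None else {
            "hill_coefficient": hill.hill_coefficient,
            "apparent_kd_uM": hill.apparent_kd,
            "r_squared": hill.r_squared,
            "points_used": hill.points_used,
        },
        "normalization": asdict(norm_meta),
    }
    result = {
        "fit": fit,
        "hill": hill,
        "chevron": chevron,
        "normalization": norm_meta,
        "summary": summary,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        fit.rmspe_profile.to_csv(out / "rmspe_profile.csv", index=False, float_format="%.12g")
        chevron.to_csv(out / "chevron.csv", index=False, float_format="%.12g")
        for tag, curve in fit.band.items():
            curve.to_csv(out / f"model_band_{tag}.csv", index=False, float_format="%.12g")
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return result
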