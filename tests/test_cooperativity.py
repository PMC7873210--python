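"""Mass fractions from peaks, Hill regression, and chevron summaries."""

import numpy as np
import pytest

from nanocage.architecture import default_species_table
from nanocage.cooperativity import chevron_summary, hill_analysis, mass_fraction_from_peaks
from nanocage.equilibrium import ThermoParams, solve_equilibrium
from nanocage.signals import (
    PeakAreaRecord,
    SignalFactors,
    normalize_peak_areas,
    predict_normalized_signals,
    propagate_sd,
)
from nanocage.synthetic import NoiseModel, gen_cooperativity_dataset


def norm_record(high, low, t0=50.0, p0=50.0, **kw):
    return PeakAreaRecord(
        t0=t0, p0=p0, replicate=kw.pop("replicate", 0),
        high_mw_area=high, low_mw_area=low, normalized=True, **kw,
    )


class TestMassFractionFromPeaks:
    def test_fully_assembled(self, unit_factors):
        frac, assembled, free = mass_fraction_from_peaks(norm_record(1.0, 0.0), unit_factors)
        assert frac == 1.0 and assembled == 100.0 and free == 0.0

    def test_fully_free_with_adjustment(self, i53_40_factors):
        frac, assembled, free = mass_fraction_from_peaks(
            norm_record(0.0, 0.89), i53_40_factors
        )
        assert frac == 0.0
        assert free == pytest.approx(100.0)

    def test_balanced_split(self, i53_40_factors):
        frac, *_ = mass_fraction_from_peaks(norm_record(0.5, 0.445), i53_40_factors)
        assert frac == pytest.approx(0.5, rel=1e-12)

    def test_round_trip_through_signal_prediction(self, simplified_table, unit_factors):
        """Peaks built from the model's own signals return its mass fraction."""
        for tot, dg in ((100.0, 3.6), (30.0, 4.0)):
            state = solve_equilibrium(tot, tot, ThermoParams(dg), simplified_table)
            high, low = predict_normalized_signals(state, 9_000, 9_000, unit_factors)
            frac, *_ = mass_fraction_from_peaks(
                norm_record(high, low, t0=tot, p0=tot), unit_factors
            )
            assert frac == pytest.approx(state.mass_fraction_assembled, abs=1e-9)

    def test_requires_equimolar_and_signal(self, unit_factors):
        with pytest.raises(ValueError, match="equimolar"):
            mass_fraction_from_peaks(norm_record(1.0, 0.0, t0=60.0, p0=30.0), unit_factors)
        with pytest.raises(ValueError, match="signal"):
            mass_fraction_from_peaks(norm_record(0.0, 0.0), unit_factors)


class TestHillAnalysis:
    def test_exact_hill_law_recovered_to_machine_precision(self, unit_factors):
        """Theta/(1-Theta) = (L/10)^3 gives slope 3 and apparent KD 10 uM."""
        records = []
        for L in (4.0, 7.0, 10.0, 14.0, 20.0):
            theta = (L / 10) ** 3 / (1 + (L / 10) ** 3)
            # choose the total so the residual free monomer equals L exactly
            total = L / (2 * (1 - theta))
            records.append(norm_record(theta, 1 - theta, t0=total, p0=total))
        result = hill_analysis(records, unit_factors)
        assert result.hill_coefficient == pytest.approx(3.0, rel=1e-9)
        assert result.apparent_kd == pytest.approx(10.0, rel=1e-9)
        assert result.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_single_point_underdetermined(self, unit_factors):
        with pytest.raises(ValueError, match="points"):
            hill_analysis([norm_record(0.5, 0.5)], unit_factors)

    def test_saturated_series_rejected(self, unit_factors):
        records = [
            norm_record(0.999, 0.001, t0=t, p0=t) for t in (50.0, 100.0, 150.0)
        ]
        with pytest.raises(ValueError, match="saturated|points"):
            hill_analysis(records, unit_factors)

    def test_model_curves_are_cooperative(self, simplified_table, unit_factors):
        """Noiseless model-generated equimolar curves have Hill slope > 1
        for any positive contact energy — cooperativity is intrinsic."""
        for dg in (1.0, 2.0, 3.6):
            # center the sampled totals on this dg's pseudo-critical point
            lo, hi = -3.0, 12.0  # log10 total, uM
            for _ in range(60):
                mid = (lo + hi) / 2
                mf = solve_equilibrium(
                    10**mid, 10**mid, ThermoParams(dg), simplified_table
                ).mass_fraction_assembled
                lo, hi = (lo, mid) if mf > 0.5 else (mid, hi)
            midpoint = 10 ** ((lo + hi) / 2)
            records = []
            for tot in midpoint * np.geomspace(0.4, 2.5, 16):
                state = solve_equilibrium(float(tot), float(tot), ThermoParams(dg), simplified_table)
                high, low = predict_normalized_signals(state, 9_000, 9_000, unit_factors)
                records.append(norm_record(high, low, t0=float(tot), p0=float(tot)))
            result = hill_analysis(records, unit_factors)
            assert result.hill_coefficient > 1.0
            assert result.apparent_kd > 0


class TestChevronSummary:
    @pytest.fixture()
    def normalized_titration(self):
        factors = SignalFactors(f_a280=0.89)
        records = gen_cooperativity_dataset(
            3.6, noise=NoiseModel(cv_multiplicative=0.0), factors=factors
        )
        normalized, _ = normalize_peak_areas(records)
        return normalized, factors

    def test_low_signal_minimum_at_equimolar(self, normalized_titration):
        normalized, factors = normalized_titration
        table = chevron_summary(normalized, factors)
        low_t = table[(table.signal == "low") & (table.series_id == "vary_t")]
        i_min = low_t["mean"].idxmin()
        assert low_t.loc[i_min, "variable_uM"] == 50.0
        # theoretical yield reference also dips to zero residual at equimolar
        assert low_t.loc[i_min, "theoretical"] == pytest.approx(0.0)

    def test_high_signal_plateaus_past_equimolar(self):
        # under the simplified model the limiting trimer caps assembly, so
        # excess pentamer cannot grow the high-MW signal
        factors = SignalFactors(f_a280=0.89)
        records = gen_cooperativity_dataset(
            3.6, noise=NoiseModel(cv_multiplicative=0.0), factors=factors,
            species_table=default_species_table("simplified"),
        )
        normalized, _ = normalize_peak_areas(records)
        table = chevron_summary(normalized, factors)
        high_p = table[(table.signal == "high") & (table.series_id == "vary_p")]
        vals = high_p.sort_values("variable_uM")
        means = vals["mean"].to_numpy()
        # gains shrink as trimer becomes limiting ...
        assert np.all(np.diff(means, 2) < 0)
        # ... and past ~1.5x equimolar the signal is flat within 5%
        above = vals[vals.variable_uM >= 75.0]["mean"].to_numpy()
        assert np.ptp(above) / above.mean() < 0.05

    def test_error_bars_match_ratio_propagation(self):
        factors = SignalFactors(f_a280=0.89)
        records = gen_cooperativity_dataset(
            3.6, variable_values=(25.0, 50.0), vary="t",
            noise=NoiseModel(cv_multiplicative=0.05, seed=11), factors=factors,
        )
        normalized, _ = normalize_peak_areas(records)
        ref_sd = (0.03, 0.02)
        table = chevron_summary(normalized, factors, equimolar_reference_sd=ref_sd)
        row = table[(table.signal == "high") & (table.variable_uM == 25.0)].iloc[0]
        grp = [
            r.high_mw_area for r in normalized
            if not r.is_reference and r.t0 == 25.0 and r.series_id == "vary_t"
        ]
        expected = propagate_sd(float(np.mean(grp)), float(np.std(grp, ddof=1)), 1.0, ref_sd[0])
        assert row["sd"] == pytest.approx(expected, rel=1e-12)
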