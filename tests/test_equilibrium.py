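"""Log-space mass-action laws, the inverse solver, and their invariants.

Two independent oracles are used: 50-digit arbitrary-precision direct
evaluation of the species laws (mpmath), and a bracketed scalar bisection on
the equimolar simplified-model mass balance (independent of the Newton
solver under test).
"""

import math

import mpmath
import numpy as np
import pytest

from nanocage.equilibrium import (
    GAS_CONSTANT_KCAL,
    FreeState,
    ThermoParams,
    evaluate_free_state,
    forward_grid,
    log_species_concentration,
    mass_fraction_assembled,
    solve_equilibrium,
    totals_from_free,
)

mpmath.mp.dps = 50


def mp_species_concentration(species, free_t_uM, free_p_uM, dg, temperature=296.0):
    """Arbitrary-precision direct evaluation of the species mass-action law."""
    a, b = species.n_trimers, species.n_pentamers
    t = mpmath.mpf(free_t_uM)
    p = mpmath.mpf(free_p_uM)
    val = (
        mpmath.mpf(3) ** a
        * mpmath.mpf(5) ** b
        * (t / 3_000_000) ** a
        * (p / 5_000_000) ** b
        * mpmath.e ** (species.contacts * mpmath.mpf(dg) / (GAS_CONSTANT_KCAL * temperature))
        / species.symmetry
    )
    return val


def bisect_equimolar_mass_fraction(total_uM, dg, tol=1e-14):
    """Scalar-bisection oracle for the simplified model at t0 = p0.

    At equimolar totals the free concentrations are equal; mass balance is
    total = 60 * [cage](free) * 1e6 + free, monotone in free, so bisection
    on free is an exact independent solution.
    """
    g = dg / (GAS_CONSTANT_KCAL * 296.0)

    def t0_of_free(free):
        ln_cage = 20 * math.log(free / 1e6) + 12 * math.log(free / 1e6) + 60 * g - math.log(60)
        return 60 * math.exp(ln_cage) * 1e6 + free

    lo, hi = 0.0, total_uM
    while hi - lo > tol * total_uM:
        mid = (lo + hi) / 2
        if t0_of_free(mid) > total_uM:
            hi = mid
        else:
            lo = mid
    free = (lo + hi) / 2
    return (total_uM - free) / total_uM


class TestSpeciesLaw:
    def test_t3p5_unit_boltzmann(self, inclusive_table):
        t3p5 = next(s for s in inclusive_table if s.species_id == "T3P5")
        ln_c = log_species_concentration(t3p5, FreeState(3.0, 5.0), ThermoParams(0.0))
        # 3 * 5 * (3/3e6) * (5/5e6) / 1 = 1.5e-11 M
        assert ln_c == pytest.approx(math.log(1.5e-11), abs=1e-12)

    def test_complete_cage_against_mp_oracle(self, inclusive_table):
        cage = inclusive_table[0]
        ln_c = log_species_concentration(cage, FreeState(5.0, 5.0), ThermoParams(3.6))
        oracle = float(mpmath.log(mp_species_concentration(cage, 5.0, 5.0, 3.6)))
        assert ln_c == pytest.approx(oracle, rel=1e-12)
        assert ln_c == pytest.approx(-27.4736, abs=1e-3)  # ~1.2e-12 M

    def test_t57p60_closed_form(self, inclusive_table):
        """The single-trimeric-void law: exponent 57, prefactor 3^19 5^12, divisor 3."""
        sp = next(s for s in inclusive_table if s.species_id == "T57P60")
        ft, fp, dg = 2.7, 11.0, 4.1
        expected = (
            19 * math.log(3) + 12 * math.log(5)
            + 19 * math.log(ft / 3e6) + 12 * math.log(fp / 5e6)
            + 57 * dg / (GAS_CONSTANT_KCAL * 296.0) - math.log(3)
        )
        got = log_species_concentration(sp, FreeState(ft, fp), ThermoParams(dg))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_oracle_equivalence_on_random_states(self, inclusive_table, rng):
        """Log-domain evaluation matches 50-digit direct evaluation to 1e-10."""
        for _ in range(10):
            ft, fp = rng.uniform(0.01, 30, size=2)
            dg = rng.uniform(0.0, 8.0)
            for sp in inclusive_table:
                ln_c = log_species_concentration(sp, FreeState(ft, fp), ThermoParams(dg))
                oracle = mpmath.log(mp_species_concentration(sp, ft, fp, dg))
                assert abs(ln_c - float(oracle)) <= 1e-10 * max(1.0, abs(float(oracle)))

    def test_zero_free_component(self, inclusive_table):
        cage = inclusive_table[0]
        assert log_species_concentration(cage, FreeState(0.0, 5.0), ThermoParams(3.6)) == -math.inf

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            FreeState(-1.0, 5.0)


class TestTotals:
    def test_all_free_zero(self, inclusive_table):
        assert totals_from_free(FreeState(0, 0), ThermoParams(3.6), inclusive_table) == (0, 0)

    def test_simplified_closed_form(self, simplified_table):
        free = FreeState(5.0, 5.0)
        params = ThermoParams(3.6)
        ln_cage = log_species_concentration(simplified_table[0], free, params)
        t0, p0 = totals_from_free(free, params, simplified_table)
        assert t0 == pytest.approx(60 * math.exp(ln_cage) * 1e6 + 5.0, rel=1e-12)
        # assembled T-monomer term is 60 * ~1.17e-12 M = ~7e-5 uM: totals
        # sit barely above the free concentration
        assert t0 == pytest.approx(5.00007, abs=2e-5)
        assert p0 == pytest.approx(t0)

    def test_totals_match_state_bookkeeping(self, inclusive_table):
        free = FreeState(3.0, 9.0)
        params = ThermoParams(4.2)
        state = evaluate_free_state(free, params, inclusive_table)
        t0, p0 = totals_from_free(free, params, inclusive_table)
        assert state.t0_uM == pytest.approx(t0, rel=1e-12)
        assert state.p0_uM == pytest.approx(p0, rel=1e-12)


class TestInverseSolver:
    @pytest.mark.parametrize(
        "total,expected_mf", [(100.0, 0.92), (50.0, 0.85)]
    )
    def test_equimolar_against_bisection_oracle(self, simplified_table, total, expected_mf):
        state = solve_equilibrium(total, total, ThermoParams(3.6), simplified_table)
        oracle_mf = bisect_equimolar_mass_fraction(total, 3.6)
        assert state.mass_fraction_assembled == pytest.approx(oracle_mf, abs=1e-9)
        assert state.mass_fraction_assembled == pytest.approx(expected_mf, abs=0.01)

    def test_no_driving_energy_stays_free(self, inclusive_table):
        state = solve_equilibrium(1000.0, 1000.0, ThermoParams(0.0), inclusive_table)
        assert state.mass_fraction_assembled < 1e-6

    def test_conservation_on_random_grid(self, inclusive_table, rng):
        for _ in range(25):
            t0 = float(rng.uniform(0.5, 300))
            p0 = float(rng.uniform(0.5, 300))
            dg = float(rng.uniform(0.0, 8.0))
            st = solve_equilibrium(t0, p0, ThermoParams(dg), inclusive_table)
            assert abs(st.t0_uM - t0) / t0 <= 1e-9
            assert abs(st.p0_uM - p0) / p0 <= 1e-9

    def test_warm_start_matches_cold(self, inclusive_table):
        params = ThermoParams(3.8)
        cold = solve_equilibrium(40, 70, params, inclusive_table)
        warm = solve_equilibrium(40, 70, params, inclusive_table, initial_free=(1.0, 30.0))
        assert warm.free.free_t == pytest.approx(cold.free.free_t, rel=1e-8)
        assert warm.free.free_p == pytest.approx(cold.free.free_p, rel=1e-8)

    def test_degenerate_single_component(self, inclusive_table):
        state = solve_equilibrium(0.0, 80.0, ThermoParams(5.0), inclusive_table)
        assert state.free.free_p == 80.0
        assert state.high_mw_monomer_uM == 0.0

    def test_monotone_in_dg(self, simplified_table):
        mfs = [
            solve_equilibrium(60, 60, ThermoParams(dg), simplified_table).mass_fraction_assembled
            for dg in (2.0, 3.0, 3.5, 4.0, 5.0, 7.0)
        ]
        assert all(b >= a for a, b in zip(mfs, mfs[1:]))

    def test_monotone_in_total(self, simplified_table):
        mfs = [
            solve_equilibrium(tot, tot, ThermoParams(3.6), simplified_table).mass_fraction_assembled
            for tot in (5, 10, 20, 40, 80, 160)
        ]
        assert all(b >= a for a, b in zip(mfs, mfs[1:]))

    def test_extreme_regimes_no_overflow(self, inclusive_table):
        # strong driving energy and trace concentrations must stay finite
        st = solve_equilibrium(1e-6, 1e-6, ThermoParams(10.0), inclusive_table)
        assert 0 <= st.mass_fraction_assembled <= 1
        st = solve_equilibrium(500.0, 500.0, ThermoParams(10.0), inclusive_table)
        assert st.mass_fraction_assembled > 0.999

    def test_simplified_inclusive_agreement_near_equimolar(
        self, simplified_table, inclusive_table
    ):
        """Intermediates stay scarce at equimolar input: the two species sets
        agree to <2% mass fraction everywhere at dg >= 3, and to <1% at
        dg >= 3.5 (worst case sits at the pseudo-critical midpoint)."""
        worst_all, worst_35 = 0.0, 0.0
        for dg in (3.0, 3.25, 3.5, 3.75, 4.0, 4.5, 5.0):
            for tot in (5, 15, 30, 60, 100, 200):
                a = solve_equilibrium(tot, tot, ThermoParams(dg), simplified_table)
                b = solve_equilibrium(tot, tot, ThermoParams(dg), inclusive_table)
                d = abs(a.mass_fraction_assembled - b.mass_fraction_assembled)
                worst_all = max(worst_all, d)
                if dg >= 3.5:
                    worst_35 = max(worst_35, d)
        assert worst_all < 0.02
        assert worst_35 < 0.01


class TestForwardGrid:
    def test_single_point_matches_direct_evaluation(self, inclusive_table):
        params = ThermoParams(3.6)
        grid = forward_grid([4.0], [6.0], params, inclusive_table)
        state = evaluate_free_state(FreeState(4.0, 6.0), params, inclusive_table)
        assert len(grid) == 1
        assert grid.loc[0, "t0_uM"] == pytest.approx(state.t0_uM, rel=1e-12)
        assert grid.loc[0, "T60P60"] == pytest.approx(state.species_conc["T60P60"], rel=1e-12)

    def test_totals_monotone_along_axes(self, inclusive_table):
        vals = np.linspace(1, 10, 10)
        grid = forward_grid(vals, vals, ThermoParams(3.6), inclusive_table)
        pivot = grid.pivot(index="free_t_uM", columns="free_p_uM", values="t0_uM")
        assert (pivot.diff(axis=0).iloc[1:] > 0).all().all()
        assert (pivot.diff(axis=1).iloc[:, 1:] > 0).all().all()

    def test_mass_fraction_spans_transition(self, simplified_table):
        grid = forward_grid(
            np.linspace(0.1, 10, 8), np.linspace(0.1, 10, 8), ThermoParams(3.6), simplified_table
        )
        # the pseudo-critical transition: nearly nothing assembled at the low
        # end, majority assembled at the high end (scalar-solve endpoints)
        assert grid["mass_fraction"].min() < 0.01
        assert grid["mass_fraction"].max() > 0.8

    def test_rejects_bad_grids(self, inclusive_table):
        with pytest.raises(ValueError):
            forward_grid([], [1.0], ThermoParams(3.6), inclusive_table)
        with pytest.raises(ValueError):
            forward_grid([0.0, 1.0], [1.0], ThermoParams(3.6), inclusive_table)


class TestMassFraction:
    def test_bounds(self, inclusive_table):
        all_free = evaluate_free_state(FreeState(10, 10), ThermoParams(0.0), inclusive_table)
        assert mass_fraction_assembled(all_free) == pytest.approx(0.0, abs=1e-9)

    def test_mw_weighted_variant(self, simplified_table):
        st = solve_equilibrium(100, 100, ThermoParams(3.6), simplified_table)
        counted = mass_fraction_assembled(st)
        weighted = mass_fraction_assembled(st, mw_t=28.0, mw_p=23.0)
        # equimolar high/low split: weighting shifts the fraction only little
        assert weighted == pytest.approx(counted, abs=0.02)

    def test_zero_totals_rejected(self, inclusive_table):
        st = evaluate_free_state(FreeState(0, 0), ThermoParams(3.6), inclusive_table)
        with pytest.raises(ValueError):
            mass_fraction_assembled(st)
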