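"""Multi-component mass-action equilibrium model, evaluated in log space.

Each assembly species T_{3a}P_{5b} with c trimer–pentamer contacts and
rotational symmetry number s obeys the mass-action law

    [T_{3a}P_{5b}] = 3^a 5^b ([T]/3e6)^a ([P]/5e6)^b exp(c dG_con/(R T)) / s

with [T], [P] the free *monomer* concentrations in uM (so [T]/3e6 is the
free trimeric building-block concentration in M), the species concentration
in M, and dG_con the per-contact association free energy stored as a positive
magnitude (favorable association; see note below).  Total monomer balances

    [T]0 = sum_species 3a [species] * 1e6 + [T]
    [P]0 = sum_species 5b [species] * 1e6 + [P]

close the system.  The complete cage (a=20, b=12, c=60, s=60) alone defines
the "simplified" model; adding eight on-pathway intermediates gives the
"inclusive" model.

Sign convention
---------------
The literature quotes dG_con as a positive magnitude inside a Boltzmann
factor written with a negative sign; assembly is favorable, so internally the
exponent is +c*dg_con/(R*T) and larger magnitudes drive more assembly.

Numerical notes
---------------
Prefactors like 3^20 5^12 and concentration products near 1e-190 are
unrepresentable separately in double precision; every species law is
evaluated as a sum of logs and totals via log-sum-exp, so the model is stable
for dg_con up to at least 10 kcal/mol and free concentrations down to
1e-6 uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .architecture import SpeciesSpec, default_species_table

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ThermoParams",
    "FreeState",
    "EquilibriumState",
    "log_species_concentration",
    "totals_from_free",
    "evaluate_free_state",
    "forward_grid",
    "solve_equilibrium",
    "mass_fraction_assembled",
]

#: Gas constant in kcal/(mol K)
GAS_CONSTANT_KCAL = 1.98720e-3

_LN_1E6 = math.log(1e6)


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic inputs: per-contact energy magnitude and temperature.

    ``dg_con`` is the magnitude of the (favorable) per-contact association
    free energy in kcal/mol; ``temperature`` in K (assemblies and models in
    the source system were run at 296 K).
    """

    dg_con: float
    temperature: float = 296.0
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if self.dg_con < 0:
            raise ValueError("dg_con is a magnitude; must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def beta_dg(self) -> float:
        """dg_con/(R T): the per-contact Boltzmann exponent."""
        return self.dg_con / (self.gas_constant * self.temperature)


@dataclass(frozen=True)
class FreeState:
    """Unassembled monomer concentrations in uM."""

    free_t: float
    free_p: float

    def __post_init__(self) -> None:
        if self.free_t < 0 or self.free_p < 0:
            raise ValueError("free concentrations must be >= 0")


@dataclass
class EquilibriumState:
    """Solved equilibrium: free monomers, species concentrations, and splits.

    ``species_conc`` is in M on the species basis; the monomer splits
    (``t_high_uM`` etc.) are per-component monomer-equivalents in uM, with
    free monomers counted in the low-MW pool alongside early intermediates
    and late intermediates counted with the complete cage in the high-MW
    pool (matching SEC elution classes).
    """

    free: FreeState
    species_conc: dict[str, float]
    t0_uM: float
    p0_uM: float
    t_high_uM: float
    p_high_uM: float
    t_low_uM: float
    p_low_uM: float

    @property
    def high_mw_monomer_uM(self) -> float:
        return self.t_high_uM + self.p_high_uM

    @property
    def low_mw_monomer_uM(self) -> float:
        return self.t_low_uM + self.p_low_uM

    @property
    def mass_fraction_assembled(self) -> float:
        return mass_fraction_assembled(self)


def _species_arrays(species_table: Sequence[SpeciesSpec]):
    a = np.array([s.n_trimers for s in species_table], dtype=float)
    b = np.array([s.n_pentamers for s in species_table], dtype=float)
    c = np.array([s.contacts for s in species_table], dtype=float)
    ln_s = np.array([math.log(s.symmetry) for s in species_table])
    return a, b, c, ln_s


def log_species_concentration(
    species: SpeciesSpec, free: FreeState, params: ThermoParams
) -> float:
    """Natural log of one species' molar concentration at given free monomers.

    Returns -inf when a required component is absent.  The prefactor
    3^a 5^b ([T]/3e6)^a collapses to ([T]_M)^a with [T]_M the free monomer
    concentration in M, so the log-law is
    a ln[T]_M + b ln[P]_M + c dg/(RT) - ln s.
    """
    if free.free_t < 0 or free.free_p < 0:
        raise ValueError("free concentrations must be >= 0")
    a, b = species.n_trimers, species.n_pentamers
    if (a > 0 and free.free_t == 0) or (b > 0 and free.free_p == 0):
        return -math.inf
    out = a * (math.log(free.free_t) - _LN_1E6) if a else 0.0
    if b:
        out += b * (math.log(free.free_p) - _LN_1E6)
    out += species.contacts * params.beta_dg - math.log(species.symmetry)
    return out


def _log_totals(
    ln_t_uM: float,
    ln_p_uM: float,
    params: ThermoParams,
    arrays,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """log of (t0, p0) in uM plus softmax weights for the Jacobian."""
    a, b, c, ln_s = arrays
    # ln species conc (M): a(x - ln 1e6) + b(y - ln 1e6) + c g - ln s
    ln_conc = (
        a * (ln_t_uM - _LN_1E6)
        + b * (ln_p_uM - _LN_1E6)
        + c * params.beta_dg
        - ln_s
    )
    # monomer-equivalent uM terms: 3a * conc * 1e6 (and the free term)
    with np.errstate(divide="ignore"):
        t_terms = np.concatenate((ln_conc + np.log(3 * a, where=a > 0, out=np.full_like(a, -np.inf)) + _LN_1E6, [ln_t_uM]))
        p_terms = np.concatenate((ln_conc + np.log(5 * b, where=b > 0, out=np.full_like(b, -np.inf)) + _LN_1E6, [ln_p_uM]))
    ln_t0 = logsumexp(t_terms)
    ln_p0 = logsumexp(p_terms)
    wt = np.exp(t_terms - ln_t0)
    wp = np.exp(p_terms - ln_p0)
    return ln_t0, ln_p0, wt, wp


def totals_from_free(
    free: FreeState,
    params: ThermoParams,
    species_table: Sequence[SpeciesSpec],
) -> tuple[float, float]:
    """Total monomer concentrations (t0, p0) in uM implied by a free state."""
    if free.free_t == 0 and free.free_p == 0:
        return 0.0, 0.0
    t0 = free.free_t
    p0 = free.free_p
    for sp in species_table:
        ln_c = log_species_concentration(sp, free, params)
        if ln_c == -math.inf:
            continue
        conc_uM = math.exp(ln_c) * 1e6
        t0 += 3 * sp.n_trimers * conc_uM
        p0 += 5 * sp.n_pentamers * conc_uM
    return t0, p0


def evaluate_free_state(
    free: FreeState,
    params: ThermoParams,
    species_table: Sequence[SpeciesSpec],
) -> EquilibriumState:
    """Full equilibrium bookkeeping for a given free-monomer state."""
    species_conc: dict[str, float] = {}
    t_high = p_high = 0.0
    t_low = free.free_t
    p_low = free.free_p
    for sp in species_table:
        ln_c = log_species_concentration(sp, free, params)
        conc = 0.0 if ln_c == -math.inf else math.exp(ln_c)
        species_conc[sp.species_id] = conc
        t_mono = 3 * sp.n_trimers * conc * 1e6
        p_mono = 5 * sp.n_pentamers * conc * 1e6
        if sp.mw_class == "high":
            t_high += t_mono
            p_high += p_mono
        else:
            t_low += t_mono
            p_low += p_mono
    return EquilibriumState(
        free=free,
        species_conc=species_conc,
        t0_uM=t_high + t_low,
        p0_uM=p_high + p_low,
        t_high_uM=t_high,
        p_high_uM=p_high,
        t_low_uM=t_low,
        p_low_uM=p_low,
    )


def forward_grid(
    t_free_values: Sequence[float],
    p_free_values: Sequence[float],
    params: ThermoParams,
    species_table: Sequence[SpeciesSpec] | None = None,
) -> pd.DataFrame:
    """Evaluate the model over a grid of free concentrations (uM).

    This is the forward parameterization used to generate 3D partition
    surfaces: linearly spaced free-concentration arrays in, one long-format
    row of totals / species concentrations / MW splits out per grid point.
    """
    t_vals = np.asarray(t_free_values, dtype=float)
    p_vals = np.asarray(p_free_values, dtype=float)
    if t_vals.size == 0 or p_vals.size == 0:
        raise ValueError("free-concentration arrays must be non-empty")
    if not (np.all(np.isfinite(t_vals)) and np.all(np.isfinite(p_vals))):
        raise ValueError("free-concentration arrays must be finite")
    if np.any(t_vals <= 0) or np.any(p_vals <= 0):
        raise ValueError("free-concentration arrays must be strictly positive")
    if species_table is None:
        species_table = default_species_table("inclusive")
    rows = []
    for ft in t_vals:
        for fp in p_vals:
            st = evaluate_free_state(FreeState(ft, fp), params, species_table)
            row = {
                "free_t_uM": ft,
                "free_p_uM": fp,
                "t0_uM": st.t0_uM,
                "p0_uM": st.p0_uM,
            }
            row.update(st.species_conc)
            row["high_mw_monomer_uM"] = st.high_mw_monomer_uM
            row["low_mw_monomer_uM"] = st.low_mw_monomer_uM
            row["mass_fraction"] = st.mass_fraction_assembled
            rows.append(row)
    return pd.DataFrame(rows)


class ConvergenceError(RuntimeError):
    """Raised when the inverse solver cannot reach the requested tolerance."""


def solve_equilibrium(
    t0: float,
    p0: float,
    params: ThermoParams,
    species_table: Sequence[SpeciesSpec] | None = None,
    rtol: float = 1e-12,
    max_iter: int = 200,
    initial_free: tuple[float, float] | None = None,
) -> EquilibriumState:
    """Solve for the free monomer state reproducing totals (t0, p0) in uM.

    Damped Newton iteration on (ln free_t, ln free_p) with the analytic
    Jacobian of the log totals (posynomials, so softmax-weighted exponent
    averages); the residual is the log-ratio of model to target totals.
    Totals are strictly increasing in each free concentration, so the
    solution is unique and independent of the starting point.

    ``initial_free`` provides a warm start (uM), e.g. from a neighboring
    point of a parameter scan.
    """
    if t0 < 0 or p0 < 0 or not (math.isfinite(t0) and math.isfinite(p0)):
        raise ValueError("totals must be finite and non-negative")
    if species_table is None:
        species_table = default_species_table("inclusive")
    if t0 == 0 or p0 == 0:
        # no heteromeric species can form; everything stays free
        return evaluate_free_state(FreeState(t0, p0), params, species_table)

    arrays = _species_arrays(species_table)
    ln_t0_target = math.log(t0)
    ln_p0_target = math.log(p0)

    def residual(x: float, y: float):
        ln_t0, ln_p0, wt, wp = _log_totals(x, y, params, arrays)
        return ln_t0 - ln_t0_target, ln_p0 - ln_p0_target, wt, wp

    if initial_free is not None and initial_free[0] > 0 and initial_free[1] > 0:
        x = math.log(min(initial_free[0], t0))
        y = math.log(min(initial_free[1], p0))
    else:
        # Initialize by bisection on a scale factor along the (t0, p0) ray:
        # the summed log residual is strictly increasing in the scale, and a
        # balanced start keeps the Newton Jacobian well conditioned (starting
        # at free = totals lets one species dominate both totals, which makes
        # the Jacobian rows numerically parallel).
        lo, hi = -80.0, 0.0
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            r1m, r2m, *_ = residual(ln_t0_target + mid, ln_p0_target + mid)
            if r1m + r2m > 0:
                hi = mid
            else:
                lo = mid
            if abs(r1m + r2m) < 0.2:
                break
        x = ln_t0_target + 0.5 * (lo + hi)
        y = ln_p0_target + 0.5 * (lo + hi)

    r1, r2, wt, wp = residual(x, y)
    err = max(abs(r1), abs(r2))
    a, b, *_ = arrays
    a_ext = np.concatenate((a, [1.0]))
    b_ext = np.concatenate((b, [0.0]))
    a_ext_p = np.concatenate((a, [0.0]))
    b_ext_p = np.concatenate((b, [1.0]))
    for _ in range(max_iter):
        if err <= rtol:
            break
        # Jacobian of (ln t0, ln p0) wrt (x, y): softmax-weighted exponents
        j11 = float(np.dot(wt, a_ext))
        j12 = float(np.dot(wt, b_ext))
        j21 = float(np.dot(wp, a_ext_p))
        j22 = float(np.dot(wp, b_ext_p))
        det = j11 * j22 - j12 * j21
        if not math.isfinite(det):
            raise ConvergenceError("non-finite Jacobian in equilibrium solve")
        scale = abs(j11 * j22) + abs(j12 * j21) + 1.0
        if abs(det) < 1e-13 * scale:
            # rows numerically parallel (one species dominates both totals):
            # take a damped diagonally regularized step instead
            lam = 1e-6 * (j11 + j22)
            j11r, j22r = j11 + lam, j22 + lam
            det = j11r * j22r - j12 * j21
            dx = -(j22r * r1 - j12 * r2) / det
            dy = -(-j21 * r1 + j11r * r2) / det
        else:
            dx = -(j22 * r1 - j12 * r2) / det
            dy = -(-j21 * r1 + j11 * r2) / det
        # damping: cap the log-space step
        step = max(abs(dx), abs(dy))
        if step > 4.0:
            dx *= 4.0 / step
            dy *= 4.0 / step
        lam = 1.0
        for _bt in range(60):
            nx, ny = x + lam * dx, y + lam * dy
            n1, n2, nwt, nwp = residual(nx, ny)
            if max(abs(n1), abs(n2)) < err:
                x, y, r1, r2, wt, wp = nx, ny, n1, n2, nwt, nwp
                err = max(abs(r1), abs(r2))
                break
            lam *= 0.5
        else:
            raise ConvergenceError(
                f"line search stalled; residuals ({r1:.3e}, {r2:.3e})"
            )
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations; residuals ({r1:.3e}, {r2:.3e})"
        )
    state = evaluate_free_state(FreeState(math.exp(x), math.exp(y)), params, species_table)
    # exact-bookkeeping check at the requested tolerance
    rel = max(abs(state.t0_uM - t0) / t0, abs(state.p0_uM - p0) / p0)
    if rel > 1e-9:
        raise ConvergenceError(f"mass balance residual {rel:.3e} exceeds 1e-9")
    return state


def mass_fraction_assembled(
    state: EquilibriumState,
    mw_t: float | None = None,
    mw_p: float | None = None,
) -> float:
    """Fraction of total material in the high-MW (assembled) pool.

    Monomer-count basis by default; pass per-monomer molecular weights for a
    mass-weighted fraction instead.
    """
    if mw_t is not None and mw_p is not None:
        num = state.t_high_uM * mw_t + state.p_high_uM * mw_p
        den = state.t0_uM * mw_t + state.p0_uM * mw_p
    else:
        num = state.high_mw_monomer_uM
        den = state.t0_uM + state.p0_uM
    if den == 0:
        raise ValueError("mass fraction undefined for zero total concentration")
    return num / den
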