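"""Equilibrium leaf-temperature solver and grid sweeps.

The net energy flux is strictly decreasing in leaf temperature, so the
equilibrium is the unique root of a scalar function; it is found with
Brent's bracketed method.  The initial bracket is ±30 K around air
temperature (clipped to the vapour-pressure validity range) and is widened
by doubling, up to 120 K total, if the net flux does not change sign across
it.  In batch mode failures are data, not exceptions: a row that cannot be
solved is returned with ``convergence = 1`` and the best iterate found.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy.optimize import brentq

from .boundary_layer import SurfaceConductances
from .energy_balance import EnergyFluxes, energy_balance_components
from .environment import DerivedEnvironment, T_VALID, sky_temperature
from .parameters import (
    ENV_COLUMNS,
    LEAF_COLUMNS,
    EnvironmentalParameters,
    LeafParameters,
    ParameterGrid,
    PhysicalConstants,
    default_constants,
    default_environment,
    default_leaf,
    validate,
)

__all__ = [
    "EnergyBalanceSolution",
    "solve_equilibrium",
    "solve_grid",
    "residual_check",
    "RESULT_COLUMNS",
]

logger = logging.getLogger("leafenergy")

_BRACKET_HALF_WIDTH = 30.0   # K
_BRACKET_MAX_WIDTH = 120.0   # K
_BRACKET_MARGIN = 1.0        # K kept clear of the p_sat validity bounds
_XTOL = 1e-10                # K, absolute temperature tolerance for Brent
_RESIDUAL_TOL = 1e-6         # W m⁻², |net| bound for a converged solution

RESULT_COLUMNS = (
    list(LEAF_COLUMNS.values())
    + list(ENV_COLUMNS.values())
    + [
        "T_leaf", "R_abs", "S_r", "H", "L", "E",
        "g_h", "g_bw", "g_tw", "Re", "Gr", "Nu", "Sh", "Ar",
        "p_sat", "p_air", "h_vap", "P_a", "T_sky", "S_lw",
        "D_h", "D_m", "D_w", "d_wv",
        "value", "convergence",
    ]
)


@dataclass(frozen=True)
class EnergyBalanceSolution:
    """Equilibrium solution for one parameter set.

    ``convergence`` is 0 when the root-find succeeded (then
    ``|value| < 1e-6 W m⁻²``) and 1 when it failed, in which case ``T_leaf``
    and ``value`` describe the best iterate found.
    """

    T_leaf: float                 # K
    fluxes: EnergyFluxes
    conductances: SurfaceConductances
    derived: DerivedEnvironment
    value: float                  # W m⁻², net flux at T_leaf
    convergence: int              # 0 converged, 1 failed


def _clip_bracket(lo: float, hi: float) -> tuple[float, float]:
    return (
        max(lo, T_VALID[0] + _BRACKET_MARGIN),
        min(hi, T_VALID[1] - _BRACKET_MARGIN),
    )


def solve_equilibrium(
    leaf: LeafParameters | None = None,
    env: EnvironmentalParameters | None = None,
    constants: PhysicalConstants | None = None,
    units: bool = False,
    xtol: float = _XTOL,
    residual_tol: float = _RESIDUAL_TOL,
    sky_model=sky_temperature,
) -> EnergyBalanceSolution:
    """Find the equilibrium leaf temperature for one parameter set.

    Parameters default to the standard leaf and environment.  With
    ``units=True`` every intermediate value in the pipeline is unit-tagged
    and dimension-checked (slower, numerically equivalent to the default
    unitless fast path).
    """
    leaf = validate(leaf if leaf is not None else default_leaf())
    env = validate(env if env is not None else default_environment())
    cons = validate(constants if constants is not None else default_constants())

    def net(t: float) -> float:
        fluxes, _, _ = energy_balance_components(
            t, leaf, env, cons, units=units, sky_model=sky_model
        )
        return fluxes.net

    def finish(t: float, convergence: int) -> EnergyBalanceSolution:
        try:
            fluxes, cond, derived = energy_balance_components(
                t, leaf, env, cons, units=units, sky_model=sky_model
            )
        except ValueError:
            nan = float("nan")
            fluxes = EnergyFluxes(nan, nan, nan, nan, nan, nan)
            cond = SurfaceConductances(*(nan,) * 2, nan, "unknown", *(nan,) * 9)
            derived = DerivedEnvironment(*(nan,) * 10)
            convergence = 1
        if convergence == 0 and not abs(fluxes.net) < residual_tol:
            convergence = 1
        return EnergyBalanceSolution(
            T_leaf=t, fluxes=fluxes, conductances=cond, derived=derived,
            value=fluxes.net, convergence=convergence,
        )

    half = _BRACKET_HALF_WIDTH
    try:
        while True:
            lo, hi = _clip_bracket(env.T_air - half, env.T_air + half)
            f_lo, f_hi = net(lo), net(hi)
            if not (math.isfinite(f_lo) and math.isfinite(f_hi)):
                logger.warning("non-finite net flux at bracket endpoint")
                return finish(env.T_air, 1)
            if f_lo == 0.0:
                return finish(lo, 0)
            if f_hi == 0.0:
                return finish(hi, 0)
            if f_lo * f_hi < 0.0:
                break
            if hi - lo >= _BRACKET_MAX_WIDTH or (
                lo == _clip_bracket(-1e9, 1e9)[0] and hi == _clip_bracket(-1e9, 1e9)[1]
            ):
                # no sign change within the admissible range
                best = lo if abs(f_lo) < abs(f_hi) else hi
                logger.warning("no sign change in bracket [%g, %g] K", lo, hi)
                return finish(best, 1)
            half *= 2.0
        root = brentq(net, lo, hi, xtol=xtol, rtol=8.9e-16)
        return finish(float(root), 0)
    except ValueError as exc:
        logger.warning("solve failed: %s", exc)
        return finish(env.T_air, 1)


def _solution_row(leaf: LeafParameters, env: EnvironmentalParameters,
                  sol: EnergyBalanceSolution) -> dict:
    row = {col: getattr(leaf, name) for name, col in LEAF_COLUMNS.items()}
    row.update({col: getattr(env, name) for name, col in ENV_COLUMNS.items()})
    fl, cond, der = sol.fluxes, sol.conductances, sol.derived
    row.update(
        T_leaf=sol.T_leaf,
        R_abs=fl.R_abs, S_r=fl.S_r, H=fl.H, L=fl.L, E=fl.E,
        g_h=cond.g_h, g_bw=cond.g_bw, g_tw=cond.g_tw,
        Re=cond.Re, Gr=cond.Gr, Nu=cond.Nu, Sh=cond.Sh, Ar=cond.Ar,
        p_sat=der.p_sat, p_air=der.p_air, h_vap=der.h_vap, P_a=der.P_a,
        T_sky=der.T_sky, S_lw=der.S_lw,
        D_h=der.D_h, D_m=der.D_m, D_w=der.D_w, d_wv=der.d_wv,
        value=sol.value, convergence=sol.convergence,
    )
    return row


def solve_grid(
    grid: ParameterGrid,
    units: bool = False,
    xtol: float = _XTOL,
    residual_tol: float = _RESIDUAL_TOL,
    sky_model=sky_temperature,
) -> pd.DataFrame:
    """Solve every row of a parameter grid; return a tidy results table.

    One output row per grid row, in grid order, carrying every input
    parameter, every calculated quantity and the convergence diagnostics.
    Failed rows are retained with ``convergence = 1``, never dropped.
    Execution is serial and deterministic: identical inputs give
    bit-identical tables.
    """
    if len(grid) == 0:
        raise ValueError("parameter grid is empty")
    records = []
    failures = 0
    for leaf, env in grid:
        try:
            sol = solve_equilibrium(
                leaf, env, grid.constants, units=units,
                xtol=xtol, residual_tol=residual_tol, sky_model=sky_model,
            )
        except Exception as exc:  # failures are data in batch mode
            logger.warning("row failed: %s", exc)
            records.append(
                {**{col: getattr(leaf, name) for name, col in LEAF_COLUMNS.items()},
                 **{col: getattr(env, name) for name, col in ENV_COLUMNS.items()},
                 **{c: float("nan") for c in RESULT_COLUMNS
                    if c not in LEAF_COLUMNS.values()
                    and c not in ENV_COLUMNS.values()},
                 "convergence": 1}
            )
            failures += 1
            continue
        failures += sol.convergence
        records.append(_solution_row(leaf, env, sol))
    logger.info("solved %d parameter combinations (%d failed)",
                len(grid), failures)
    df = pd.DataFrame.from_records(records, columns=RESULT_COLUMNS)
    return df


def residual_check(solution: EnergyBalanceSolution,
                   tolerance: float = _RESIDUAL_TOL) -> bool:
    """True iff the solution converged and its residual is below tolerance."""
    return solution.convergence == 0 and abs(solution.value) < tolerance
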