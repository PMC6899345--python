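"""Shared fixtures: random parameter draws and the brute-force root oracle."""

from __future__ import annotations

import numpy as np
import pytest

import leafenergy as le

# plausible draw ranges for random parameter sets (well inside the
# soft-warning validation bounds, so draws never trigger warnings)
LEAF_RANGES = {
    "d": (0.004, 0.4),
    "abs_s": (0.3, 0.8),
    "abs_l": (0.92, 0.99),
    "g_sw": (0.5, 10.0),
    "g_uw": (0.01, 0.5),
    "logit_sr": (-3.0, 3.0),
}
ENV_RANGES = {
    "P": (80.0, 101.3246),
    "r": (0.1, 0.4),
    "RH": (0.1, 0.95),
    "S_sw": (0.0, 1200.0),
    "T_air": (278.0, 313.0),
    "u": (0.1, 10.0),
}


def draw_parameters(rng: np.random.Generator):
    """One random (LeafParameters, EnvironmentalParameters) pair.

    Leaf size is drawn log-uniformly (it spans two decades); everything else
    uniformly.
    """
    leaf_vals = {k: float(rng.uniform(*v)) for k, v in LEAF_RANGES.items()}
    lo, hi = LEAF_RANGES["d"]
    leaf_vals["d"] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    env_vals = {k: float(rng.uniform(*v)) for k, v in ENV_RANGES.items()}
    return le.LeafParameters(**leaf_vals), le.EnvironmentalParameters(**env_vals)


def grid_scan_root(leaf, env, constants=None, coarse=0.1, fine=1e-3,
                   half_width=30.0) -> float:
    """Brute-force oracle for the equilibrium temperature.

    Scans the net energy flux on a coarse grid over the solver bracket,
    asserts a single sign change (the net flux is strictly decreasing), then
    rescans that interval at ``fine`` resolution and returns the midpoint of
    the sign-change pair.  Independent of the Brent solver.
    """
    def f(t):
        return le.net_energy_flux(float(t), leaf, env, constants).net

    lo = max(env.T_air - half_width, 241.0)
    hi = min(env.T_air + half_width, 339.0)
    ts = np.arange(lo, hi + coarse / 2, coarse)
    vals = np.array([f(t) for t in ts])
    changes = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
    assert len(changes) == 1, "net flux must cross zero exactly once"
    i = int(changes[0])
    ts2 = np.arange(ts[i], ts[i + 1] + fine / 2, fine)
    vals2 = [f(t) for t in ts2]
    for j in range(len(ts2) - 1):
        if np.sign(vals2[j]) != np.sign(vals2[j + 1]):
            return float(0.5 * (ts2[j] + ts2[j + 1]))
    raise AssertionError("sign change lost on fine grid")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
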