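"""Density-dependent responses: steady-state branches, folds, and classes.

A feedback circuit's density-dependent response (DDR) is the set of its
steady-state protein levels as a function of cell density.  With positive
feedback the branch structure can fold: a pair of saddle-node (fold)
bifurcations bounds a density interval with two stable states.  Relative to
the terminal density ``rho_T`` the DDR falls into one of four classes:

- ``M``   monostable — smooth, typically sigmoidal rise with density;
- ``B+``  bistable with the threshold crossed before ``rho_T`` (abrupt
  switch to the induced state);
- ``B±``  bistable and hysteretic at ``rho_T`` (terminal state depends on
  the initial state);
- ``B−``  the bistable window lies entirely above ``rho_T`` (never induced).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import ode_rhs, plf_eval
from .params import ConfigurationError, PLFParams, TopologySpec
from .predict import FixedPoint, FixedPointSet

#: root-scan bracket: steady states of x = lambda f(x) lie in [lambda eps, lambda]
SCAN_POINTS = 512
DENSITY_POINTS = 400
DENSITY_RANGE = (1e-4, 1.0)


class DDRType(str, Enum):
    M = "M"
    B_PLUS = "B+"
    B_PM = "B±"
    B_MINUS = "B−"


def _feedback_map(topo: TopologySpec, p: PLFParams) -> Callable[[np.ndarray], np.ndarray]:
    """x -> lambda * f(x) for the protein in feedback (vectorized)."""
    lam = topo.feedback_lambda
    if topo.kind == "luxR_feedback":
        return lambda x: lam * plf_eval(topo.luxI_fixed, x, p)
    if topo.kind == "luxI_feedback":
        return lambda x: lam * plf_eval(x, topo.luxR_fixed, p)
    raise ConfigurationError(
        f"1-D steady-state analysis requires a single-protein feedback topology, got {topo.kind!r}"
    )


def steady_states_at_density(
    topo: TopologySpec, p: PLFParams, rho: float, n_scan: int = SCAN_POINTS
) -> FixedPointSet:
    """All steady states of the feedback ODE at a clamped density.

    Roots of ``lambda f(x; rho) - x`` are bracketed on a log-spaced scan over
    ``[lambda eps / 10, 10 lambda]`` (steady states are confined to
    ``[lambda eps, lambda]``) and refined by Brent's method to 1e-10
    relative.  Stability follows the sign of the derivative of the net rate;
    labels alternate, starting and ending stable.
    """
    if rho < 0:
        raise ValueError("density must be >= 0")
    p_rho = p.with_density(rho)
    F = _feedback_map(topo, p_rho)
    lam = topo.feedback_lambda
    xs = np.geomspace(lam * p.basal_fraction / 10.0, 10.0 * lam, n_scan)
    g = F(xs) - xs
    sign = np.sign(g)
    roots: list[float] = []
    for k in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        r = brentq(lambda x: float(F(x)) - x, xs[k], xs[k + 1],
                   xtol=1e-300, rtol=1e-10)
        roots.append(float(r))
    for k in np.nonzero(g == 0.0)[0]:  # exact hits on the scan grid
        roots.append(float(xs[k]))
    roots = sorted(set(roots))
    points = []
    for r in roots:
        h = 1e-6 * max(r, lam * p.basal_fraction)
        slope = (float(F(r + h)) - float(F(max(r - h, 0.0)))) / (2 * h)
        points.append(FixedPoint(level=r, stability="stable" if slope < 1.0 else "unstable"))
    return FixedPointSet(points)


@dataclass
class DDRCurve:
    """Steady-state branches over a density grid, with fold locations."""

    densities: np.ndarray
    fixed_points: list[FixedPointSet]
    rho_T: float
    rho_low: float | None = None   # lower fold density (onset of bistability)
    rho_high: float | None = None  # upper fold density (loss of the low branch)
    degenerate: bool = False       # root count other than 1 or 3 somewhere

    @property
    def bistable(self) -> bool:
        return self.rho_low is not None

    def branch_counts(self) -> np.ndarray:
        return np.array([len(fp) for fp in self.fixed_points])


def _count_roots_vectorized(topo: TopologySpec, p: PLFParams, rhos: np.ndarray,
                            n_scan: int = SCAN_POINTS) -> np.ndarray:
    """Root count per density via one vectorized (density x scan) sign scan."""
    lam = topo.feedback_lambda
    xs = np.geomspace(lam * p.basal_fraction / 10.0, 10.0 * lam, n_scan)
    c, m = p.ahl_density_const, p.hill_m
    if topo.kind == "luxI_feedback":
        A = c * rhos[:, None] * xs[None, :]
        occ = np.where(A > 0, A**m / (p.ahl_luxr_halfsat**m + A**m), 0.0)
        Rstar = topo.luxR_fixed * occ
    else:  # luxR_feedback
        A = c * rhos * topo.luxI_fixed
        occ = np.where(A > 0, A**m / (p.ahl_luxr_halfsat**m + A**m), 0.0)
        Rstar = occ[:, None] * xs[None, :]
    Kn = p.luxr_dna_halfsat**p.hill_n
    with np.errstate(over="ignore"):
        Rn = Rstar**p.hill_n
    f = np.where(np.isinf(Rn), 1.0, (p.basal_fraction * Kn + Rn) / (Kn + Rn))
    g = lam * f - xs[None, :]
    sign_change = (np.sign(g[:, :-1]) * np.sign(g[:, 1:])) < 0
    return sign_change.sum(axis=1)


def compute_ddr(
    topo: TopologySpec,
    p: PLFParams,
    density_grid: np.ndarray | None = None,
    rho_T: float = 0.05,
    fold_rtol: float = 1e-3,
) -> DDRCurve:
    """Trace the steady-state branches of a 1-D feedback loop over density.

    Folds (changes in root count) are localized by bisection on the density
    axis to ``fold_rtol`` relative.  Densities with a root count other than
    1 or 3 flag the curve as degenerate rather than being silently patched.
    """
    if density_grid is None:
        density_grid = np.geomspace(*DENSITY_RANGE, DENSITY_POINTS)
    rhos = np.asarray(density_grid, dtype=float)
    if np.any(rhos <= 0) or np.any(np.diff(rhos) <= 0):
        raise ConfigurationError("density grid must be positive and ascending")
    counts = _count_roots_vectorized(topo, p, rhos)
    degenerate = bool(np.any(~np.isin(counts, (1, 3))))
    fps = [steady_states_at_density(topo, p, r) for r in rhos]

    def count_at(rho: float) -> int:
        return int(_count_roots_vectorized(topo, p, np.array([rho]))[0])

    def bisect_fold(r_lo: float, r_hi: float) -> float:
        c_lo = count_at(r_lo)
        while (r_hi - r_lo) / r_hi > fold_rtol:
            mid = np.sqrt(r_lo * r_hi)
            if count_at(mid) == c_lo:
                r_lo = mid
            else:
                r_hi = mid
        return float(np.sqrt(r_lo * r_hi))

    rho_low = rho_high = None
    tri = np.nonzero(counts == 3)[0]
    if tri.size:
        i0, i1 = tri[0], tri[-1]
        if not np.all(counts[i0 : i1 + 1] == 3):
            degenerate = True
        rho_low = bisect_fold(rhos[i0 - 1], rhos[i0]) if i0 > 0 else float(rhos[0])
        rho_high = (
            bisect_fold(rhos[i1], rhos[i1 + 1]) if i1 < len(rhos) - 1 else float(rhos[-1])
        )
    return DDRCurve(
        densities=rhos,
        fixed_points=fps,
        rho_T=rho_T,
        rho_low=rho_low,
        rho_high=rho_high,
        degenerate=degenerate,
    )


def classify_ddr(ddr: DDRCurve) -> DDRType:
    """Assign the M / B+ / B± / B− class relative to the terminal density."""
    if not ddr.bistable:
        return DDRType.M
    if ddr.rho_T > ddr.rho_high:
        return DDRType.B_PLUS
    if ddr.rho_T < ddr.rho_low:
        return DDRType.B_MINUS
    return DDRType.B_PM


def bifurcation_map(
    topo: TopologySpec,
    p: PLFParams,
    n_values: np.ndarray,
    regulator_values: np.ndarray,
    rho_T: float = 0.05,
    density_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Classify the DDR over a (hill_n x regulator level) parameter slice.

    Returns an object array of :class:`DDRType`, shape
    ``(len(n_values), len(regulator_values))``.  The same slice can be
    computed for either feedback topology, so topology effects can be read
    off by comparing maps cell by cell.
    """
    n_values = np.asarray(n_values, dtype=float)
    regulator_values = np.asarray(regulator_values, dtype=float)
    if n_values.size < 2 or regulator_values.size < 2:
        raise ConfigurationError("parameter ranges need >= 2 values each")
    if density_grid is None:
        density_grid = np.geomspace(*DENSITY_RANGE, 200)
    reg_field = "luxI_fixed" if topo.kind == "luxR_feedback" else "luxR_fixed"
    out = np.empty((n_values.size, regulator_values.size), dtype=object)
    for i, n in enumerate(n_values):
        p_n = p.replace(hill_n=float(n))
        for j, reg in enumerate(regulator_values):
            t = topo.replace(**{reg_field: float(reg)})
            rhos = np.asarray(density_grid, dtype=float)
            counts = _count_roots_vectorized(t, p_n, rhos)
            tri = np.nonzero(counts == 3)[0]
            if tri.size == 0:
                out[i, j] = DDRType.M
                continue
            rho_low = rhos[max(tri[0] - 1, 0)]
            rho_high = rhos[min(tri[-1] + 1, len(rhos) - 1)]
            if rho_T > rho_high:
                out[i, j] = DDRType.B_PLUS
            elif rho_T < rho_low:
                out[i, j] = DDRType.B_MINUS
            else:
                out[i, j] = DDRType.B_PM
    return out


@dataclass
class DynamicResponse:
    """Feedback trajectory under logistic growth with its quasi-static target."""

    t: np.ndarray
    density: np.ndarray
    level: np.ndarray          # dynamic feedback-protein level
    target: np.ndarray         # instantaneous stable steady state (history branch)


def dynamic_response(
    topo: TopologySpec,
    p: PLFParams,
    growth_rate: float,
    carrying_capacity: float = 1.0,
    rho0: float = 1e-3,
    t_grid: np.ndarray | None = None,
    history: str = "OFF",
) -> DynamicResponse:
    """Co-integrate logistic density growth with the feedback ODE.

    The returned ``target`` is the quasi-static DDR overlay: at each time
    the stable steady state on the branch connected to the given history
    (OFF follows the lowest stable branch until it vanishes, ON the
    highest), after which the branch jumps.  The dynamic response lags this
    moving target whenever protein kinetics are not infinitely fast.
    """
    if growth_rate <= 0:
        raise ConfigurationError("growth rate must be > 0")
    if history not in ("OFF", "ON"):
        raise ConfigurationError(f"history must be 'OFF' or 'ON', got {history!r}")
    if t_grid is None:
        t_end = np.log(carrying_capacity / rho0 * 99) / growth_rate
        t_grid = np.linspace(0.0, t_end, 300)
    t_grid = np.asarray(t_grid, dtype=float)

    def rho_of_t(t):
        e = np.exp(growth_rate * t)
        return carrying_capacity * rho0 * e / (carrying_capacity + rho0 * (e - 1.0))

    lam = topo.feedback_lambda
    x0 = lam * p.basal_fraction if history == "OFF" else lam

    def rhs(t, y):
        return ode_rhs(y, t, topo, p.with_density(float(rho_of_t(t))))

    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), [x0], t_eval=t_grid,
        method="LSODA", rtol=1e-8, atol=1e-10 * lam,
    )
    if not sol.success:
        raise RuntimeError(f"dynamic integration failed: {sol.message}")
    dens = rho_of_t(t_grid)
    target = np.empty_like(t_grid)
    prev = x0
    for k, rho in enumerate(dens):
        fps = steady_states_at_density(topo, p, float(rho))
        stable = fps.stable_levels
        if stable.size == 0:  # should not occur for these maps
            target[k] = prev
            continue
        # history-connected branch: nearest stable level to the previous target
        target[k] = stable[np.argmin(np.abs(np.log(stable) - np.log(prev)))]
        prev = target[k]
    return DynamicResponse(t=t_grid, density=dens, level=sol.y[0], target=target)
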