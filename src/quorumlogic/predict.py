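"""Predicting feedback steady states from the promoter logic function.

A feedback loop's steady states are the points where an *input-output
characteristic* (IOC: a one-dimensional slice of the PLF at fixed regulator
level) intersects the *line of equivalence* (the affine constraint closing
the loop).  The model-independent route interpolates measured IOCs by power
laws (linear in log-log space) with conservative flat extrapolation outside
the measured range, enumerates intersections analytically segment by
segment, and propagates measurement uncertainty by Monte Carlo.  The
model-based route evaluates the fitted PLF instead of interpolating.

Stability of the enumerated fixed points follows the one-dimensional
alternation convention: where the IOC crosses the line from above to below,
the fixed point is stable; tangential crossings are labeled unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import EquivalenceLine, subtract_background
from .model import plf_eval
from .params import ConfigurationError, PLFParams, TopologySpec
from .synthetic import PLFGrid

#: crossings closer than this in log units are merged as tangencies
TANGENCY_LOG_TOL = 1e-9

#: pseudo-infinite extent (in log units) of the flat extrapolation segments
_FLAT_EXTENT = 60.0


@dataclass(frozen=True)
class FixedPoint:
    level: float
    stability: str  # "stable" | "unstable" | "unknown"


@dataclass
class FixedPointSet:
    """Steady-state levels with stability labels, sorted ascending."""

    points: list[FixedPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda q: q.level)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def levels(self) -> np.ndarray:
        return np.array([q.level for q in self.points])

    @property
    def stabilities(self) -> list[str]:
        return [q.stability for q in self.points]

    @property
    def stable_levels(self) -> np.ndarray:
        return np.array([q.level for q in self.points if q.stability == "stable"])

    @property
    def multistable(self) -> bool:
        return len(self.stable_levels) > 1


@dataclass
class IOC:
    """Input-output characteristic: one slice of the PLF at fixed regulator.

    ``x`` (would-be feedback input) and ``y`` (output) are background
    subtracted fluorescence values; ``x`` strictly increasing, all positive.
    """

    x: np.ndarray
    y: np.ndarray
    regulator: float = np.nan
    axis: str = ""
    y_log_sd: np.ndarray | None = None  # per-point SEM of log-output

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size == 0:
            raise ConfigurationError("empty IOC")
        if self.x.size != self.y.size:
            raise ConfigurationError("IOC x and y lengths differ")
        if np.any(np.diff(self.x) <= 0):
            raise ConfigurationError("IOC inputs must be strictly increasing")
        if np.any(self.x <= 0) or np.any(self.y <= 0):
            raise ConfigurationError("IOC values must be positive (post-floor)")


def ioc_from_grid(
    grid: PLFGrid,
    axis: str,
    regulator_index: int,
    input_background: float = 0.0,
    output_background: float = 0.0,
    floor_frac: float = 1e-6,
) -> IOC:
    """Extract a replicate-averaged, background-subtracted slice of the grid.

    ``axis`` names the would-be feedback input varying along the slice:
    ``"luxR"`` takes a vertical cut (fixed aTc level, LuxR varies; used to
    predict LuxR-feedback), ``"luxI"`` a horizontal cut (fixed IPTG level,
    LuxI varies; used to predict LuxI-feedback).  ``floor_frac`` sets the
    post-subtraction floor as a fraction of the channel maximum.
    """
    summary = grid.replicate_summary().reset_index()
    if axis == "luxR":
        if not 0 <= regulator_index < len(grid.aTc_levels):
            raise ConfigurationError(f"regulator index {regulator_index} out of range")
        level = grid.aTc_levels[regulator_index]
        sl = summary[summary["aTc_ng_ml"] == level]
        xcol, reg = "luxR_yfp", level
    elif axis == "luxI":
        if not 0 <= regulator_index < len(grid.IPTG_levels):
            raise ConfigurationError(f"regulator index {regulator_index} out of range")
        level = grid.IPTG_levels[regulator_index]
        sl = summary[summary["IPTG_uM"] == level]
        xcol, reg = "luxI_cfp", level
    else:
        raise ConfigurationError(f"axis must be 'luxR' or 'luxI', got {axis!r}")
    sl = sl.dropna(subset=[xcol, "output_cfp"])
    if len(sl) < 2:
        raise ConfigurationError("IOC slice has fewer than 2 points")
    x_raw = sl[xcol].to_numpy()
    y_raw = sl["output_cfp"].to_numpy()
    x = subtract_background(x_raw, input_background, floor_frac * np.max(x_raw))
    y = subtract_background(y_raw, output_background, floor_frac * np.max(y_raw))
    n_rep = sl["n_rep"].to_numpy(dtype=float)
    y_sem = sl["log_sd"].to_numpy() / np.sqrt(np.maximum(n_rep, 1.0))
    order = np.argsort(x)
    x, y, y_sem = x[order], y[order], y_sem[order]
    # collapse numerically tied inputs (both at the floor) to keep x strict
    keep = np.concatenate([[True], np.diff(x) > 0])
    return IOC(x=x[keep], y=y[keep], regulator=reg, axis=axis, y_log_sd=y_sem[keep])


def loglog_interp(ioc: IOC, x) -> np.ndarray | float:
    """Power-law interpolation of an IOC (linear in log-log space).

    Outside the measured input range the IOC is conservatively extrapolated
    by flat lines at the first/last node value.
    """
    xq = np.asarray(x, dtype=float)
    if np.any(xq <= 0):
        raise ValueError("query inputs must be positive")
    lo = np.log(ioc.x)
    ly = np.log(ioc.y)
    out = np.exp(np.interp(np.log(xq), lo, ly))
    return float(out) if out.ndim == 0 else out


def _segments(ioc: IOC):
    """Segment list [(u0, u1, a, b)] of log-IOC Y = a + b u, with flat tails."""
    u = np.log(ioc.x)
    v = np.log(ioc.y)
    segs = [(u[0] - _FLAT_EXTENT, u[0], v[0], 0.0)]
    for k in range(len(u) - 1):
        b = (v[k + 1] - v[k]) / (u[k + 1] - u[k])
        a = v[k] - b * u[k]
        segs.append((u[k], u[k + 1], a, b))
    segs.append((u[-1], u[-1] + _FLAT_EXTENT, v[-1], 0.0))
    return segs


def find_intersections(ioc: IOC, line: EquivalenceLine | float) -> FixedPointSet:
    """All crossings of the interpolated IOC with the line of equivalence.

    Coordinates are background-subtracted, so the line is ``y = s x`` —
    in log space ``Y = u + log s``, linear like the interpolated IOC, and
    every intersection is solved exactly segment by segment (flat
    extrapolation segments included).  Stability by crossing direction:
    the IOC passing from above the line to below it marks a stable fixed
    point.  Tangencies (crossings closer than ``TANGENCY_LOG_TOL`` in log
    units, or segments lying on the line) are counted once with stability
    unknown.
    """
    s = line.scale if isinstance(line, EquivalenceLine) else float(line)
    if s <= 0:
        raise ValueError("line scale must be > 0")
    ls = np.log(s)
    segs = _segments(ioc)
    crossings: list[float] = []
    for i, (u0, u1, a, b) in enumerate(segs):
        # g(u) = (a + b u) - (u + ls): linear in u with slope (b - 1)
        if b == 1.0:
            if abs(a - ls) < TANGENCY_LOG_TOL:
                # segment lies on the line: count once, at its midpoint
                crossings.append(0.5 * (u0 + u1))
            continue
        ustar = (a - ls) / (1.0 - b)
        # half-open [u0, u1) to avoid double-counting shared nodes
        last = i == len(segs) - 1
        if u0 <= ustar < u1 or (last and ustar == u1):
            crossings.append(ustar)
    crossings.sort()
    # merge near-coincident crossings (tangential pairs)
    merged: list[float] = []
    for u in crossings:
        if merged and u - merged[-1] < TANGENCY_LOG_TOL:
            merged[-1] = 0.5 * (merged[-1] + u)
        else:
            merged.append(u)

    def _gap(u: float) -> float:
        """log-IOC minus log-line at log-input u (flat outside nodes)."""
        lu = np.log(ioc.x)
        lv = np.log(ioc.y)
        return float(np.interp(u, lu, lv)) - (u + ls)

    delta = 1e-7
    points = []
    for u in merged:
        g_lo, g_hi = _gap(u - delta), _gap(u + delta)
        if g_lo > 0 > g_hi:
            stab = "stable"
        elif g_lo < 0 < g_hi:
            stab = "unstable"
        else:
            stab = "unknown"
        points.append(FixedPoint(level=float(np.exp(u)), stability=stab))
    return FixedPointSet(points)


@dataclass
class MCPredictResult:
    """Monte-Carlo ensemble of intersection predictions."""

    trials: list[FixedPointSet]
    deterministic: FixedPointSet
    multistable_fraction: float

    @property
    def all_stable_levels(self) -> np.ndarray:
        return np.concatenate(
            [t.stable_levels for t in self.trials if len(t.stable_levels)]
            or [np.array([])]
        )


def mc_predict(
    grid: PLFGrid,
    line: EquivalenceLine | float,
    axis: str,
    regulator_index: int,
    trials: int = 1000,
    seed: int = 0,
    noise_log_sd: float | np.ndarray | None = None,
    input_background: float = 0.0,
    output_background: float = 0.0,
) -> MCPredictResult:
    """Propagate measurement uncertainty through the intersection analysis.

    Each trial perturbs the log-outputs of the IOC nodes with independent
    Gaussian noise (per-node SD from the replicate standard errors of the
    grid unless ``noise_log_sd`` overrides them), re-runs interpolation and
    intersection, and records the predicted levels.  Reports the fraction of
    trials with more than one stable intersection (multistable predictions).
    """
    if trials < 1:
        raise ConfigurationError("trials must be >= 1")
    base = ioc_from_grid(grid, axis, regulator_index, input_background, output_background)
    det = find_intersections(base, line)
    if noise_log_sd is None:
        sd = base.y_log_sd if base.y_log_sd is not None else np.zeros_like(base.y)
    else:
        sd = np.broadcast_to(np.asarray(noise_log_sd, dtype=float), base.y.shape)
    rng = np.random.default_rng(seed)
    out: list[FixedPointSet] = []
    n_multi = 0
    for _ in range(trials):
        y_pert = base.y * np.exp(rng.normal(0.0, sd))
        trial_ioc = IOC(x=base.x, y=y_pert, regulator=base.regulator, axis=base.axis)
        fps = find_intersections(trial_ioc, line)
        out.append(fps)
        if fps.multistable:
            n_multi += 1
    return MCPredictResult(
        trials=out, deterministic=det, multistable_fraction=n_multi / trials
    )


def interp_across_regulator(
    regulator_levels: Sequence[float],
    predictions: Sequence[np.ndarray | Sequence[float]],
    target: float,
) -> np.ndarray:
    """Log-log interpolation of predicted stable levels across regulators.

    ``predictions[k]`` holds the sorted stable levels predicted at
    ``regulator_levels[k]``.  Multivalued regions are interpolated branch
    wise (lower branch with lower, upper with upper).  If the branch count
    changes between the flanking regulator levels, only the persisting outer
    branches are interpolated and a warning is issued.
    """
    regs = np.asarray(regulator_levels, dtype=float)
    if regs.size < 2:
        raise ConfigurationError("need >= 2 measured regulator levels")
    if np.any(np.diff(regs) <= 0):
        raise ConfigurationError("regulator levels must be strictly increasing")
    preds = [np.sort(np.asarray(v, dtype=float)) for v in predictions]
    if target in regs:
        return preds[int(np.nonzero(regs == target)[0][0])]
    if target < regs[0] or target > regs[-1]:
        # flat extrapolation, consistent with the IOC convention
        return preds[0 if target < regs[0] else -1]
    k = int(np.searchsorted(regs, target)) - 1
    lo, hi = preds[k], preds[k + 1]
    n_lo, n_hi = len(lo), len(hi)
    n = min(n_lo, n_hi)
    if n_lo != n_hi:
        warnings.warn(
            f"branch count changes between regulator levels {regs[k]:g} and "
            f"{regs[k + 1]:g} ({n_lo} vs {n_hi}); interpolating the {n} "
            "persisting outer branch(es)",
            stacklevel=2,
        )
    if n == 0:
        return np.array([])
    # pair outermost branches: lowest with lowest, highest with highest
    lo_sel = np.concatenate([lo[: (n + 1) // 2], lo[n_lo - n // 2:]]) if n_lo > n else lo
    hi_sel = np.concatenate([hi[: (n + 1) // 2], hi[n_hi - n // 2:]]) if n_hi > n else hi
    t = (np.log(target) - np.log(regs[k])) / (np.log(regs[k + 1]) - np.log(regs[k]))
    return np.exp((1 - t) * np.log(lo_sel) + t * np.log(hi_sel))


def model_based_ioc(
    p: PLFParams,
    topo: TopologySpec,
    regulator: float,
    input_range: tuple[float, float],
    n_points: int = 400,
    output_scale: float | None = None,
) -> IOC:
    """IOC evaluated from the parameterized PLF instead of interpolation.

    Returns ``output_scale * f`` along a dense log-spaced input grid with
    the regulator held fixed; ``output_scale`` defaults to the topology's
    reporter production scale (``lambda_Z``) or 1.
    """
    lo, hi = input_range
    if lo <= 0 or hi <= lo:
        raise ConfigurationError("input range must be positive and increasing")
    if output_scale is None:
        output_scale = topo.lambda_Z if topo.lambda_Z is not None else 1.0
    x = np.geomspace(lo, hi, n_points)
    if topo.kind == "luxR_feedback":
        y = output_scale * plf_eval(regulator, x, p)
        axis = "luxR"
    elif topo.kind == "luxI_feedback":
        y = output_scale * plf_eval(x, regulator, p)
        axis = "luxI"
    else:
        raise ConfigurationError(f"model_based_ioc needs a 1-D feedback topology, got {topo.kind!r}")
    return IOC(x=x, y=np.maximum(y, 1e-300), regulator=regulator, axis=axis)
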