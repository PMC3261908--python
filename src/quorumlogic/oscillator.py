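"""Dual positive/negative-feedback oscillator built on the pR promoter.

LuxR activates its own expression through pR (positive feedback), while a
LacI repressor — also expressed from pR — shuts down LuxI production from
pLac (negative feedback).  With density clamped (chemostat), the slow
LuxI variable drags the bistable LuxR subsystem around its hysteresis
loop, producing relaxation oscillations when the LuxI response rate
``gamma_I`` is slow enough; a Hopf bifurcation in ``gamma_I`` separates
the oscillatory and stable regimes.

By default LacI is taken at quasi-steady state (proportional to pR
activity), giving a two-dimensional (LuxR, LuxI) phase plane; an explicit
three-variable variant with LacI dynamics is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, fsolve
from scipy.signal import find_peaks

from .model import plf_eval
from .params import ConfigurationError, PLFParams

#: chemostat density clamp (OD600) used for dual-feedback runs
CHEMOSTAT_DENSITY = 0.185


@dataclass(frozen=True)
class OscillatorParams:
    """Constants of the dual positive/negative-feedback model.

    ``plf`` carries the promoter-logic constants at the clamped chemostat
    density.  ``lambda_R``/``gamma_R`` are the LuxR production scale and
    response rate; ``beta_I``/``gamma_I`` the LuxI production ceiling (from
    fully de-repressed pLac) and response rate — the free dynamical
    parameter of the model; ``laci_scale`` converts pR activity to LacI
    level, repressing pLac with half-saturation ``laci_halfsat`` and Hill
    coefficient ``laci_hill``.  ``gamma_L`` only matters for the explicit
    three-variable variant.
    """

    plf: PLFParams = field(
        default_factory=lambda: PLFParams(density=CHEMOSTAT_DENSITY)
    )
    lambda_R: float = 104.0
    gamma_R: float = 1.0
    beta_I: float = 150.0
    gamma_I: float = 0.05
    laci_scale: float = 100.0
    laci_halfsat: float = 10.0
    laci_hill: float = 2.0
    gamma_L: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lambda_R", "gamma_R", "beta_I", "gamma_I",
                     "laci_scale", "laci_halfsat", "laci_hill", "gamma_L"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    def replace(self, **kw) -> "OscillatorParams":
        return replace(self, **kw)

    def repression(self, laci) -> np.ndarray | float:
        """pLac activity under LacI repression: 1 / (1 + (L/K_L)^h_L)."""
        return 1.0 / (1.0 + (np.asarray(laci, dtype=float) / self.laci_halfsat) ** self.laci_hill)

    def rhs(self, t, y, explicit_laci: bool = False) -> np.ndarray:
        """Vector field; state [R, I] (or [R, I, L] with explicit LacI)."""
        y = np.clip(np.asarray(y, dtype=float), 0.0, None)
        R, I = y[0], y[1]
        f = plf_eval(I, R, self.plf)
        if explicit_laci:
            L = y[2]
            return np.array([
                self.gamma_R * (self.lambda_R * f - R),
                self.gamma_I * (self.beta_I * self.repression(L) - I),
                self.gamma_L * (self.laci_scale * f - L),
            ])
        L = self.laci_scale * f
        return np.array([
            self.gamma_R * (self.lambda_R * f - R),
            self.gamma_I * (self.beta_I * self.repression(L) - I),
        ])


DEFAULT_OSCILLATOR = OscillatorParams()


def nullclines(
    p: OscillatorParams,
    I_range: tuple[float, float] = (0.5, 200.0),
    R_range: tuple[float, float] = (0.5, 200.0),
    n_points: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """LuxR and LuxI nullclines in the (LuxI, LuxR) phase plane.

    Returns two ``(k, 2)`` arrays of (I, R) points.  The LuxR nullcline
    solves ``R = lambda_R f(I, R)`` for each I (all branches, so it may be
    multivalued where the positive feedback is bistable); the LuxI nullcline
    solves ``I = beta_I / (1 + (L/K_L)^h_L)`` with LacI at quasi-steady
    state.  Segments with no solution in range are simply absent (and a
    warning is issued if a whole curve is empty).
    """
    if I_range[0] <= 0 or R_range[0] <= 0 or I_range[1] <= I_range[0] or R_range[1] <= R_range[0]:
        raise ConfigurationError("nullcline ranges must be positive and increasing")
    Is = np.geomspace(*I_range, n_points)
    Rs = np.geomspace(*R_range, 4 * n_points)
    # LuxR nullcline: roots of lambda_R f(I, R) - R over the R scan, per I
    r_null = []
    for I in Is:
        g = p.lambda_R * plf_eval(I, Rs, p.plf) - Rs
        s = np.sign(g)
        for k in np.nonzero(s[:-1] * s[1:] < 0)[0]:
            r = brentq(lambda R: p.lambda_R * plf_eval(I, R, p.plf) - R,
                       Rs[k], Rs[k + 1], rtol=1e-12)
            r_null.append((I, r))
    # LuxI nullcline: roots of beta_I rep(L(I,R)) - I over the I scan, per R
    i_null = []
    for R in Rs[::4]:
        g = p.beta_I * p.repression(p.laci_scale * plf_eval(Is, R, p.plf)) - Is
        s = np.sign(g)
        for k in np.nonzero(s[:-1] * s[1:] < 0)[0]:
            r = brentq(
                lambda I: p.beta_I * p.repression(p.laci_scale * plf_eval(I, R, p.plf)) - I,
                Is[k], Is[k + 1], rtol=1e-12,
            )
            i_null.append((r, R))
    for name, curve in (("LuxR", r_null), ("LuxI", i_null)):
        if not curve:
            warnings.warn(f"{name} nullcline has no points in range", stacklevel=2)
    return np.array(r_null).reshape(-1, 2), np.array(i_null).reshape(-1, 2)


@dataclass
class FixedPointResult:
    R: float
    I: float
    eigenvalues: np.ndarray

    @property
    def stable(self) -> bool:
        return bool(np.max(self.eigenvalues.real) < 0)


def _jacobian(p: OscillatorParams, y: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    n = len(y)
    J = np.zeros((n, n))
    for j in range(n):
        h = rel_step * max(abs(y[j]), 1.0)
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (p.rhs(0.0, y + e) - p.rhs(0.0, y - e)) / (2 * h)
    return J


def fixed_point(
    p: OscillatorParams, rel_step: float = 1e-6, n_starts: int = 5
) -> FixedPointResult:
    """Locate the phase-plane fixed point and its Jacobian eigenvalues.

    Root-finding from a log-spaced lattice of starting points; eigenvalues
    by central-difference Jacobian with relative step ``rel_step``.  The
    fixed point's location does not depend on the rates ``gamma``, only its
    stability does.
    """
    starts_R = np.geomspace(p.lambda_R * p.plf.basal_fraction, p.lambda_R, n_starts)
    starts_I = np.geomspace(max(p.beta_I * 1e-3, 1e-6), p.beta_I, n_starts)
    roots = []
    for R0 in starts_R:
        for I0 in starts_I:
            sol, info, ier, _ = fsolve(
                lambda y: p.rhs(0.0, y), [R0, I0], full_output=True, xtol=1e-12
            )
            if ier == 1 and np.all(sol > 0) and np.max(np.abs(p.rhs(0.0, sol))) < 1e-8:
                if not any(np.allclose(sol, r, rtol=1e-6) for r in roots):
                    roots.append(sol)
    if not roots:
        raise RuntimeError("no fixed point found in the positive quadrant")
    if len(roots) > 1:
        warnings.warn(f"{len(roots)} fixed points found; returning the first", stacklevel=2)
    y = roots[0]
    eig = np.linalg.eigvals(_jacobian(p, y, rel_step))
    return FixedPointResult(R=float(y[0]), I=float(y[1]), eigenvalues=eig)


@dataclass
class Trajectory:
    """Simulated time course, with limit-cycle summary when periodic.

    ``period`` and ``amplitude`` (of LuxR, peak minus trough over the
    analyzed tail) are set only when at least three consecutive inter-peak
    intervals agree within 5%; otherwise they are NaN and ``oscillatory``
    is False.
    """

    t: np.ndarray
    R: np.ndarray
    I: np.ndarray
    L: np.ndarray | None = None
    period: float = np.nan
    amplitude: float = np.nan
    oscillatory: bool = False


def simulate(
    p: OscillatorParams,
    init=(1.0, 1.0),
    duration: float = 600.0,
    n_eval: int = 4000,
    explicit_laci: bool = False,
) -> Trajectory:
    """Integrate the oscillator and detect sustained oscillations.

    Peaks are detected on the LuxR trace after discarding the first half of
    the run (transient); the period is the mean inter-peak interval.
    """
    init = np.asarray(init, dtype=float)
    if explicit_laci and init.size == 2:
        init = np.append(init, p.laci_scale * p.plf.basal_fraction)
    t_eval = np.linspace(0.0, duration, n_eval)
    sol = solve_ivp(
        lambda t, y: p.rhs(t, y, explicit_laci),
        (0.0, duration), init, t_eval=t_eval, method="LSODA",
        rtol=1e-9, atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"oscillator integration failed: {sol.message}")
    t, R, I = sol.t, sol.y[0], sol.y[1]
    L = sol.y[2] if explicit_laci else None
    tail = t >= 0.5 * duration
    Rt, tt = R[tail], t[tail]
    span = Rt.max() - Rt.min()
    period = amplitude = np.nan
    oscillatory = False
    if span > 1e-6 * max(Rt.max(), 1.0):
        peaks, _ = find_peaks(Rt, prominence=0.1 * span)
        if len(peaks) >= 4:
            intervals = np.diff(tt[peaks])
            last = intervals[-3:]
            if np.ptp(last) <= 0.05 * np.mean(last):
                period = float(np.mean(last))
                amplitude = float(span)
                oscillatory = True
    return Trajectory(t=t, R=R, I=I, L=L, period=period,
                      amplitude=amplitude, oscillatory=oscillatory)


def hopf_scan(
    p: OscillatorParams,
    gamma_range: tuple[float, float],
    rtol: float = 1e-4,
    rel_step: float = 1e-6,
) -> float:
    """Hopf boundary in the LuxI response rate ``gamma_I``, by bisection.

    The fixed point itself does not move with ``gamma_I``, so only the
    eigenvalues are re-evaluated.  Requires the bracket to straddle a sign
    change of the leading real part; returns the boundary to ``rtol``
    relative.
    """
    lo, hi = gamma_range
    if lo <= 0 or hi <= lo:
        raise ConfigurationError("gamma range must be positive and increasing")

    fp0 = fixed_point(p.replace(gamma_I=lo), rel_step=rel_step)
    y = np.array([fp0.R, fp0.I])

    def max_re(g: float) -> float:
        J = _jacobian(p.replace(gamma_I=g), y, rel_step)
        return float(np.max(np.linalg.eigvals(J).real))

    f_lo, f_hi = max_re(lo), max_re(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no Hopf sign change in gamma_I range [{lo}, {hi}] "
            f"(leading Re = {f_lo:.3g}, {f_hi:.3g})"
        )
    while (hi - lo) / hi > rtol:
        mid = np.sqrt(lo * hi)
        if max_re(mid) * f_lo > 0:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
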