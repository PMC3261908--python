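"""Closed-form promoter logic function, induction curves, and feedback ODEs.

The model chain is: LuxI level and cell density set the steady-state AHL
concentration (``A = c * rho * I``); AHL activates LuxR with Hill
cooperativity ``m``; active LuxR activates pR with Hill cooperativity ``n``
on top of a basal rate ``eps``.  The maximal pR rate is normalized to 1, so
the PLF returns a fraction of maximum in [eps, 1].
"""

from __future__ import annotations

import numpy as np

from .params import ConfigurationError, HillInductionParams, PLFParams, TopologySpec

__all__ = [
    "ahl_level",
    "active_luxr",
    "plf_eval",
    "hill_induction",
    "density_rescale",
    "ode_rhs",
]


def _check_nonnegative(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr


def ahl_level(luxI, density, const) -> np.ndarray | float:
    """Steady-state AHL concentration, proportional to density x LuxI.

    Parameters are the LuxI level (fluorescence a.u.), the cell density
    (OD600), and the protocol-specific proportionality constant ``c``.
    """
    I = _check_nonnegative("luxI", luxI)
    rho = _check_nonnegative("density", density)
    c = _check_nonnegative("const", const)
    out = c * rho * I
    return float(out) if out.ndim == 0 else out


def active_luxr(luxR, ahl, p: PLFParams):
    """AHL-bound (active) LuxR: R* = R * A^m / (K_A^m + A^m)."""
    R = np.asarray(luxR, dtype=float)
    A = np.asarray(ahl, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        Am = A**p.hill_m
        occ = np.where(A > 0, Am / (p.ahl_luxr_halfsat**p.hill_m + Am), 0.0)
    return R * occ


def plf_eval(luxI, luxR, p: PLFParams) -> np.ndarray | float:
    """Promoter logic function: pR transcription rate as fraction of maximum.

    AND-type in its two inputs: the output stays at the basal fraction
    unless both LuxI (hence AHL, at the given density) and LuxR are present.
    Bounded in [eps, 1] and monotone nondecreasing in both inputs.
    """
    I = _check_nonnegative("luxI", luxI)
    R = _check_nonnegative("luxR", luxR)
    A = ahl_level(I, p.density, p.ahl_density_const)
    Rstar = active_luxr(R, A, p)
    Kn = p.luxr_dna_halfsat**p.hill_n
    with np.errstate(over="ignore"):
        Rn = np.asarray(Rstar, dtype=float) ** p.hill_n
    # Guard the saturated limit where R*^n overflows: f -> 1.
    out = np.where(
        np.isinf(Rn), 1.0, (p.basal_fraction * Kn + Rn) / (Kn + Rn)
    )
    return float(out) if out.ndim == 0 else out


def hill_induction(inducer, q: HillInductionParams) -> np.ndarray | float:
    """Expression level driven by an inducible promoter (Hill curve).

    Returns ``basal + span * x^h / (halfsat^h + x^h)``; equals
    ``basal + span/2`` at ``x = halfsat``.
    """
    x = _check_nonnegative("inducer", inducer)
    with np.errstate(divide="ignore"):
        xh = x**q.hill
    out = q.basal + q.span * np.where(
        np.isinf(xh), 1.0, xh / (q.halfsat**q.hill + xh)
    )
    return float(out) if out.ndim == 0 else out


def density_rescale(p: PLFParams, factor: float) -> PLFParams:
    """PLF parameters at a density scaled by ``factor``.

    Because AHL enters only through the product ``c * rho * I``, evaluating
    the rescaled PLF at LuxI level ``I`` is identical to evaluating the
    original at ``I * factor`` — the density squeeze of the logic surface
    along its LuxI axis.
    """
    if not np.isfinite(factor) or factor <= 0:
        raise ValueError(f"factor must be positive and finite, got {factor}")
    return p.with_density(p.density * factor)


def ode_rhs(state, t, topo: TopologySpec, p: PLFParams) -> np.ndarray:
    """Right-hand side of the feedback circuit ODEs.

    State layout by topology kind:

    - ``feedforward``: ``[Z]``, dZ/dt = gamma_Z (lambda_Z f(I, R) - Z) with
      both regulators held at their fixed levels;
    - ``luxR_feedback``: ``[R]``, LuxR produced from pR, LuxI fixed;
    - ``luxI_feedback``: ``[I]``, LuxI produced from pR, LuxR fixed;
    - ``dual_positive``: ``[R, I]``, both proteins produced from pR.

    ``t`` is accepted (and ignored) so the signature suits ODE integrators.
    """
    x = np.atleast_1d(np.asarray(state, dtype=float))
    if x.shape[0] != topo.state_dim:
        raise ConfigurationError(
            f"state dimension {x.shape[0]} does not match topology "
            f"{topo.kind!r} (expected {topo.state_dim})"
        )
    x = np.clip(x, 0.0, None)  # integrators may step infinitesimally below 0
    if topo.kind == "feedforward":
        f = plf_eval(topo.luxI_fixed, topo.luxR_fixed, p)
        return np.array([topo.gamma_Z * (topo.lambda_Z * f - x[0])])
    if topo.kind == "luxR_feedback":
        f = plf_eval(topo.luxI_fixed, x[0], p)
        return np.array([topo.gamma_R * (topo.lambda_R * f - x[0])])
    if topo.kind == "luxI_feedback":
        f = plf_eval(x[0], topo.luxR_fixed, p)
        return np.array([topo.gamma_I * (topo.lambda_I * f - x[0])])
    # dual_positive
    f = plf_eval(x[1], x[0], p)
    return np.array(
        [
            topo.gamma_R * (topo.lambda_R * f - x[0]),
            topo.gamma_I * (topo.lambda_I * f - x[1]),
        ]
    )
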