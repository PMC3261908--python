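"""Nonlinear least-squares estimation of promoter-logic parameters.

The parameterized PLF is fit to a replicated two-input grid on the log
scale (measurement noise is multiplicative), with the AHL-LuxR Hill
coefficient ``m`` held fixed: fitted freely it drifts upward without bound
while the chi-square decreases monotonically, so the standard protocol is a
sweep over fixed ``m`` values.  A single-density grid cannot separate the
AHL half-saturation ``K_A`` from the AHL-to-density constant ``c``; the fit
therefore estimates their identifiable combination, the LuxI level at
half-saturating AHL, ``kappa = K_A / (c rho)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .model import plf_eval
from .params import ConfigurationError, PLFParams
from .synthetic import NoiseModel, PLFGrid, generate_plf_grid


class FitError(RuntimeError):
    """Raised when the least-squares fit cannot be performed or converge."""


@dataclass
class FitResult:
    """Best-fit PLF parameters and diagnostics.

    ``params`` is a :class:`PLFParams` whose AHL axis is normalized so that
    ``params.luxi_halfsat`` equals the fitted identifiable combination
    ``kappa`` (``ahl_density_const`` and ``density`` are set to 1); the PLF
    it defines on (LuxI, LuxR) fluorescence coordinates is fully determined.
    """

    params: PLFParams
    amplitude: float
    chi_square: float
    ndata: int
    nvarys: int
    fixed_m: float
    stderr: dict = field(default_factory=dict)
    success: bool = True
    message: str = ""

    @property
    def luxi_halfsat(self) -> float:
        return self.params.luxi_halfsat

    @property
    def reduced_chi_square(self) -> float:
        return self.chi_square / max(self.ndata - self.nvarys, 1)


def _prepare(grid: PLFGrid):
    s = grid.replicate_summary().dropna()
    I = s["luxI_cfp"].to_numpy()
    R = s["luxR_yfp"].to_numpy()
    y = s["output_cfp"].to_numpy()
    sem = s["log_sd"].to_numpy() / np.sqrt(np.maximum(s["n_rep"].to_numpy(), 1.0))
    if len(np.unique(np.round(np.log(I), 6))) < 2 or len(np.unique(np.round(np.log(R), 6))) < 2:
        raise FitError("grid needs >= 2 distinct levels per input axis")
    if np.ptp(np.log(y)) < 1e-9:
        raise FitError("flat grid: output shows no variation to fit")
    return I, R, y, sem


def _model_log(pars, I, R, m_fixed):
    p = PLFParams(
        basal_fraction=pars["eps"].value,
        ahl_luxr_halfsat=pars["kappa"].value,
        luxr_dna_halfsat=pars["K_R"].value,
        hill_m=m_fixed,
        hill_n=pars["n"].value,
        ahl_density_const=1.0,
        density=1.0,
    )
    return np.log(pars["amp"].value) + np.log(plf_eval(I, R, p))


def fit_plf(
    grid: PLFGrid,
    m_fixed: float = 2.0,
    init: PLFParams | None = None,
    weights: np.ndarray | None = None,
    n_starts: int = 5,
) -> FitResult:
    """Fit the parameterized PLF to a grid by weighted log-space least squares.

    Residuals are ``log(model) - log(data)`` on replicate geometric means,
    weighted by replicate standard errors of the log-output (uniform where
    these vanish, e.g. noise-free grids).  Five log-spaced multi-starts of
    the half-saturation parameters guard against local minima; the lowest
    chi-square wins, ties broken by first index.  Free parameters: basal
    fraction ``eps``, LuxI half-saturation combination ``kappa``, LuxR-DNA
    half-saturation ``K_R``, Hill ``n``, and output amplitude; ``m`` is held
    fixed.
    """
    if m_fixed < 1:
        raise ConfigurationError("m_fixed must be >= 1")
    I, R, y, sem = _prepare(grid)
    logy = np.log(y)
    if weights is None:
        # weight by SEM of log-output; uniform fallback where SEM ~ 0
        w = np.where(sem > 1e-6, 1.0 / np.clip(sem, 1e-6, None), 1.0)
        if np.any(sem <= 1e-6) and np.any(sem > 1e-6):
            w = np.ones_like(sem)  # mixed case: fall back to uniform
    else:
        w = np.asarray(weights, dtype=float)

    def residual(pars):
        return (_model_log(pars, I, R, m_fixed) - logy) * w

    amp0 = float(np.max(y))
    eps0 = float(np.clip(np.min(y) / amp0, 1e-5, 0.4))
    kappa_grid = np.geomspace(np.min(I[I > 0]) if np.any(I > 0) else 1.0, np.max(I), n_starts)
    KR0 = float(np.exp(np.mean(np.log(R))))
    if init is not None:
        kappa_grid = np.concatenate([[init.luxi_halfsat], kappa_grid])
        KR0 = init.luxr_dna_halfsat

    best = None
    for kappa0 in kappa_grid:
        pars = lmfit.Parameters()
        pars.add("eps", value=eps0, min=1e-8, max=0.9)
        pars.add("kappa", value=float(kappa0), min=1e-8 * np.max(I), max=1e4 * np.max(I))
        pars.add("K_R", value=KR0, min=1e-8 * np.max(R), max=1e6 * np.max(R))
        pars.add("n", value=init.hill_n if init is not None else 1.5, min=0.05, max=8.0)
        pars.add("amp", value=amp0, min=amp0 * 1e-4, max=amp0 * 1e4)
        try:
            res = lmfit.minimize(residual, pars, method="leastsq", nan_policy="raise")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr - 1e-30:
            best = res
    if best is None:
        raise FitError("all multi-start fits failed")
    bp = best.params
    fitted = PLFParams(
        basal_fraction=float(bp["eps"].value),
        ahl_luxr_halfsat=float(bp["kappa"].value),
        luxr_dna_halfsat=float(bp["K_R"].value),
        hill_m=float(m_fixed),
        hill_n=float(bp["n"].value),
        ahl_density_const=1.0,
        density=1.0,
    )
    stderr = {k: (bp[k].stderr if bp[k].stderr is not None else np.nan)
              for k in ("eps", "kappa", "K_R", "n", "amp")}
    return FitResult(
        params=fitted,
        amplitude=float(bp["amp"].value),
        chi_square=float(best.chisqr),
        ndata=len(y),
        nvarys=int(best.nvarys),
        fixed_m=float(m_fixed),
        stderr=stderr,
        success=bool(best.success),
        message=str(getattr(best, "message", "")),
    )


def sweep_m(
    grid: PLFGrid, m_values, init: PLFParams | None = None
) -> pd.DataFrame:
    """One fixed-``m`` fit per value; shared initialization policy.

    Returns a table with one row per ``m`` (chi-square, fitted parameters,
    success flag); per-fit failures appear as flagged rows rather than
    aborting the sweep.
    """
    m_values = np.asarray(m_values, dtype=float)
    if m_values.size < 2:
        raise ConfigurationError("sweep needs >= 2 m values")
    rows = []
    for m in m_values:
        try:
            r = fit_plf(grid, m_fixed=float(m), init=init)
            rows.append(
                dict(m=m, chi_square=r.chi_square, eps=r.params.basal_fraction,
                     kappa=r.params.luxi_halfsat, K_R=r.params.luxr_dna_halfsat,
                     n=r.params.hill_n, amp=r.amplitude, success=r.success)
            )
        except (FitError, ConfigurationError) as e:
            rows.append(dict(m=m, chi_square=np.nan, eps=np.nan, kappa=np.nan,
                             K_R=np.nan, n=np.nan, amp=np.nan, success=False))
    return pd.DataFrame(rows)


@dataclass
class GoodnessOfFit:
    """Monte-Carlo goodness-of-fit: Q is the fraction of synthetic datasets
    (generated from the fitted model with the estimated noise) whose refit
    chi-square exceeds the observed one."""

    q: float
    chi_square_observed: float
    chi_square_synthetic: np.ndarray
    n_failed: int


def goodness_of_fit_mc(
    grid: PLFGrid,
    fit: FitResult,
    trials: int = 1000,
    seed: int = 0,
) -> GoodnessOfFit:
    """Parametric-bootstrap calibration of the fit's chi-square.

    Synthetic grids are generated from the fitted PLF with log-normal noise
    on all three measured channels (inputs and output), with per-channel
    replicate-level log-SDs estimated from the real grid's scatter, then
    refit (single start from the fitted parameters, same fixed ``m``).
    Resampling the input channels matters: the real fit regresses on noisy
    replicate-averaged inputs, and synthetic datasets must carry the same
    error structure for their chi-squares to be comparable.  Refit failures
    are counted, not silently dropped.  A well-specified model yields Q
    roughly uniform on [0, 1]; gross misspecification drives Q toward 0.
    """
    if trials < 100:
        raise ConfigurationError("trials must be >= 100")
    I, R, y, sem = _prepare(grid)
    rng = np.random.default_rng(seed)
    model_log = _model_log_from_fit(fit, I, R)
    # pooled per-replicate log-SD per channel
    g = grid.data.groupby(["aTc_ng_ml", "IPTG_uM"])
    chan_sd = {}
    for col in ("luxI_cfp", "luxR_yfp", "output_cfp"):
        sds = g[col].apply(
            lambda v: np.std(np.log(np.clip(v, 1e-12, None)), ddof=1) if len(v) > 1 else 0.0
        )
        chan_sd[col] = float(np.sqrt(np.mean(sds.to_numpy() ** 2)))
    reps = max(int(round(len(grid.data) / max(len(y), 1))), 1)
    chis = []
    n_failed = 0
    for _ in range(trials):
        # per-replicate noise on every channel, then geometric-mean summary,
        # matching the real pipeline's averaging
        rows = []
        for k in range(len(y)):
            for r in range(reps):
                rows.append((
                    I[k], R[k], r + 1,
                    I[k] * np.exp(rng.normal(0.0, chan_sd["luxI_cfp"])),
                    R[k] * np.exp(rng.normal(0.0, chan_sd["luxR_yfp"])),
                    np.exp(model_log[k] + rng.normal(0.0, chan_sd["output_cfp"])),
                ))
        df = pd.DataFrame(rows, columns=["aTc_ng_ml", "IPTG_uM", "replicate",
                                         "luxI_cfp", "luxR_yfp", "output_cfp"])
        syn = PLFGrid(df, tuple(np.unique(df["aTc_ng_ml"])), tuple(np.unique(df["IPTG_uM"])))
        try:
            r = fit_plf(syn, m_fixed=fit.fixed_m, init=fit.params, n_starts=1)
            chis.append(r.chi_square)
        except (FitError, ConfigurationError):
            n_failed += 1
    chis = np.asarray(chis)
    q = float(np.mean(chis > fit.chi_square)) if chis.size else np.nan
    return GoodnessOfFit(
        q=q, chi_square_observed=fit.chi_square,
        chi_square_synthetic=chis, n_failed=n_failed,
    )


def _model_log_from_fit(fit: FitResult, I, R) -> np.ndarray:
    return np.log(fit.amplitude) + np.log(plf_eval(I, R, fit.params))
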