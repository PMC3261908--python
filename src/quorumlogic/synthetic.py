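"""Synthetic fluorescence datasets with the statistical structure of
single-cell imaging measurements.

The generators emulate the measurement design of a two-input promoter
characterization: a 6 x 7 inducer grid (aTc driving LuxI::CFP, IPTG driving
LuxR::YFP) read out by a CFP reporter from pR, with replicated measurements
and multiplicative log-normal noise (single-cell fluorescence distributions
are approximately log-normal, and population summaries are geometric means).
All fluorescence values are in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import hill_induction, ode_rhs, plf_eval
from .params import (
    ConfigurationError,
    DEFAULT_ATC_INDUCTION,
    DEFAULT_ATC_LEVELS,
    DEFAULT_IPTG_INDUCTION,
    DEFAULT_IPTG_LEVELS,
    HillInductionParams,
    PLFParams,
    TopologySpec,
)

GRID_COLUMNS = ["aTc_ng_ml", "IPTG_uM", "replicate", "luxI_cfp", "luxR_yfp", "output_cfp"]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal measurement noise.

    ``cv`` is the coefficient of variation of the multiplicative factor;
    ``cv = 0`` reproduces noise-free model output exactly.  The log-normal
    is parameterized to have unit mean.
    """

    cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ConfigurationError("cv must be >= 0")

    @property
    def sigma_log(self) -> float:
        """Standard deviation of log-factors implied by the CV."""
        return float(np.sqrt(np.log1p(self.cv**2)))

    def factors(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.cv == 0:
            return np.ones(shape)
        s = self.sigma_log
        return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=shape)


@dataclass
class PLFGrid:
    """A replicated two-input promoter logic dataset.

    ``data`` has one row per (aTc, IPTG, replicate) with measured LuxI::CFP,
    LuxR::YFP and output CFP fluorescence.
    """

    data: pd.DataFrame
    aTc_levels: tuple
    IPTG_levels: tuple

    def __post_init__(self) -> None:
        missing = [c for c in GRID_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"grid table missing columns: {missing}")
        fluor = self.data[["luxI_cfp", "luxR_yfp", "output_cfp"]].to_numpy()
        if np.any(fluor < 0):
            raise ConfigurationError("fluorescence values must be nonnegative")
        keys = self.data[["aTc_ng_ml", "IPTG_uM", "replicate"]]
        if keys.duplicated().any():
            row = int(np.nonzero(keys.duplicated().to_numpy())[0][0])
            raise ConfigurationError(f"duplicated replicate key at row {row}")

    @property
    def n_combinations(self) -> int:
        return len(self.aTc_levels) * len(self.IPTG_levels)

    def replicate_summary(self) -> pd.DataFrame:
        """Geometric-mean levels and log-SDs per inducer combination.

        Geometric means are the natural population summary for log-normally
        distributed fluorescence.  Returned frame is indexed by
        (aTc_ng_ml, IPTG_uM) in level order, with columns
        ``luxI_cfp``, ``luxR_yfp``, ``output_cfp`` (geometric means),
        ``log_sd`` and ``n_rep`` for the output channel.
        """
        df = self.data.copy()
        for col in ("luxI_cfp", "luxR_yfp", "output_cfp"):
            if (df[col] <= 0).any():
                # Floor at a tiny positive value so logs are defined.
                df[col] = df[col].clip(lower=1e-12)
        g = df.groupby(["aTc_ng_ml", "IPTG_uM"], sort=False)
        out = g.agg(
            luxI_cfp=("luxI_cfp", lambda v: float(np.exp(np.mean(np.log(v))))),
            luxR_yfp=("luxR_yfp", lambda v: float(np.exp(np.mean(np.log(v))))),
            output_cfp=("output_cfp", lambda v: float(np.exp(np.mean(np.log(v))))),
            log_sd=("output_cfp", lambda v: float(np.std(np.log(v), ddof=1)) if len(v) > 1 else 0.0),
            n_rep=("output_cfp", "size"),
        )
        # Stable level ordering
        idx = pd.MultiIndex.from_product(
            [self.aTc_levels, self.IPTG_levels], names=["aTc_ng_ml", "IPTG_uM"]
        )
        return out.reindex(idx)


def generate_plf_grid(
    p: PLFParams = None,
    qI: HillInductionParams = DEFAULT_ATC_INDUCTION,
    qR: HillInductionParams = DEFAULT_IPTG_INDUCTION,
    aTc_levels: Sequence[float] = DEFAULT_ATC_LEVELS,
    IPTG_levels: Sequence[float] = DEFAULT_IPTG_LEVELS,
    noise: NoiseModel = NoiseModel(),
    replicates: int = 3,
    output_scale: float = 1.0,
) -> PLFGrid:
    """Generate a replicated promoter-logic grid from the forward model.

    Per (aTc, IPTG) combination: LuxI and LuxR levels follow the inducer
    Hill curves, the output follows the PLF, and every measured value is
    multiplied by an independent log-normal factor with coefficient of
    variation ``noise.cv``.  Deterministic for a fixed ``noise.seed``.
    """
    if p is None:
        from .params import DEFAULT_PLF

        p = DEFAULT_PLF
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    if len(aTc_levels) == 0 or len(IPTG_levels) == 0:
        raise ConfigurationError("inducer level lists must be non-empty")
    rng = np.random.default_rng(noise.seed)
    rows = []
    for a in aTc_levels:
        for g in IPTG_levels:
            luxI = hill_induction(a, qI)
            luxR = hill_induction(g, qR)
            out = output_scale * plf_eval(luxI, luxR, p)
            fac = noise.factors(rng, (replicates, 3))
            for r in range(replicates):
                rows.append(
                    (a, g, r + 1, luxI * fac[r, 0], luxR * fac[r, 1], out * fac[r, 2])
                )
    df = pd.DataFrame(rows, columns=GRID_COLUMNS)
    return PLFGrid(df, tuple(aTc_levels), tuple(IPTG_levels))


def generate_equivalence_table(
    true_scale: float,
    backgrounds: tuple[float, float] = (0.0, 0.0),
    IPTG_levels: Sequence[float] = DEFAULT_IPTG_LEVELS,
    noise: NoiseModel = NoiseModel(),
    induction: HillInductionParams = DEFAULT_IPTG_INDUCTION,
) -> pd.DataFrame:
    """Paired-fluorescence calibration table for a line-of-equivalence fit.

    Two reporters are expressed from the same inducible promoter over a
    range of inducer levels; their fluorescence signals differ by a
    translation/detection scale factor and channel backgrounds:
    ``x = b_x + expr``, ``y = b_y + true_scale * expr * eta`` with a unit
    mean log-normal factor ``eta`` on the measured output channel.  With
    ``cv = 0`` the points are exactly affine:
    ``y = b_y + true_scale * (x - b_x)``.
    """
    if true_scale <= 0:
        raise ConfigurationError("true_scale must be > 0")
    if len(IPTG_levels) < 3:
        raise ConfigurationError("need >= 3 inducer levels for an affine fit")
    b_x, b_y = backgrounds
    rng = np.random.default_rng(noise.seed)
    expr = hill_induction(np.asarray(IPTG_levels, dtype=float), induction)
    fac = noise.factors(rng, len(expr))
    x = b_x + expr
    y = b_y + true_scale * expr * fac
    return pd.DataFrame({"IPTG_uM": IPTG_levels, "x": x, "y": y})


def generate_feedback_dataset(
    topo: TopologySpec,
    p: PLFParams,
    regulator_levels: Sequence[float],
    rho_T: float,
    histories: Sequence[str] = ("OFF", "ON"),
    noise: NoiseModel = NoiseModel(),
    t_max: float = 200.0,
    settle_tol: float = 1e-8,
) -> pd.DataFrame:
    """Terminal feedback responses from ON/OFF-history initial conditions.

    For each regulator level and history, the 1-D feedback ODE is integrated
    at terminal density ``rho_T`` from a basal (OFF) or saturated (ON)
    initial state until the relative rate of change falls below
    ``settle_tol``; the terminal level is reported with multiplicative
    measurement noise.  Non-convergent integrations are flagged in the
    ``converged`` column rather than dropped.
    """
    if len(regulator_levels) == 0:
        raise ConfigurationError("regulator_levels must be non-empty")
    if topo.kind not in ("luxR_feedback", "luxI_feedback"):
        raise ConfigurationError("feedback dataset requires a 1-D feedback topology")
    rng = np.random.default_rng(noise.seed)
    p_T = p.with_density(rho_T)
    lam = topo.feedback_lambda
    reg_field = "luxI_fixed" if topo.kind == "luxR_feedback" else "luxR_fixed"
    rows = []
    for reg in regulator_levels:
        t = topo.replace(**{reg_field: float(reg)})
        for hist in histories:
            if hist not in ("OFF", "ON"):
                raise ConfigurationError(f"unknown history {hist!r}")
            x0 = lam * p.basal_fraction if hist == "OFF" else lam
            sol = solve_ivp(
                lambda tt, y: ode_rhs(y, tt, t, p_T),
                (0.0, t_max),
                [x0],
                method="LSODA",
                rtol=1e-9,
                atol=1e-12 * lam,
            )
            x_end = float(sol.y[0, -1])
            rate = abs(ode_rhs([x_end], 0.0, t, p_T)[0])
            converged = bool(sol.success) and rate <= settle_tol * max(lam, x_end)
            measured = x_end * float(noise.factors(rng, ()))
            rows.append((reg, hist, x_end, measured, converged))
    return pd.DataFrame(
        rows, columns=["regulator", "history", "terminal", "measured", "converged"]
    )
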