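"""Stage-oriented pipeline runner: synthesize -> fit -> calibrate -> predict.

Each stage logs its inputs, outputs and timing; any stage failure aborts
the run with the stage name.  All randomness derives from the single run
seed, so a re-run with the same configuration is bit-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as qio
from .calibration import fit_equivalence_line
from .ddr import classify_ddr, compute_ddr
from .fitting import fit_plf, sweep_m
from .params import (
    DEFAULT_LUXI_FEEDBACK,
    DEFAULT_LUXR_FEEDBACK,
    DEFAULT_PLF,
    DEFAULT_RHO_T_AUTONOMOUS,
    write_params,
)
from .predict import mc_predict
from .synthetic import NoiseModel, generate_equivalence_table, generate_plf_grid

log = logging.getLogger("quorumlogic")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str | Path = "quorumlogic_run"
    seed: int = 0
    noise_cv: float = 0.15
    replicates: int = 3
    m_fixed: float = 2.0
    mc_trials: int = 1000
    equivalence_scale: float = 0.5
    force: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("seed", "noise_cv", "replicates", "m_fixed", "mc_trials",
                 "equivalence_scale")}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the demo pipeline end to end; returns a result summary.

    Stages: synthetic grid and calibration table generation; equivalence
    line fit; PLF fit (fixed-m sweep); model-independent Monte-Carlo
    predictions per topology; DDR classification of the default feedback
    loops.  Artifacts are written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = qio.config_digest(config.as_dict())
    meta = {"seed": config.seed, "config_digest": digest}
    results: dict = {"config_digest": digest}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                r = fn()
            except Exception:
                log.error("stage %s: FAILED", name)
                raise
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return r
        return wrap

    noise = NoiseModel(cv=config.noise_cv, seed=config.seed)

    grid = stage("make-synthetic")(
        lambda: generate_plf_grid(noise=noise, replicates=config.replicates)
    )
    qio.write_grid(grid, out / "plf_grid.tsv", metadata=meta, force=True)

    eq = stage("make-equivalence")(
        lambda: generate_equivalence_table(
            config.equivalence_scale, noise=NoiseModel(cv=config.noise_cv,
                                                       seed=config.seed + 1)
        )
    )
    qio.write_table(eq, out / "equivalence.tsv", metadata=meta, force=True)

    line = stage("calibrate")(lambda: fit_equivalence_line(eq))
    write_params(line, out / "equivalence_line.params", header=f"config {digest}")

    fit = stage("fit-plf")(lambda: fit_plf(grid, m_fixed=config.m_fixed))
    write_params(fit.params, out / "plf_fit.params",
                 header=f"chi_square {fit.chi_square:.6g}; config {digest}")
    sweep = stage("sweep-m")(lambda: sweep_m(grid, [1.0, 1.5, 2.0, 3.0]))
    qio.write_table(sweep, out / "m_sweep.tsv", metadata=meta, force=True)
    results["fit_chi_square"] = fit.chi_square
    results["fit_n"] = fit.params.hill_n

    mc = stage("predict")(
        lambda: mc_predict(grid, line, axis="luxI", regulator_index=3,
                           trials=config.mc_trials, seed=config.seed + 2)
    )
    results["multistable_fraction"] = mc.multistable_fraction

    def ddr_stage():
        classes = {}
        for name, topo in (("luxR_feedback", DEFAULT_LUXR_FEEDBACK),
                           ("luxI_feedback", DEFAULT_LUXI_FEEDBACK)):
            curve = compute_ddr(topo, DEFAULT_PLF, rho_T=DEFAULT_RHO_T_AUTONOMOUS)
            classes[name] = classify_ddr(curve).value
        return classes

    results["ddr_classes"] = stage("ddr")(ddr_stage)
    log.info("pipeline complete: %s", results)
    return results
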