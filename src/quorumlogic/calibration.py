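"""Fluorescence calibration: backgrounds and lines of equivalence.

When a feedback loop is closed, the input and output protein levels are
forced onto an affine relation whose slope is the ratio of translation
efficiencies — the *line of equivalence*.  It is measured by expressing the
two reporters from the same inducible promoter and fitting the paired
fluorescence readings.  After background subtraction the line passes
through the origin, and appears with unit slope on a log-log plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ConfigurationError


class CalibrationError(ValueError):
    """Raised when an equivalence-line fit is degenerate or unphysical."""


@dataclass(frozen=True)
class EquivalenceLine:
    """Affine input-to-output fluorescence calibration ``y = b_y + s (x - b_x)``."""

    scale: float
    background_x: float = 0.0
    background_y: float = 0.0
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise CalibrationError("scale must be > 0")
        if self.background_x < 0 or self.background_y < 0:
            raise CalibrationError("backgrounds must be >= 0")

    def predict(self, x):
        return self.background_y + self.scale * (np.asarray(x, dtype=float) - self.background_x)


def fit_equivalence_line(
    pairs: pd.DataFrame | np.ndarray,
    background_x: float | None = None,
) -> EquivalenceLine:
    """Least-squares affine fit of paired fluorescence readings.

    ``pairs`` is a table with columns ``x`` and ``y`` (or a 2-column array).
    The slope is the input-to-output scale factor.  Fluorescence noise is
    multiplicative, so residuals are weighted by ``1/x^2`` (constant
    relative error); the weights depend only on the regressor, keeping the
    slope estimate unbiased.  The split of the fitted
    intercept into channel backgrounds is not determined by the pairs alone:
    if an independent zero-inducer reading of the x channel is supplied as
    ``background_x``, the y background is derived from the intercept at that
    reading; otherwise the x background is taken as zero and the intercept
    is assigned entirely to the y channel.
    """
    if isinstance(pairs, pd.DataFrame):
        x = pairs["x"].to_numpy(dtype=float)
        y = pairs["y"].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise CalibrationError("need >= 3 pairs for an affine fit")
    if np.ptp(x) == 0:
        raise CalibrationError("degenerate calibration: x values are all equal")
    # Affine fit y = a + s x, weighted for constant relative error
    w = 1.0 / np.maximum(x, 1e-6 * np.max(np.abs(x))) ** 2
    A = np.column_stack([np.ones_like(x), x])
    sw = np.sqrt(w)
    (a, s), *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    if s <= 0:
        raise CalibrationError(
            f"fitted scale {s:.3g} <= 0: channels appear miscalibrated"
        )
    resid = y - (a + s * x)
    dof = max(len(x) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    b_x = 0.0 if background_x is None else float(background_x)
    b_y = float(a + s * b_x)
    if b_y < 0:
        b_y = 0.0  # intercept slightly below zero under noise: clamp
    return EquivalenceLine(scale=float(s), background_x=b_x, background_y=b_y,
                           residual_sd=residual_sd)


def subtract_background(values, background, floor: float = 1e-6):
    """Background-subtract fluorescence, clamped at a positive floor.

    The floor keeps subsequent log-log interpolation defined; clamping is
    part of the contract, not an error.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    v = np.asarray(values, dtype=float)
    out = np.maximum(v - background, floor)
    return float(out) if out.ndim == 0 else out
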