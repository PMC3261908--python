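"""Parameter containers for the promoter logic function and circuit topologies.

All fluorescence quantities are in arbitrary units (a.u.); cell density is
OD600 throughout.  The promoter logic function (PLF) gives the transcription
rate of the LuxR-dependent promoter pR as a fraction of its maximal rate, as
a function of the LuxI and LuxR levels of the cell at a given density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable


class ConfigurationError(ValueError):
    """Raised when a parameter set or topology violates its invariants."""


@dataclass(frozen=True)
class PLFParams:
    """Biochemical constants of the parameterized promoter logic function.

    Attributes
    ----------
    basal_fraction:
        Basal transcription rate of pR relative to its maximum (``0 < eps < 1``).
    ahl_luxr_halfsat:
        Half-saturation AHL concentration for AHL-LuxR binding, in AHL a.u.
    luxr_dna_halfsat:
        Half-saturation level of active (AHL-bound) LuxR for pR activation,
        in LuxR fluorescence a.u.
    hill_m:
        Hill coefficient of AHL-LuxR binding (cooperativity of activation by
        the signal).
    hill_n:
        Hill coefficient of active-LuxR/DNA binding.
    ahl_density_const:
        Proportionality constant ``c`` linking steady-state AHL to
        density x LuxI (AHL a.u. per (OD600 x LuxI a.u.)).  Protocol
        specific: sender-receiver and autonomous-loop growth modalities
        accumulate AHL differently.
    density:
        Cell density (OD600) at which the PLF is evaluated.
    """

    basal_fraction: float = 0.008
    ahl_luxr_halfsat: float = 100.0
    luxr_dna_halfsat: float = 40.0
    hill_m: float = 2.0
    hill_n: float = 1.45
    ahl_density_const: float = 20.0
    density: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.basal_fraction < 1.0:
            raise ConfigurationError(
                f"basal_fraction must lie in (0, 1), got {self.basal_fraction}"
            )
        for name in ("ahl_luxr_halfsat", "luxr_dna_halfsat", "ahl_density_const"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.hill_m < 1:
            raise ConfigurationError("hill_m must be >= 1")
        if self.hill_n <= 0:
            raise ConfigurationError("hill_n must be > 0")
        if self.density < 0:
            raise ConfigurationError("density must be >= 0")

    @property
    def luxi_halfsat(self) -> float:
        """LuxI level at which AHL reaches its half-saturation, K_A/(c*rho).

        This combination, not K_A and c separately, is what a single-density
        PLF measurement determines.
        """
        if self.density == 0:
            return math.inf
        return self.ahl_luxr_halfsat / (self.ahl_density_const * self.density)

    def with_density(self, density: float) -> "PLFParams":
        return replace(self, density=density)

    def replace(self, **kw) -> "PLFParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class HillInductionParams:
    """Hill-shaped inducer -> expression curve for an inducible promoter.

    Expression rises from ``basal`` at zero inducer to ``basal + span`` at
    saturation, with half-maximal induction at ``halfsat``.
    """

    basal: float
    span: float
    halfsat: float
    hill: float

    def __post_init__(self) -> None:
        if self.basal < 0:
            raise ConfigurationError("basal must be >= 0")
        if self.span <= 0:
            raise ConfigurationError("span must be > 0")
        if self.halfsat <= 0:
            raise ConfigurationError("halfsat must be > 0")
        if self.hill <= 0:
            raise ConfigurationError("hill must be > 0")


TOPOLOGY_KINDS = (
    "feedforward",
    "luxR_feedback",
    "luxI_feedback",
    "dual_positive",
)


@dataclass(frozen=True)
class TopologySpec:
    """Which protein(s) close the loop at pR, and their scaled rates.

    ``lambda_*`` are production rates per unit transcription divided by the
    decay rate, so that steady states live directly in fluorescence units
    (a protein at full pR activity settles at ``lambda``).  ``gamma_*`` are
    response (decay/dilution) rates, in 1/time.  ``luxI_fixed`` and
    ``luxR_fixed`` are the constitutively expressed regulator levels required
    by the topology.
    """

    kind: str
    lambda_R: float | None = None
    lambda_I: float | None = None
    lambda_Z: float | None = None
    gamma_R: float = 1.0
    gamma_I: float = 1.0
    gamma_Z: float = 1.0
    luxI_fixed: float | None = None
    luxR_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in TOPOLOGY_KINDS:
            raise ConfigurationError(
                f"unknown topology kind {self.kind!r}; expected one of {TOPOLOGY_KINDS}"
            )
        required = {
            "feedforward": ("lambda_Z", "luxI_fixed", "luxR_fixed"),
            "luxR_feedback": ("lambda_R", "luxI_fixed"),
            "luxI_feedback": ("lambda_I", "luxR_fixed"),
            "dual_positive": ("lambda_R", "lambda_I"),
        }[self.kind]
        for name in required:
            value = getattr(self, name)
            if value is None:
                raise ConfigurationError(f"topology {self.kind!r} requires {name}")
            if name.startswith("lambda") and value <= 0:
                raise ConfigurationError(f"{name} must be > 0")
            if name.startswith("lux") and value < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("gamma_R", "gamma_I", "gamma_Z"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    @property
    def state_dim(self) -> int:
        return 2 if self.kind == "dual_positive" else 1

    @property
    def feedback_lambda(self) -> float:
        """Production scale of the protein in feedback (1-D topologies)."""
        if self.kind == "feedforward":
            return self.lambda_Z
        if self.kind == "luxR_feedback":
            return self.lambda_R
        if self.kind == "luxI_feedback":
            return self.lambda_I
        raise ConfigurationError(f"{self.kind} has no single feedback protein")

    def replace(self, **kw) -> "TopologySpec":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Canonical default parameter set (synthetic, arbitrary fluorescence units).
#
# The defaults describe an AND-type pR promoter whose output spans two orders
# of magnitude over the default induction grid, a LuxR-feedback loop whose
# production strength sits below the bistability window (monostable for every
# regulator level and density), and a LuxI-feedback loop strong enough to be
# bistable/hysteretic at intermediate regulator levels.
# ---------------------------------------------------------------------------

DEFAULT_PLF = PLFParams()

#: aTc -> LuxI::CFP induction (pTet), aTc in ng/ml.
DEFAULT_ATC_INDUCTION = HillInductionParams(basal=10.0, span=1000.0, halfsat=10.0, hill=2.0)

#: IPTG -> LuxR::YFP induction (pLac), IPTG in uM.
DEFAULT_IPTG_INDUCTION = HillInductionParams(basal=10.0, span=600.0, halfsat=60.0, hill=1.5)

#: Inducer levels of the default two-input induction grid.
DEFAULT_ATC_LEVELS = (0.0, 1.0, 5.0, 10.0, 20.0, 50.0)
DEFAULT_IPTG_LEVELS = (0.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0)

#: Terminal densities (OD600): autonomous loops vs sender-receiver protocol.
DEFAULT_RHO_T_AUTONOMOUS = 0.05
DEFAULT_RHO_T_SENDER_RECEIVER = 0.1

DEFAULT_LUXR_FEEDBACK = TopologySpec(
    kind="luxR_feedback", lambda_R=60.0, luxI_fixed=100.0
)
#: default regulator is the IPTG = 10 uM pLac-induced LuxR level, inside the
#: hysteretic window of the LuxI-feedback loop at the autonomous terminal density
DEFAULT_LUXI_FEEDBACK = TopologySpec(
    kind="luxI_feedback", lambda_I=600.0, luxR_fixed=48.0
)


# ---------------------------------------------------------------------------
# Flat key/value parameter-file serialization
# ---------------------------------------------------------------------------

def default_params_path() -> Path:
    """Path of the canonical default PLF parameter file shipped with the package."""
    return Path(__file__).parent / "data" / "default_plf.params"


def _coerce(text: str):
    text = text.strip()
    if text in ("None", ""):
        return None
    try:
        return float(text)
    except ValueError:
        return text


def write_params(obj, path: str | Path, header: str | None = None) -> None:
    """Write a dataclass as a flat ``key = value`` text file."""
    lines = []
    if header:
        lines.extend(f"# {line}" for line in header.splitlines())
    for f in fields(obj):
        lines.append(f"{f.name} = {getattr(obj, f.name)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path: str | Path, cls):
    """Read a flat ``key = value`` file back into dataclass ``cls``."""
    kw = {}
    known = {f.name for f in fields(cls)}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"malformed parameter line: {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in known:
            raise ConfigurationError(f"unknown parameter {key!r} for {cls.__name__}")
        kw[key] = _coerce(value)
    return cls(**kw)
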