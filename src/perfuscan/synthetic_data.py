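"""Seeded generators emulating the study's measurement series.

Everything the analysis pipeline consumes can be generated here with the
statistical structure the method assumes, so the full pipeline is testable
without any acquisition:

* cadaver-perfusion temperature records — cadaver rectal temperature at
  external examination uniform over the observed 9-31.6 degC span, excreted
  perfusate temperature from the packaged in-cadaver model (physical
  convention) plus Gaussian noise with the model's residual spread
  (0.8778 degC by default), pre-scan perfusate temperature uniform over the
  20-24 degC storage band, in-cadaver dwell time uniform over 1-23 min;
* inversion-recovery series at the scanner's TI protocol
  {50, 100, 200, 350, 600, 1000, 4000} ms;
* multi-echo spin-echo trains (spacing 10.6 or 20 ms, 32 echoes) with an
  inflated first echo emulating the stimulated-echo artifact that motivates
  the discard-first-echo rule;
* viscosity triplets at 8/10/20 degC with density back-filled so that the
  kinematic viscosity * density product reproduces the noisy dynamic value.

MR noise is Gaussian on the signed signal (sigma defaulting to 1 % of S0)
or Rician on the magnitude.  All generators are pure functions of
(config, parameters): the same seed reproduces the same output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import DomainError, InputError
from .relaxometry import EchoDecaySeries, InversionRecoverySeries, PROTOCOL_TI_MS
from .temp_models import QuadraticTempModel, ViscosityMeasurement, load_registry

__all__ = [
    "CadaverPerfusionRecord",
    "GeneratorConfig",
    "gen_cadaver_temps",
    "gen_ir_series",
    "gen_mse_series",
    "gen_viscosity_measurements",
    "default_cadaver_model",
    "CADAVER_TEMP_RANGE_C",
    "PERFUSATE_STORAGE_RANGE_C",
    "DWELL_TIME_RANGE_MIN",
    "CADAVER_MODEL_RSE_C",
]

#: Observed cadaver core-temperature span (degC) in the perfusion study.
CADAVER_TEMP_RANGE_C = (9.0, 31.6)
#: Ambient storage band of the perfusate before the scan (degC).
PERFUSATE_STORAGE_RANGE_C = (20.0, 24.0)
#: In-cadaver dwell time of the excreted perfusate (minutes).
DWELL_TIME_RANGE_MIN = (1.0, 23.0)
#: Residual standard error of the in-cadaver temperature model (degC).
CADAVER_MODEL_RSE_C = 0.8778

_DEFAULT_S0 = 1000.0


@dataclass(frozen=True)
class CadaverPerfusionRecord:
    """One perfused cadaver: temperatures (degC) and dwell time (min)."""

    theta_ee: float  # cadaver rectal temperature at external examination
    theta_p0: float  # perfusate temperature before the scan
    theta_p1: float  # excreted perfusate temperature
    time_c: float    # minutes the perfusate spent in the cadaver

    def __post_init__(self):
        for name in ("theta_ee", "theta_p0", "theta_p1"):
            v = getattr(self, name)
            if not (0.0 <= v <= 45.0):
                raise DomainError(f"{name}={v} outside the plausible 0-45 degC band")
        if self.time_c < 0:
            raise DomainError("time_c must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded generator settings.

    ``noise_sigma=None`` means "use the generator's own default" (the
    model's residual spread for temperature/viscosity data, 1 % of S0 for
    MR series).
    """

    seed: int = 0
    n: int = 21
    noise_sigma: float | None = None
    noise_model: Literal["gaussian", "rician"] = "gaussian"

    def __post_init__(self):
        if self.n < 1:
            raise InputError("n must be >= 1")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise InputError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise InputError(f"unknown noise_model {self.noise_model!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_cadaver_model() -> QuadraticTempModel:
    """Packaged in-cadaver temperature model under the physical convention,
    so generated data show the observed positive temperature correlation."""
    return load_registry().cadaver_model.with_convention("physical")


def gen_cadaver_temps(
    config: GeneratorConfig,
    model: QuadraticTempModel | None = None,
) -> list[CadaverPerfusionRecord]:
    """Generate ``config.n`` cadaver-perfusion temperature records."""
    if model is None:
        model = default_cadaver_model()
    sigma = CADAVER_MODEL_RSE_C if config.noise_sigma is None else config.noise_sigma
    rng = config.rng()
    theta_ee = rng.uniform(*CADAVER_TEMP_RANGE_C, size=config.n)
    theta_p0 = rng.uniform(*PERFUSATE_STORAGE_RANGE_C, size=config.n)
    time_c = rng.uniform(*DWELL_TIME_RANGE_MIN, size=config.n)
    theta_p1 = np.array([model(t) for t in theta_ee]) + rng.normal(0.0, sigma, size=config.n)
    theta_p1 = np.clip(theta_p1, 0.0, 45.0)
    return [
        CadaverPerfusionRecord(
            theta_ee=float(a), theta_p0=float(b), theta_p1=float(c), time_c=float(d)
        )
        for a, b, c, d in zip(theta_ee, theta_p0, theta_p1, time_c)
    ]


def _noisy_signal(signed: np.ndarray, sigma: float, noise_model: str,
                  rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Apply the configured noise; returns (signals, magnitude_flag)."""
    if noise_model == "gaussian":
        return signed + rng.normal(0.0, sigma, size=signed.shape), False
    # Rician: magnitude of the complex signal with iid Gaussian noise on
    # both quadratures; sigma = 0 degenerates to |signed|.
    re = signed + rng.normal(0.0, sigma, size=signed.shape)
    im = rng.normal(0.0, sigma, size=signed.shape)
    return np.hypot(re, im), True


def gen_ir_series(
    t1: float,
    config: GeneratorConfig,
    protocol: Sequence[float] = PROTOCOL_TI_MS,
    s0: float = _DEFAULT_S0,
    inversion_factor: float = 1.0,
) -> InversionRecoverySeries:
    """Inversion-recovery signals S(TI) = S0 (1 - 2A exp(-TI/T1)) + noise."""
    if t1 <= 0:
        raise DomainError("t1 must be positive")
    sigma = 0.01 * s0 if config.noise_sigma is None else config.noise_sigma
    ti = np.asarray(protocol, dtype=float)
    signed = s0 * (1.0 - 2.0 * inversion_factor * np.exp(-ti / t1))
    signals, magnitude = _noisy_signal(signed, sigma, config.noise_model, config.rng())
    return InversionRecoverySeries(inversion_times=ti, signals=signals,
                                   magnitude_flag=magnitude)


def gen_mse_series(
    t2: float,
    config: GeneratorConfig,
    echo_spacing: float = 20.0,
    etl: int = 32,
    first_echo_bias: float = 0.1,
    s0: float = _DEFAULT_S0,
) -> EchoDecaySeries:
    """Echo-train signals S(TE) = S0 exp(-TE/T2) with an inflated first echo.

    The first echo is multiplied by ``1 + first_echo_bias`` to emulate the
    stimulated-echo contamination that makes it unreliable in practice.
    """
    if t2 <= 0:
        raise DomainError("t2 must be positive")
    if etl < 3:
        raise InputError("etl must be >= 3")
    sigma = 0.01 * s0 if config.noise_sigma is None else config.noise_sigma
    te = echo_spacing * np.arange(1, etl + 1, dtype=float)
    clean = s0 * np.exp(-te / t2)
    clean[0] *= 1.0 + first_echo_bias
    signals, _ = _noisy_signal(clean, sigma, config.noise_model, config.rng())
    return EchoDecaySeries(echo_times=te, signals=signals)


def gen_viscosity_measurements(
    model: QuadraticTempModel,
    config: GeneratorConfig,
    temps: Sequence[float] = (8.0, 10.0, 20.0),
) -> list[ViscosityMeasurement]:
    """Viscometer triplets whose dynamic viscosity scatters about ``model``.

    Density is drawn uniform over 0.8-1.15 g/cm^3 (the span of the studied
    liquids) and the kinematic viscosity back-filled as mu/rho, so every
    record satisfies mu = nu * rho exactly.
    """
    if model.quantity != "viscosity_mPa_s":
        raise InputError("model must describe viscosity_mPa_s")
    sigma = (model.rse or 0.1) if config.noise_sigma is None else config.noise_sigma
    rng = config.rng()
    out = []
    for theta in temps:
        mu = float(model(theta)) + float(rng.normal(0.0, sigma)) if sigma > 0 else float(model(theta))
        rho = float(rng.uniform(0.8, 1.15))
        out.append(ViscosityMeasurement(
            temperature=float(theta), kinematic_viscosity=mu / rho, density=rho,
        ))
    return out
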