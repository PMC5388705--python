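"""Empirical quadratic temperature-dependence models for perfusate properties.

Post-mortem angiography perfuses cadaver vessels with a liquid whose
behaviour — dynamic viscosity, MR relaxation times — depends strongly on
temperature, and cadaver core temperatures span roughly 0-30 degC.  Each
property is described by the same empirical quadratic form

    q(theta) = q(theta_ref) + A * dtheta + B * dtheta**2

where ``dtheta`` is a signed temperature offset from a reference
temperature.  Two sign conventions for ``dtheta`` are supported and must be
chosen explicitly:

``as_printed``
    dtheta = theta_ref - theta.  This is how the coefficient tables for the
    packaged models are published, and reproduces their printed claims
    (e.g. the 27-33 mPa*s viscosity window of the preferred perfusates
    over 8-20 degC).

``physical``
    dtheta = theta - theta_ref.  With the same coefficients this mirrors
    the model about the reference temperature and yields the physically
    observed correlations (viscosity falls, relaxation times rise, with
    temperature).  The synthetic-data generators use this convention.

The packaged registry carries the quadratic coefficients for the nine
experimentally characterised liquids (viscosity referenced to 20 degC,
T1/T2 referenced to 23 degC) and the in-cadaver perfusate-temperature
model (excreted perfusate temperature as a function of cadaver rectal
temperature, referenced to the warmest observed cadaver, 31.6 degC).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .exceptions import ComputationError, DomainError, ExtrapolationWarning, FitError, InputError

__all__ = [
    "Convention",
    "QuadraticTempModel",
    "ViscosityMeasurement",
    "PerfusateRecord",
    "FitDiagnostics",
    "Registry",
    "dynamic_viscosity",
    "evaluate_model",
    "fit_quadratic",
    "pearson_r",
    "load_registry",
    "save_registry",
    "PREFERRED_PERFUSATES",
]

Convention = Literal["as_printed", "physical"]
_CONVENTIONS = ("as_printed", "physical")

#: Temperature band (degC) outside which evaluation warns: the empirical
#: models were built from measurements between roughly 0.6 and 23.2 degC.
VALID_TEMP_BAND = (0.0, 40.0)

#: The two liquids preferred for targeted post-mortem MR angiography on
#: physical (viscosity) and relaxation grounds.
PREFERRED_PERFUSATES = ("Paraffin oil", "Paraffin oil + Angiofil (6%)")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadraticTempModel:
    """Quadratic model of a temperature-dependent quantity.

    Parameters
    ----------
    quantity:
        What the model describes; canonical values are ``viscosity_mPa_s``,
        ``T1_ms``, ``T2_ms`` and ``perfusate_temp_C``.
    reference_temperature:
        Reference temperature in degC at which the model returns
        ``reference_value`` exactly (under either convention).
    reference_value:
        Value of the quantity at the reference temperature, in the
        quantity's units.
    linear_coeff, quad_coeff:
        Coefficients A (units/degC) and B (units/degC^2).
    delta_convention:
        Sign convention for the temperature offset; mandatory, no silent
        default (see module docstring).
    rse:
        Residual standard error of the fit that produced the coefficients,
        in quantity units (optional).
    coeff_se:
        Standard errors of (A, B) when known (optional).
    """

    quantity: str
    reference_temperature: float
    reference_value: float
    linear_coeff: float
    quad_coeff: float
    delta_convention: Convention
    rse: float | None = None
    coeff_se: tuple[float, float] | None = None

    def __post_init__(self):
        if not math.isfinite(self.reference_temperature):
            raise DomainError("reference_temperature must be finite")
        if self.delta_convention not in _CONVENTIONS:
            raise InputError(
                f"delta_convention must be one of {_CONVENTIONS}, "
                f"got {self.delta_convention!r}"
            )
        if self.rse is not None and self.rse < 0:
            raise DomainError("rse must be non-negative")

    def delta(self, theta):
        """Signed temperature offset for ``theta`` under this convention."""
        theta = np.asarray(theta, dtype=float)
        if self.delta_convention == "as_printed":
            d = self.reference_temperature - theta
        else:
            d = theta - self.reference_temperature
        return d if d.ndim else float(d)

    def __call__(self, theta):
        return evaluate_model(self, theta)

    def with_convention(self, convention: Convention) -> "QuadraticTempModel":
        """Same coefficients under the other sign convention (mirror model)."""
        return replace(self, delta_convention=convention)


@dataclass(frozen=True)
class ViscosityMeasurement:
    """One viscometer reading: kinematic viscosity plus density.

    Dynamic viscosity is derived as mu = nu * rho (mPa*s from mm^2/s and
    g/cm^3).
    """

    temperature: float
    kinematic_viscosity: float  # nu, mm^2/s
    density: float              # rho, g/cm^3
    dynamic_viscosity: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "dynamic_viscosity",
            dynamic_viscosity(self.kinematic_viscosity, self.density),
        )


@dataclass(frozen=True)
class PerfusateRecord:
    """A named liquid with its (optional) property models."""

    name: str
    nature: Literal["lipophilic", "hygroscopic", "hydrophilic"]
    viscosity_model: QuadraticTempModel | None = None
    t1_model: QuadraticTempModel | None = None
    t2_model: QuadraticTempModel | None = None


@dataclass(frozen=True)
class FitDiagnostics:
    """OLS diagnostics: rse = sqrt(rss / degrees_of_freedom)."""

    rss: float
    rse: float
    degrees_of_freedom: int
    coeff_se: tuple[float, ...]

    def __post_init__(self):
        if self.degrees_of_freedom < 1:
            raise ComputationError("degrees_of_freedom must be >= 1")


@dataclass(frozen=True)
class Registry:
    """The packaged model collection: perfusates plus the cadaver model."""

    perfusates: dict[str, PerfusateRecord]
    cadaver_model: QuadraticTempModel

    def __getitem__(self, name: str) -> PerfusateRecord:
        return self.perfusates[name]

    def __len__(self) -> int:
        return len(self.perfusates)

    def __iter__(self):
        return iter(self.perfusates.values())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def dynamic_viscosity(nu: float, rho: float) -> float:
    """Dynamic (absolute) viscosity mu = nu * rho.

    Parameters are kinematic viscosity ``nu`` in mm^2/s and density ``rho``
    in g/cm^3; the product is the dynamic viscosity in mPa*s.
    """
    if nu < 0:
        raise DomainError(f"kinematic viscosity must be >= 0, got {nu}")
    if rho <= 0:
        raise DomainError(f"density must be > 0, got {rho}")
    return nu * rho


def evaluate_model(model: QuadraticTempModel, theta):
    """Evaluate a quadratic temperature model at temperature(s) ``theta`` (degC).

    Warns (:class:`ExtrapolationWarning`) outside the 0-40 degC band the
    empirical fits plausibly cover; scalar in, scalar out.
    """
    arr = np.asarray(theta, dtype=float)
    lo, hi = VALID_TEMP_BAND
    if np.any((arr < lo) | (arr > hi)):
        warnings.warn(
            f"evaluating {model.quantity} model outside [{lo}, {hi}] degC",
            ExtrapolationWarning,
            stacklevel=2,
        )
    d = np.asarray(model.delta(theta), dtype=float)
    out = model.reference_value + model.linear_coeff * d + model.quad_coeff * d * d
    return out if out.ndim else float(out)


def fit_quadratic(
    points: Iterable[tuple[float, float]],
    reference_temperature: float,
    convention: Convention,
    fix_intercept: bool = False,
    intercept_value: float | None = None,
    quantity: str = "generic",
) -> tuple[QuadraticTempModel, FitDiagnostics]:
    """Ordinary least squares fit of the quadratic model in the offset basis.

    Parameters
    ----------
    points:
        (temperature degC, value) pairs.
    reference_temperature, convention:
        Define the offset ``dtheta`` in which the design matrix is built.
    fix_intercept:
        If true, the reference value is not fitted: it is taken from
        ``intercept_value``, or, when that is ``None``, from a supplied point
        lying exactly at the reference temperature.
    quantity:
        Passed through to the returned model.

    Returns the fitted model (which evaluates through the fit) and OLS
    diagnostics with ``df = n - p`` (p counts fitted parameters only).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("points must be (temperature, value) pairs")
    temps, values = pts[:, 0], pts[:, 1]
    n = len(temps)
    n_distinct = len(np.unique(temps))

    if fix_intercept:
        if intercept_value is None:
            at_ref = np.isclose(temps, reference_temperature)
            if not at_ref.any():
                raise InputError(
                    "fix_intercept=True needs intercept_value or a point at "
                    "the reference temperature"
                )
            intercept_value = float(values[at_ref][0])
        p = 2
        min_distinct = 2
    else:
        p = 3
        min_distinct = 3
    if n < 3:
        raise InputError(f"need at least 3 points, got {n}")
    if n_distinct < min_distinct:
        raise FitError(
            f"rank-deficient design: {n_distinct} distinct temperatures, "
            f"need {min_distinct}"
        )
    df = n - p
    if df < 1:
        raise InputError(f"degrees of freedom {df} < 1 (n={n}, p={p})")

    if convention not in _CONVENTIONS:
        raise InputError(f"unknown convention {convention!r}")
    d = (reference_temperature - temps) if convention == "as_printed" else (temps - reference_temperature)

    if fix_intercept:
        X = np.column_stack([d, d * d])
        y = values - intercept_value
    else:
        X = np.column_stack([np.ones(n), d, d * d])
        y = values
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise FitError("rank-deficient design matrix")

    resid = y - X @ coef
    rss = float(resid @ resid)
    rse = math.sqrt(rss / df)
    xtx_inv = np.linalg.inv(X.T @ X)
    coeff_se = tuple(float(s) for s in np.sqrt(np.diag(xtx_inv)) * rse)

    if fix_intercept:
        ref_value, a, b = intercept_value, coef[0], coef[1]
        ab_se = coeff_se
    else:
        ref_value, a, b = coef
        ab_se = coeff_se[1:]

    model = QuadraticTempModel(
        quantity=quantity,
        reference_temperature=float(reference_temperature),
        reference_value=float(ref_value),
        linear_coeff=float(a),
        quad_coeff=float(b),
        delta_convention=convention,
        rse=rse,
        coeff_se=(ab_se[0], ab_se[1]),
    )
    diagnostics = FitDiagnostics(rss=rss, rse=rse, degrees_of_freedom=df, coeff_se=coeff_se)
    return model, diagnostics


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise InputError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComputationError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Packaged registry I/O
# ---------------------------------------------------------------------------

def _record_from_json(obj: dict, convention: Convention) -> PerfusateRecord:
    def model(quantity, ref_temp, ref_key, a_key, b_key, rse_key):
        if obj.get(ref_key) is None:
            return None
        return QuadraticTempModel(
            quantity=quantity,
            reference_temperature=ref_temp,
            reference_value=obj[ref_key],
            linear_coeff=obj[a_key],
            quad_coeff=obj[b_key],
            delta_convention=convention,
            rse=obj.get(rse_key),
        )

    return PerfusateRecord(
        name=obj["name"],
        nature=obj["nature"],
        viscosity_model=model("viscosity_mPa_s", 20.0, "mu20", "A_visc", "B_visc", "rse_visc"),
        t1_model=model("T1_ms", 23.0, "T1_23", "A_T1", "B_T1", "rse_T1"),
        t2_model=model("T2_ms", 23.0, "T2_23", "A_T2", "B_T2", "rse_T2"),
    )


def load_registry(path: str | Path | None = None, convention: Convention = "as_printed") -> Registry:
    """Load a registry JSON file; ``None`` loads the packaged registry.

    The packaged registry holds the nine experimentally characterised
    liquids and the in-cadaver perfusate-temperature model.  ``convention``
    sets ``delta_convention`` on every returned model; the packaged
    coefficient tables are published in the ``as_printed`` convention.
    """
    if path is None:
        raw = resources.files("perfuscan").joinpath("data/registry.json").read_text()
    else:
        raw = Path(path).read_text()
    try:
        doc = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise InputError(f"malformed registry JSON: {exc}") from exc

    records = {}
    for obj in doc.get("perfusates", []):
        rec = _record_from_json(obj, convention)
        if rec.name in records:
            raise InputError(f"duplicate perfusate name {rec.name!r} in registry")
        records[rec.name] = rec

    cad = doc["cadaver_perfusate_temp"]
    cadaver_model = QuadraticTempModel(
        quantity="perfusate_temp_C",
        reference_temperature=cad["reference_temperature"],
        reference_value=cad["intercept"],
        linear_coeff=cad["A"],
        quad_coeff=cad["B"],
        delta_convention=convention,
        rse=cad.get("rse"),
        coeff_se=tuple(cad["coeff_se"]) if cad.get("coeff_se") else None,
    )
    return Registry(perfusates=records, cadaver_model=cadaver_model)


def save_registry(registry: Registry, path: str | Path) -> None:
    """Write a registry back to the JSON interchange format (lossless)."""
    perfusates = []
    for rec in registry:
        obj: dict = {"name": rec.name, "nature": rec.nature}
        if rec.viscosity_model is not None:
            m = rec.viscosity_model
            obj.update(mu20=m.reference_value, A_visc=m.linear_coeff,
                       B_visc=m.quad_coeff, rse_visc=m.rse)
        if rec.t1_model is not None:
            m = rec.t1_model
            obj.update(T1_23=m.reference_value, A_T1=m.linear_coeff,
                       B_T1=m.quad_coeff, rse_T1=m.rse)
        if rec.t2_model is not None:
            m = rec.t2_model
            obj.update(T2_23=m.reference_value, A_T2=m.linear_coeff,
                       B_T2=m.quad_coeff, rse_T2=m.rse)
        perfusates.append(obj)
    cad = registry.cadaver_model
    doc = {
        "perfusates": perfusates,
        "cadaver_perfusate_temp": {
            "reference_temperature": cad.reference_temperature,
            "intercept": cad.reference_value,
            "A": cad.linear_coeff,
            "B": cad.quad_coeff,
            "rse": cad.rse,
            "coeff_se": list(cad.coeff_se) if cad.coeff_se else None,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))
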