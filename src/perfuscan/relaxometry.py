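"""Mono-exponential relaxometry: inversion-recovery T1 and multi-echo T2.

Signal models
-------------
Inversion recovery (three parameters)::

    S(TI) = S0 * (1 - 2 * A * exp(-TI / T1))

``S0`` is the equilibrium signal, ``A`` (close to 1) absorbs incomplete
inversion, ``T1`` the longitudinal relaxation time.  Magnitude-reconstructed
data lose the sign of the early-TI points; ``restore_from_magnitude`` mode
recovers it by trying every candidate zero-crossing position and keeping the
polarity assignment with minimum residual sum of squares.

Multi-echo spin echo (two parameters)::

    S(TE) = S0 * exp(-TE / T2)

The first echo of a spin-echo train is systematically off (stimulated-echo
contamination), so it is discarded by default before fitting.

Both fitters use bounded nonlinear least squares (T1/T2 in (0, 20000] ms,
A in [0.5, 1.5]) with derivative-free initialisation and up to three
deterministically jittered restarts.  The ROI procedure averages the voxels
of each slice first and fits the averaged series per slice
("average-then-fit"); the summary over slices reports mean, sample SD and
relative standard deviation (RSD = 100 * SD / mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ComputationError, FitError, InputError
from .temp_models import FitDiagnostics

__all__ = [
    "InversionRecoverySeries",
    "EchoDecaySeries",
    "T1FitResult",
    "T2FitResult",
    "ROIStack",
    "SliceSummary",
    "fit_t1_ir",
    "fit_t2_mse",
    "average_then_fit",
    "PROTOCOL_TI_MS",
]

#: Inversion-time protocol (ms) of the quantitative scans the package models.
PROTOCOL_TI_MS = (50.0, 100.0, 200.0, 350.0, 600.0, 1000.0, 4000.0)

_TIME_BOUND_MS = 20_000.0  # upper bound for T1/T2 estimates
_MAX_RESTARTS = 3
_JITTER = (1.0, 0.5, 2.0, 1.3)  # initial + up to 3 jittered restarts


def _as_sorted(times, signals, min_points, what):
    t = np.asarray(times, dtype=float)
    s = np.asarray(signals, dtype=float)
    if t.ndim != 1 or t.shape != s.shape:
        raise InputError(f"{what}: times and signals must be equal-length vectors")
    if len(t) < min_points:
        raise InputError(f"{what}: need at least {min_points} points, got {len(t)}")
    if np.any(t <= 0):
        raise InputError(f"{what}: times must be positive")
    if len(np.unique(t)) != len(t):
        raise InputError(f"{what}: duplicate time points")
    order = np.argsort(t)
    return t[order], s[order]


@dataclass(frozen=True)
class InversionRecoverySeries:
    """TI-indexed signal vector; points are stored sorted by TI."""

    inversion_times: np.ndarray
    signals: np.ndarray
    magnitude_flag: bool = False

    def __post_init__(self):
        t, s = _as_sorted(self.inversion_times, self.signals, 4, "IR series")
        object.__setattr__(self, "inversion_times", t)
        object.__setattr__(self, "signals", s)

    def __len__(self):
        return len(self.inversion_times)


@dataclass(frozen=True)
class EchoDecaySeries:
    """TE-indexed echo train; echo times form an arithmetic progression."""

    echo_times: np.ndarray
    signals: np.ndarray

    def __post_init__(self):
        t, s = _as_sorted(self.echo_times, self.signals, 3, "echo train")
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise InputError("echo times must be an arithmetic progression")
        object.__setattr__(self, "echo_times", t)
        object.__setattr__(self, "signals", s)

    @classmethod
    def from_train(cls, echo_spacing: float, signals) -> "EchoDecaySeries":
        """Build a series at echo times spacing*(1..len(signals))."""
        n = len(signals)
        return cls(echo_spacing * np.arange(1, n + 1), np.asarray(signals, float))

    @property
    def echo_spacing(self) -> float:
        return float(self.echo_times[1] - self.echo_times[0])

    def __len__(self):
        return len(self.echo_times)


@dataclass(frozen=True)
class T1FitResult:
    s0: float
    inversion_factor: float  # A
    t1: float
    diagnostics: FitDiagnostics
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class T2FitResult:
    s0: float
    t2: float
    diagnostics: FitDiagnostics
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Nonlinear fitting machinery
# ---------------------------------------------------------------------------

def _bounded_lsq(residual, x0, bounds):
    """least_squares with deterministic jittered restarts; returns first
    converged fit, else raises FitError carrying the best candidate."""
    best = None
    lo, hi = bounds
    for factor in _JITTER[: _MAX_RESTARTS + 1]:
        start = np.clip(np.asarray(x0, float) * factor, np.asarray(lo) + 1e-12, hi)
        try:
            res = least_squares(residual, start, bounds=bounds, method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success and np.all(np.isfinite(res.x)):
            return res
    raise FitError("nonlinear least squares failed to converge", best=best)


def _diagnostics_from_lsq(res, n, p) -> FitDiagnostics:
    rss = float(2.0 * res.cost)
    df = n - p
    if df < 1:
        raise ComputationError("not enough points for diagnostics")
    rse = math.sqrt(rss / df)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * rse**2
        se = tuple(float(x) for x in np.sqrt(np.clip(np.diag(cov), 0, None)))
    except np.linalg.LinAlgError:
        se = tuple(float("nan") for _ in range(p))
    return FitDiagnostics(rss=rss, rse=rse, degrees_of_freedom=df, coeff_se=se)


def _ir_model(params, ti):
    s0, a, t1 = params
    return s0 * (1.0 - 2.0 * a * np.exp(-ti / t1))


def _fit_ir_signed(ti, sig):
    """Fit the signed IR model to one polarity assignment."""
    s0_init = float(np.max(np.abs(sig))) or 1.0
    # T1 init: interpolated zero crossing (null at TI = T1 ln 2), else
    # minimum-|signal| TI.
    crossing = np.nonzero((sig[:-1] < 0) & (sig[1:] >= 0))[0]
    if len(crossing):
        i = crossing[0]
        frac = -sig[i] / (sig[i + 1] - sig[i])
        tzc = ti[i] + frac * (ti[i + 1] - ti[i])
    else:
        tzc = ti[int(np.argmin(np.abs(sig)))]
    t1_init = min(max(tzc / math.log(2.0), 1.0), _TIME_BOUND_MS)
    bounds = ([1e-9, 0.5, 1e-6], [np.inf, 1.5, _TIME_BOUND_MS])
    res = _bounded_lsq(lambda p: _ir_model(p, ti) - sig, [s0_init, 1.0, t1_init], bounds)
    return res


def fit_t1_ir(
    series: InversionRecoverySeries,
    polarity_mode: Literal["signed", "restore_from_magnitude"] = "restore_from_magnitude",
) -> T1FitResult:
    """Fit the three-parameter inversion-recovery model.

    ``signed`` trusts the sign of the input signals; ``restore_from_magnitude``
    treats them as magnitudes, negates the first *c* points for every
    candidate crossing position c = 0..n, and keeps the fit with minimum RSS.
    """
    ti, sig = series.inversion_times, series.signals
    n = len(ti)
    flags: list[str] = []

    if polarity_mode == "signed":
        if np.all(sig >= 0) or np.all(sig <= 0):
            flags.append("no_sign_change")
        best = _fit_ir_signed(ti, sig)
        best_c = None
    elif polarity_mode == "restore_from_magnitude":
        mag = np.abs(sig)
        best, best_c = None, 0
        for c in range(n + 1):
            signed = mag.copy()
            signed[:c] *= -1.0
            try:
                res = _fit_ir_signed(ti, signed)
            except FitError:
                continue
            if best is None or res.cost < best.cost:
                best, best_c = res, c
        if best is None:
            raise FitError("no polarity assignment converged")
        if best_c in (0, n):
            flags.append("no_sign_change")
    else:
        raise InputError(f"unknown polarity_mode {polarity_mode!r}")

    s0, a, t1 = (float(v) for v in best.x)
    if t1 >= 0.999 * _TIME_BOUND_MS:
        flags.append("t1_at_bound")
    if not (0.5 < a <= 1.5):
        flags.append("inversion_factor_at_bound")
    return T1FitResult(
        s0=s0, inversion_factor=a, t1=t1,
        diagnostics=_diagnostics_from_lsq(best, n, 3),
        flags=tuple(flags),
    )


def fit_t2_mse(series: EchoDecaySeries, discard_first_echo: bool = True) -> T2FitResult:
    """Fit the mono-exponential echo decay, optionally dropping echo 1.

    Initialisation is a log-linear regression on the retained echoes; when
    any retained signal is non-positive the fit falls back to a direct
    nonlinear start.
    """
    te, sig = series.echo_times, series.signals
    flags: list[str] = []
    if discard_first_echo:
        te, sig = te[1:], sig[1:]
        flags.append("first_echo_discarded")
    n = len(te)
    if n < 3:
        raise InputError(f"need >= 3 echoes after discard, got {n}")

    if np.all(sig > 0):
        slope, logb = np.polyfit(te, np.log(sig), 1)
        if slope < 0:
            t2_init = min(-1.0 / slope, _TIME_BOUND_MS)
        else:
            t2_init = float(te[-1])
        s0_init = float(np.exp(logb))
    else:
        flags.append("log_init_unavailable")
        s0_init = float(np.max(np.abs(sig))) or 1.0
        t2_init = float((te[-1] - te[0]) / 3.0) or 1.0

    bounds = ([1e-9, 1e-6], [np.inf, _TIME_BOUND_MS])
    best = _bounded_lsq(
        lambda p: p[0] * np.exp(-te / p[1]) - sig, [s0_init, t2_init], bounds
    )
    s0, t2 = (float(v) for v in best.x)
    if t2 >= 0.999 * _TIME_BOUND_MS:
        flags.append("t2_at_bound")
    return T2FitResult(
        s0=s0, t2=t2, diagnostics=_diagnostics_from_lsq(best, n, 2),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Slice-wise average-then-fit ROI procedure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROIStack:
    """One averaged series per slice of an ROI, plus voxel provenance."""

    series: tuple
    voxel_counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.series) != len(self.voxel_counts):
            raise InputError("one voxel count per slice required")
        if len(self.series) == 0:
            raise InputError("empty ROI stack")
        if any(v <= 0 for v in self.voxel_counts):
            raise InputError("voxel counts must be positive")

    @property
    def n_slices(self) -> int:
        return len(self.series)


@dataclass(frozen=True)
class SliceSummary:
    """Per-slice fits with mean / sample SD / RSD over the slice estimates."""

    per_slice: tuple
    estimates: np.ndarray
    mean: float
    sd: float
    rsd_percent: float
    failures: tuple[int, ...] = ()


def average_then_fit(
    stack: ROIStack,
    fit_kind: Literal["t1", "t2"],
    **options,
) -> SliceSummary:
    """Fit each slice's averaged series independently and summarise.

    ``options`` are forwarded to the underlying fitter (``polarity_mode``
    for T1, ``discard_first_echo`` for T2).  Slices whose fit fails are
    excluded from the summary and listed in ``failures``.
    """
    if fit_kind not in ("t1", "t2"):
        raise InputError(f"fit_kind must be 't1' or 't2', got {fit_kind!r}")
    per_slice: list = []
    estimates: list[float] = []
    failures: list[int] = []
    for i, series in enumerate(stack.series):
        try:
            if fit_kind == "t1":
                result = fit_t1_ir(series, **options)
                estimates.append(result.t1)
            else:
                result = fit_t2_mse(series, **options)
                estimates.append(result.t2)
            per_slice.append(result)
        except (FitError, InputError) as exc:
            per_slice.append(exc)
            failures.append(i)
    if not estimates:
        raise FitError("every slice failed to fit")
    est = np.asarray(estimates)
    mean = float(np.mean(est))
    sd = float(np.std(est, ddof=1)) if len(est) > 1 else 0.0
    rsd = 100.0 * sd / mean if mean != 0 else float("nan")
    return SliceSummary(
        per_slice=tuple(per_slice), estimates=est, mean=mean, sd=sd,
        rsd_percent=rsd, failures=tuple(failures),
    )
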