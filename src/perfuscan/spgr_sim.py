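"""Isochromat Bloch simulation of an RF-spoiled gradient-echo sequence.

The sequence excites every TR with flip angle alpha, reads out at TE, and
destroys residual transverse coherence with a spoiler gradient plus a
quadratically incremented RF phase (phi_k = dphi * k(k+1)/2, dphi = 117 deg
by default — the standard choice that approximates ideal spoiling).  The
voxel is modelled as ``n_spins`` isochromats that each accumulate a fixed
spoiler phase 2*pi*j/n_spins per TR; the reported signal is the magnitude of
the isochromat-mean complex transverse magnetisation at the TE of the final
excitation.  The simulation is fully deterministic: no random phases.

Under ideal spoiling the steady-state signal is the closed-form Ernst
expression

    S = M0 * sin(a) * (1 - E1) / (1 - E1 cos(a)) * exp(-TE/T2),
    E1 = exp(-TR/T1),

maximised at the Ernst angle arccos(E1); it serves as an independent oracle
for the simulator (agreement within a few percent is the known quality of
117-degree quadratic spoiling).

Contrast between a perfusate and a tissue at one temperature is the signed
signal difference per flip angle.  The optimal flip angle(s) maximise that
contrast (maximum reported to four significant figures; ties at the rounded
maximum give up to two optimal angles).  Across temperatures the union of
optimal angles defines a flip range, and the relative contrast difference

    d_r = |C_opt - C_min| / |mean(C_opt, C_min)| * 100

quantifies the penalty of using any angle in that range at a given
temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .exceptions import ComputationError, DomainError, InputError

__all__ = [
    "TissueProperties",
    "SpoiledGRESequence",
    "SignalCurve",
    "ContrastResult",
    "OptimalFlip",
    "simulate_spgr",
    "ernst_signal",
    "ernst_angle",
    "sweep_flip",
    "contrast_curve",
    "optimal_flip",
    "flip_range_over_temperatures",
    "relative_difference",
    "analyse_contrast_over_temperatures",
    "round_to_sig_figs",
]


@dataclass(frozen=True)
class TissueProperties:
    """Relaxation properties of one substance at one temperature.

    ``t2 <= t1`` is deliberately not enforced: for oils T2 approaches T1.
    """

    label: str
    t1: float  # ms
    t2: float  # ms
    m0: float = 1.0  # relative proton density

    def __post_init__(self):
        if self.t1 <= 0 or self.t2 <= 0:
            raise DomainError("t1 and t2 must be positive")
        if self.m0 <= 0:
            raise DomainError("m0 must be positive")


@dataclass(frozen=True)
class SpoiledGRESequence:
    """Spoiled gradient-echo protocol parameters."""

    te: float = 5.0    # ms
    tr: float = 20.0   # ms
    flip_angles: tuple[int, ...] = tuple(range(0, 91))  # degrees
    n_spins: int = 100
    n_excitations: int = 100
    rf_phase_increment: float = 117.0  # degrees
    phase_schedule: Literal["quadratic", "linear"] = "quadratic"

    def __post_init__(self):
        if not (0 < self.te < self.tr):
            raise DomainError("need 0 < TE < TR")
        if self.n_spins < 1 or self.n_excitations < 1:
            raise DomainError("n_spins and n_excitations must be >= 1")
        if any(not (0 <= f < 180) for f in self.flip_angles):
            raise DomainError("flip angles must lie in [0, 180) degrees")
        if self.phase_schedule not in ("quadratic", "linear"):
            raise InputError(f"unknown phase_schedule {self.phase_schedule!r}")


@dataclass(frozen=True)
class SignalCurve:
    """Signal magnitude per flip angle, in units of m0."""

    flip_angles: np.ndarray
    signals: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.flip_angles, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if f.shape != s.shape or f.ndim != 1:
            raise InputError("flip_angles and signals must be equal-length vectors")
        object.__setattr__(self, "flip_angles", f)
        object.__setattr__(self, "signals", s)


@dataclass(frozen=True)
class OptimalFlip:
    flips: tuple[float, ...]
    c_opt: float
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class ContrastResult:
    """Contrast-vs-flip curve with its optimum and range statistics."""

    flip_angles: np.ndarray
    contrast: np.ndarray
    optimal_flips: tuple[float, ...]
    c_opt: float
    c_min_over_range: float
    d_r_percent: float
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Bloch simulation
# ---------------------------------------------------------------------------

def _rf_phases_deg(increment: float, n: int, schedule: str) -> np.ndarray:
    k = np.arange(n, dtype=float)
    if schedule == "quadratic":
        return increment * k * (k + 1) / 2.0
    return increment * k


def simulate_spgr(
    tissue: TissueProperties,
    seq: SpoiledGRESequence,
    flip: float,
    return_trace: bool = False,
):
    """Simulate one flip angle; deterministic.

    Each TR: instantaneous rotation by ``flip`` about a transverse axis at
    the RF phase phi_k; relaxation to TE; sample the isochromat-mean complex
    transverse magnetisation demodulated by phi_k; relaxation to TR; apply
    the per-isochromat spoiler phase 2*pi*j/n_spins.  Returns the signal
    magnitude at the final excitation, or the full per-excitation trace when
    ``return_trace`` is set.
    """
    n = seq.n_spins
    m0 = tissue.m0
    alpha = math.radians(flip)
    cos_a, sin_a = math.cos(alpha), math.sin(alpha)
    e1_te = math.exp(-seq.te / tissue.t1)
    e2_te = math.exp(-seq.te / tissue.t2)
    rest = seq.tr - seq.te
    e1_rest = math.exp(-rest / tissue.t1)
    e2_rest = math.exp(-rest / tissue.t2)

    spoiler = np.exp(2j * math.pi * np.arange(n) / n)
    phases = np.radians(_rf_phases_deg(seq.rf_phase_increment, seq.n_excitations,
                                       seq.phase_schedule))

    mxy = np.zeros(n, dtype=complex)
    mz = np.full(n, m0, dtype=float)
    trace = np.empty(seq.n_excitations, dtype=float)
    for k in range(seq.n_excitations):
        phi = phases[k]
        rot = np.exp(-1j * phi)
        # rotate by alpha about the transverse axis at phase phi
        mp = mxy * rot
        my_new = mp.imag * cos_a + mz * sin_a
        mz = -mp.imag * sin_a + mz * cos_a
        mxy = (mp.real + 1j * my_new) / rot
        # relax to the echo time and sample (receiver demodulated at phi)
        mxy *= e2_te
        mz = m0 + (mz - m0) * e1_te
        trace[k] = abs(np.mean(mxy * rot))
        # relax to TR, then gradient spoiler dephasing
        mxy *= e2_rest
        mz = m0 + (mz - m0) * e1_rest
        mxy *= spoiler
    return trace if return_trace else float(trace[-1])


def ernst_signal(t1: float, t2: float, tr: float, te: float, flip: float,
                 m0: float = 1.0) -> float:
    """Closed-form ideally spoiled steady-state signal (validation oracle)."""
    if min(t1, t2, tr, te) <= 0 or te >= tr:
        raise DomainError("need positive t1, t2 and 0 < te < tr")
    a = math.radians(flip)
    e1 = math.exp(-tr / t1)
    return m0 * math.sin(a) * (1.0 - e1) / (1.0 - e1 * math.cos(a)) * math.exp(-te / t2)


def ernst_angle(t1: float, tr: float) -> float:
    """Flip angle (degrees) maximising the ideally spoiled signal."""
    return math.degrees(math.acos(math.exp(-tr / t1)))


def sweep_flip(tissue: TissueProperties, seq: SpoiledGRESequence) -> SignalCurve:
    """Simulate every configured flip angle (deterministic)."""
    flips = np.asarray(seq.flip_angles, dtype=float)
    signals = np.array([simulate_spgr(tissue, seq, f) for f in flips])
    return SignalCurve(flip_angles=flips, signals=signals)


# ---------------------------------------------------------------------------
# Contrast analysis
# ---------------------------------------------------------------------------

def contrast_curve(perfusate: SignalCurve, tissue: SignalCurve) -> np.ndarray:
    """Signed per-flip contrast S_perfusate - S_tissue."""
    if not np.array_equal(perfusate.flip_angles, tissue.flip_angles):
        raise InputError("flip-angle grids do not match")
    return perfusate.signals - tissue.signals


def round_to_sig_figs(x: float, sig_figs: int) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig_figs - 1 - int(math.floor(math.log10(abs(x)))))


def optimal_flip(flip_angles, contrast, sig_figs: int = 4) -> OptimalFlip:
    """Flip angle(s) maximising contrast, with the maximum rounded to
    ``sig_figs`` significant figures.

    All grid angles whose rounded contrast equals the rounded maximum are
    optimal; if more than two tie, the two smallest are reported with a
    multiplicity warning.  An all-zero curve returns flip 0 with a warning.
    """
    flips = np.asarray(flip_angles, dtype=float)
    c = np.asarray(contrast, dtype=float)
    if len(flips) == 0 or flips.shape != c.shape:
        raise InputError("non-empty matching flip/contrast vectors required")
    if np.all(c == 0):
        return OptimalFlip(flips=(0.0,), c_opt=0.0, warnings=("all_zero_contrast",))
    rounded = np.array([round_to_sig_figs(v, sig_figs) for v in c])
    c_opt = float(np.max(rounded))
    ties = flips[rounded == c_opt]
    warnings_: tuple[str, ...] = ()
    if len(ties) > 2:
        warnings_ = (f"{len(ties)} flip angles tie at the rounded maximum",)
        ties = ties[:2]
    return OptimalFlip(flips=tuple(float(f) for f in ties), c_opt=c_opt,
                       warnings=warnings_)


def flip_range_over_temperatures(optimal_sets: Sequence[Sequence[float]]):
    """(min, max) over the union of per-temperature optimal flip sets.

    Returns ``(fmin, fmax, warnings)``; a gap warning is attached when the
    union does not cover every integer grid angle between the extremes.
    """
    sets = [set(s) for s in optimal_sets if len(s)]
    if not sets:
        raise InputError("need at least one non-empty optimal set")
    union = set().union(*sets)
    fmin, fmax = min(union), max(union)
    warnings_: tuple[str, ...] = ()
    expected = set(np.arange(fmin, fmax + 0.5, 1.0))
    if not expected <= union and fmax - fmin > 1:
        warnings_ = ("optimal flip sets leave a gap inside the reported range",)
    return float(fmin), float(fmax), warnings_


def relative_difference(c_opt: float, c_min: float) -> float:
    """d_r (%) = |C_opt - C_min| / |mean(C_opt, C_min)| * 100."""
    mean = (c_opt + c_min) / 2.0
    if mean == 0:
        raise ComputationError("relative difference undefined: zero mean contrast")
    return abs(c_opt - c_min) / abs(mean) * 100.0


def analyse_contrast_over_temperatures(
    contrast_by_temp: Mapping[float, np.ndarray],
    flip_angles,
    sig_figs: int = 4,
) -> tuple[dict[float, ContrastResult], tuple[float, float]]:
    """Full per-temperature contrast analysis for one perfusate/tissue pair.

    For each temperature the optimal flip set and C_opt are found; the union
    of optimal sets over all temperatures defines the flip range; within
    that range each temperature's minimum contrast C_min and d_r are
    computed.  Returns the per-temperature results and the flip range.
    """
    flips = np.asarray(flip_angles, dtype=float)
    optima = {t: optimal_flip(flips, c, sig_figs) for t, c in contrast_by_temp.items()}
    fmin, fmax, range_warnings = flip_range_over_temperatures(
        [o.flips for o in optima.values()]
    )
    in_range = (flips >= fmin) & (flips <= fmax)
    results: dict[float, ContrastResult] = {}
    for t, c in contrast_by_temp.items():
        c = np.asarray(c, dtype=float)
        opt = optima[t]
        c_min = float(np.min(c[in_range]))
        try:
            d_r = relative_difference(opt.c_opt, c_min)
        except ComputationError:
            d_r = float("nan")
        results[t] = ContrastResult(
            flip_angles=flips, contrast=c, optimal_flips=opt.flips,
            c_opt=opt.c_opt, c_min_over_range=c_min, d_r_percent=d_r,
            warnings=opt.warnings + range_warnings,
        )
    return results, (fmin, fmax)
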