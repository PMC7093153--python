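"""Filament-dissociation and ATP-turnover kinetics.

Dissociation of a recombinase from fluorescently labeled ssDNA is followed
by fluorescence anisotropy sampled once per second; the decay obeys

    anisotropy(t) = amplitude * exp(-k_off * (t - t0)) + floor

where ``floor`` is the free-DNA anisotropy (~0.1).  Traces are first
truncated where a trailing 20-point moving average reaches the free-DNA
level (0.106), then fitted by bounded nonlinear least squares.

ATP turnover is quantified from a malachite-green assay: A620 readings are
baselined to the time-zero value, converted to phosphate concentrations
through a linear standard curve, and the slope of Pi(t) divided by the
recombinase concentration gives k_cat (per minute).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AnisotropyTrace",
    "KoffFitResult",
    "AtpaseTimeCourse",
    "KcatResult",
    "truncate_trace",
    "fit_koff",
    "pi_from_absorbance",
    "fit_kcat",
]


@dataclass
class AnisotropyTrace:
    time: np.ndarray  # seconds, strictly increasing
    anisotropy: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.time.shape != self.anisotropy.shape or self.time.ndim != 1:
            raise ValueError("time and anisotropy must be matching 1-D arrays")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.anisotropy)):
            raise ValueError("anisotropy values must be finite")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class KoffFitResult:
    k_off: float  # 1/s
    amplitude: float
    floor: float
    rss: float
    n_points_used: int
    converged: bool
    degenerate: bool = False

    def predict(self, t: np.ndarray, t0: float = 0.0) -> np.ndarray:
        return self.amplitude * np.exp(-self.k_off * (np.asarray(t) - t0)) + self.floor


@dataclass
class AtpaseTimeCourse:
    time_min: np.ndarray
    a620: np.ndarray
    standard_curve: Sequence[tuple[float, float]]  # (pi_um, a620)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.a620 = np.asarray(self.a620, dtype=float)
        if self.time_min.shape != self.a620.shape:
            raise ValueError("time and absorbance must have matching shapes")
        if not np.any(self.time_min == 0):
            raise ValueError("time course must include a t=0 point")
        if len(self.standard_curve) < 3:
            raise ValueError("standard curve needs at least 3 points")


@dataclass
class KcatResult:
    slope: float  # µM/min
    rad51_conc: float  # µM
    k_cat: float  # 1/min
    fold_vs_reference: float | None = None


def truncate_trace(
    trace: AnisotropyTrace, window: int = 20, stop_level: float = 0.106
) -> AnisotropyTrace:
    """Cut a trace where its trailing moving average first reaches baseline.

    The moving average is trailing (current point plus the ``window - 1``
    preceding points, so the rule is causal); the returned trace is the
    prefix ending at the first index where that average is <= ``stop_level``,
    or the full trace if the level is never reached.
    """
    if len(trace) < window:
        raise ValueError(f"trace has {len(trace)} points, fewer than window={window}")
    csum = np.concatenate([[0.0], np.cumsum(trace.anisotropy)])
    trailing = (csum[window:] - csum[:-window]) / window  # index window-1 onward
    hits = np.nonzero(trailing <= stop_level)[0]
    if hits.size == 0:
        return trace
    cut = hits[0] + window - 1
    return AnisotropyTrace(trace.time[: cut + 1], trace.anisotropy[: cut + 1])


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    floor0 = float(y[-1])
    amp0 = float(y[0] - y[-1])
    half = y[-1] + 0.5 * (y[0] - y[-1])
    if amp0 > 0:
        below = np.nonzero(y <= half)[0]
    else:
        below = np.nonzero(y >= half)[0]
    t_half = float(t[below[0]] - t[0]) if below.size else float(t[-1] - t[0])
    k0 = np.log(2) / t_half if t_half > 0 else 0.1
    return amp0, float(np.clip(k0, 1e-6, 10.0)), float(np.clip(floor0, 0.0, 0.5))


def fit_koff(
    trace: AnisotropyTrace,
    t0: float = 0.0,
    max_restarts: int = 5,
    seed: int = 0,
) -> KoffFitResult:
    """Fit the 3-parameter exponential dissociation model to a trace.

    Bounds: k_off in (0, 10] 1/s, floor in [0, 0.5]. On non-convergence the
    fit is restarted up to ``max_restarts`` times from jittered initial
    guesses; a non-positive fitted amplitude triggers a degenerate-fit
    warning (the trace carries no decay information).
    """
    if len(trace) < 10:
        raise ValueError("need at least 10 points to fit k_off")
    t = trace.time - t0
    y = trace.anisotropy

    def residuals(p: np.ndarray) -> np.ndarray:
        amp, k, floor = p
        return amp * np.exp(-k * t) + floor - y

    amp0, k0, floor0 = _initial_guess(t, y)
    lb = np.array([-1.0, 1e-9, 0.0])
    ub = np.array([1.0, 10.0, 0.5])
    rng = np.random.default_rng(seed)
    best = None
    x0 = np.clip([amp0, k0, floor0], lb, ub)
    for attempt in range(max_restarts + 1):
        try:
            sol = least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
        except Exception:
            sol = None
        if sol is not None and (best is None or sol.cost < best.cost):
            best = sol
        if sol is not None and sol.success:
            break
        jitter = rng.normal(scale=[abs(amp0) * 0.3 + 1e-3, k0 * 0.5 + 1e-3, 0.01])
        x0 = np.clip([amp0, k0, floor0] + jitter, lb, ub)
    if best is None:
        raise RuntimeError("k_off fit failed to converge after bounded restarts")
    amp, k, floor = best.x
    rss = float(2 * best.cost)
    degenerate = amp <= 0 or abs(amp) < 1e-6
    if degenerate:
        warnings.warn("degenerate k_off fit: non-positive or vanishing amplitude")
    return KoffFitResult(
        k_off=float(k),
        amplitude=float(amp),
        floor=float(floor),
        rss=rss,
        n_points_used=len(trace),
        converged=bool(best.success),
        degenerate=degenerate,
    )


def pi_from_absorbance(course: AtpaseTimeCourse) -> np.ndarray:
    """Convert baselined A620 readings to phosphate concentrations (µM).

    The time-zero absorbance is subtracted from every reading, a straight
    line (intercept fitted) is least-squares fitted to the standard curve,
    and each baselined value is inverted through that line.
    """
    pi_std = np.array([p for p, _ in course.standard_curve], dtype=float)
    a_std = np.array([a for _, a in course.standard_curve], dtype=float)
    order = np.argsort(pi_std)
    if not np.all(np.diff(a_std[order]) > 0):
        warnings.warn("standard curve absorbances are not monotonic in Pi")
    slope, intercept = np.polyfit(pi_std, a_std, 1)
    if slope <= 0:
        raise ValueError("standard curve slope must be positive")
    i0 = int(np.nonzero(course.time_min == 0)[0][0])
    baselined = course.a620 - course.a620[i0]
    # The intercept is fitted so it can absorb bias in the standard-curve
    # points without tilting the slope, but baselining already anchors the
    # sample at Pi(t=0) = 0, so only the slope enters the conversion.
    return baselined / slope


def fit_kcat(
    time_min: np.ndarray,
    pi_um: np.ndarray,
    rad51_conc: float,
    reference: KcatResult | None = None,
) -> KcatResult:
    """k_cat from the slope of Pi(t) divided by the recombinase concentration."""
    time_min = np.asarray(time_min, dtype=float)
    pi_um = np.asarray(pi_um, dtype=float)
    if len(time_min) < 3:
        raise ValueError("need at least 3 time points")
    if rad51_conc <= 0:
        raise ValueError("Rad51 concentration must be positive")
    slope, _ = np.polyfit(time_min, pi_um, 1)
    k_cat = float(slope) / rad51_conc
    fold = k_cat / reference.k_cat if reference is not None else None
    return KcatResult(
        slope=float(slope), rad51_conc=rad51_conc, k_cat=k_cat, fold_vs_reference=fold
    )
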