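"""Damping and frequency identification from free-vibration records.

A loaded pole released from its neutral position rings down as an
underdamped single-degree-of-freedom oscillator.  The accelerometer at the
load attachment measures vertical acceleration; displacement follows by
double integration (with drift control), the ring-down peaks give the damped
frequency from inter-peak intervals, and the logarithmic decrement

    phi = ln(y_i / y_{i+1}),   y_i > y_{i+1}

of consecutive peak magnitudes yields the damping ratio

    zeta = phi / sqrt((2*pi)**2 + phi**2),

the decay rate relative to a critically damped system.  The median decrement
over all valid cycles characterises the trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt
from scipy.signal import detrend as _sp_detrend
from scipy.signal import find_peaks

__all__ = [
    "VibrationTrial",
    "VibrationResult",
    "InsufficientCyclesError",
    "DriftWarning",
    "integrate_to_displacement",
    "dominant_frequency",
    "find_decay_peaks",
    "damped_frequency",
    "log_decrement",
    "damping_ratio",
    "analyze_trial",
]

#: Maximum allowed sampling jitter, as a fraction of the mean time step.
_MAX_JITTER = 0.01


class InsufficientCyclesError(ValueError):
    """Fewer oscillation cycles than the estimator needs."""


class DriftWarning(UserWarning):
    """Residual low-frequency drift survived detrending."""


@dataclass(frozen=True)
class VibrationTrial:
    """One free-vibration record at a single load level.

    ``time`` must be a uniform grid (jitter below 1% of the step);
    ``acceleration`` is the vertical acceleration at the load attachment in
    m s^-2, ``load_mass`` the per-end applied mass (basket included) in kg.
    """

    time: np.ndarray
    acceleration: np.ndarray
    load_mass: float
    pole_id: str = ""
    end_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.acceleration, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("time and acceleration must be 1-D arrays of equal length")
        if t.size < 4:
            raise ValueError("record too short")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(dt - dt.mean())) > _MAX_JITTER * dt.mean():
            raise ValueError("non-uniform sampling grid (jitter above 1% of dt)")
        if self.load_mass <= 0:
            raise ValueError("load_mass must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "acceleration", a)

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.time)))


@dataclass(frozen=True)
class VibrationResult:
    """Identified ring-down parameters for one trial."""

    damped_frequency: float  # Hz
    peak_magnitudes: np.ndarray
    peak_times: np.ndarray
    log_decrement_median: float
    damping_ratio: float
    n_cycles: int


def integrate_to_displacement(trial: VibrationTrial, detrend: str = "linear") -> np.ndarray:
    """Displacement by cumulative-trapezoid double integration of acceleration.

    The pole is released from rest at its neutral position, so both initial
    conditions are zero.  Sensor bias integrates to quadratic drift; a linear
    detrend of the displacement removes the bulk of it (``detrend="none"``
    disables this).  A :class:`DriftWarning` is raised when a quadratic
    component comparable to the oscillation survives.
    """
    if detrend not in ("linear", "none"):
        raise ValueError(f"unknown detrend mode {detrend!r}")
    v = cumulative_trapezoid(trial.acceleration, trial.time, initial=0.0)
    y = cumulative_trapezoid(v, trial.time, initial=0.0)
    if detrend == "linear":
        y = _sp_detrend(y, type="linear")
    # quadratic residual dominating the oscillation => unremoved drift
    coefs = np.polynomial.polynomial.polyfit(trial.time, y, 2)
    quad_part = coefs[2] * trial.time**2
    osc_scale = np.std(y - np.polynomial.polynomial.polyval(trial.time, coefs))
    if np.std(quad_part) > 5.0 * max(osc_scale, 1e-30):
        warnings.warn(
            "quadratic drift dominates the integrated displacement; "
            "check sensor bias or detrend mode",
            DriftWarning,
            stacklevel=2,
        )
    return y


def dominant_frequency(signal: np.ndarray, dt: float) -> float:
    """Frequency (Hz) of the largest non-DC periodogram peak of a signal."""
    x = np.asarray(signal, dtype=float)
    amp = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(x.size, dt)
    if amp.size < 3:
        raise InsufficientCyclesError("record too short for a spectral estimate")
    return float(freqs[1:][np.argmax(amp[1:])])


def find_decay_peaks(
    displacement: np.ndarray,
    time: np.ndarray,
    prominence_fraction: float = 0.05,
    skip_first_half_cycle: bool = True,
    center_frequency: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ring-down peak magnitudes and times, one per oscillation cycle.

    The oscillation about its mean is sign-normalised (flipped when the
    release direction makes the excursions negative-going) and local maxima
    with prominence at least ``prominence_fraction`` of the first peak are
    kept, ordered in time.  The first half-cycle holds the release transient
    and is discarded by default.

    When ``center_frequency`` (Hz) is given, the series is first band-passed
    around it (zero-phase, 2nd-order Butterworth, band 0.7-1.4x the
    carrier).  Integrated sensor noise random-walks the displacement
    baseline far below the oscillation frequency, so confining the analysis
    band around the carrier leaves the decay envelope intact (the decay
    bandwidth ``zeta * omega_n`` is far narrower than the band) while
    removing the wander.
    """
    y = np.asarray(displacement, dtype=float)
    t = np.asarray(time, dtype=float)
    if center_frequency is not None:
        dt = float(np.mean(np.diff(t)))
        nyq = 0.5 / dt
        lo = 0.7 * center_frequency
        hi = min(1.4 * center_frequency, 0.95 * nyq)
        if not (0 < lo < hi):
            raise ValueError("center_frequency incompatible with the sampling rate")
        b, a = butter(2, [lo / nyq, hi / nyq], btype="bandpass")
        y = filtfilt(b, a, y)
    x = y - y.mean()
    if np.abs(x.min()) > np.abs(x.max()):
        x = -x
    distance = None
    if center_frequency is not None:
        dt = float(np.mean(np.diff(t)))
        distance = max(int(0.7 / (center_frequency * dt)), 1)
    idx, _ = find_peaks(x)
    idx = idx[x[idx] > 0]
    if idx.size == 0:
        raise InsufficientCyclesError("no oscillation peaks found")
    # reference the largest ring-down peak: robust to filter edge transients
    reference = float(np.max(x[idx]))
    idx, _ = find_peaks(
        x, prominence=prominence_fraction * reference, distance=distance
    )
    idx = idx[x[idx] > 0]
    if skip_first_half_cycle and idx.size > 2:
        period = np.median(np.diff(t[idx]))
        idx = idx[t[idx] >= t[0] + 0.5 * period]
    if idx.size < 2:
        raise InsufficientCyclesError("fewer than 2 ring-down peaks")
    return x[idx], t[idx]


def damped_frequency(peak_times: np.ndarray) -> float:
    """Damped oscillation frequency (Hz) from the mean per-cycle interval.

    An interval spanning several cycles (interior peaks dropped by the
    prominence filter) is counted with its cycle multiplicity, estimated as
    the interval over the median interval, so a missed peak does not bias
    the mean.
    """
    t = np.asarray(peak_times, dtype=float)
    if t.size < 2:
        raise InsufficientCyclesError("need at least 2 peaks")
    iv = np.diff(t)
    cycles = np.maximum(np.round(iv / np.median(iv)), 1.0)
    return 1.0 / float(np.mean(iv / cycles))


def log_decrement(peak_magnitudes: np.ndarray) -> float:
    """Median per-cycle logarithmic decrement of the peak envelope.

    Only consecutive pairs with ``y_i > y_{i+1}`` contribute; pairs violating
    monotone decay (noise) are skipped rather than clipped.
    """
    y = np.asarray(peak_magnitudes, dtype=float)
    if y.size < 2:
        raise InsufficientCyclesError("need at least 2 peaks")
    pairs = [(a, b) for a, b in zip(y[:-1], y[1:]) if a > b > 0]
    if not pairs:
        raise InsufficientCyclesError("no strictly decreasing peak pair")
    decs = np.log([a / b for a, b in pairs])
    return float(np.median(decs))


def damping_ratio(phi: float) -> float:
    """Damping ratio from the logarithmic decrement.

    ``zeta = phi / sqrt((2*pi)**2 + phi**2)``; lies in [0, 1) for any
    ``phi >= 0``.
    """
    if phi < 0:
        raise ValueError("logarithmic decrement must be nonnegative")
    return phi / np.sqrt(4.0 * np.pi**2 + phi**2)


def analyze_trial(
    trial: VibrationTrial,
    detrend: str = "linear",
    prominence_fraction: float = 0.05,
) -> VibrationResult:
    """Full ring-down identification for one trial.

    Integrates acceleration to displacement, locates the decaying peaks, and
    returns the damped frequency, median logarithmic decrement and damping
    ratio.  The analysis band is centred on the dominant frequency of the
    *acceleration* spectrum (white sensor noise, no integration drift),
    which steers the displacement band-pass in :func:`find_decay_peaks`.
    """
    y = integrate_to_displacement(trial, detrend=detrend)
    f0 = dominant_frequency(trial.acceleration, trial.dt)
    mags, times = find_decay_peaks(
        y, trial.time, prominence_fraction=prominence_fraction, center_frequency=f0
    )
    phi = log_decrement(mags)
    return VibrationResult(
        damped_frequency=damped_frequency(times),
        peak_magnitudes=mags,
        peak_times=times,
        log_decrement_median=phi,
        damping_ratio=damping_ratio(phi),
        n_cycles=int(mags.size),
    )
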