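"""Sensor-current time-series and sniff-audio-envelope analysis.

A metal-oxide gas sensor sniffing an odor produces a current trace with a
baseline (~10 mA), a rise to a plateau while odor is present (~20 mA), and
per-cycle oscillations of amplitude A synchronized with the sniffing motion.
This module extracts those features, locates the odor-onset time, and
estimates sniffing frequency from an audio amplitude envelope by windowed
peak counting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import find_peaks

__all__ = [
    "SensorTrace",
    "TraceFeatures",
    "InsufficientDataError",
    "extract_features",
    "detect_onset",
    "sniff_frequency_from_envelope",
    "read_trace_csv",
    "write_trace_csv",
]


class InsufficientDataError(ValueError):
    """Raised when a trace does not cover enough of the sniff cycle."""


@dataclass(frozen=True)
class SensorTrace:
    """Uniformly sampled non-negative current trace with odor-window metadata."""

    times: np.ndarray       # s
    current: np.ndarray     # mA
    sample_rate: float      # Hz
    odor_windows: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "current", c)
        object.__setattr__(self, "odor_windows",
                           tuple((float(a), float(b))
                                 for a, b in self.odor_windows))
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and current must be 1-d and equal length")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not math.isclose(float(np.median(dt)), 1.0 / self.sample_rate,
                                rel_tol=1e-6):
                raise ValueError("sample_rate inconsistent with times")
        if np.any(c < 0):
            raise ValueError("current must be non-negative")
        for a, b in self.odor_windows:
            if not a < b:
                raise ValueError(f"bad odor window ({a}, {b})")


@dataclass(frozen=True)
class TraceFeatures:
    baseline: float                   # mA
    response_magnitude: float         # mA
    per_cycle_amplitudes: np.ndarray  # mA
    mean_amplitude: float             # mA (A)
    amplitude_sd: float               # mA
    onset_time: float | None          # s
    above_noise: bool


def _pre_odor_segment(trace: SensorTrace) -> np.ndarray:
    if not trace.odor_windows:
        raise ValueError("trace carries no odor windows")
    t_on = min(a for a, _ in trace.odor_windows)
    mask = trace.times < t_on
    if not np.any(mask):
        raise InsufficientDataError("no pre-odor segment to estimate baseline")
    return trace.current[mask]


def extract_features(trace: SensorTrace, frequency: float,
                     noise_floor: float = 0.03,
                     onset_threshold: float = 0.5) -> TraceFeatures:
    """Extract baseline, response magnitude and per-cycle amplitude.

    Baseline is the median of the pre-odor segment (robust to the device's
    non-negative noise).  Response magnitude is the median of the second
    half of the first odor window (past the sensor's rise) minus baseline.
    Per-cycle amplitude is the amplitude of the sniff-frequency oscillation
    within each complete 1/f cycle window after removing a moving-median
    trend of window 1/f, measured by quadrature projection onto the
    fundamental (for the sinusoidal ripple this equals half its
    peak-to-trough excursion, and unlike a raw peak-to-trough it is not
    biased upward by noise extremes); A is the mean over cycles.  Cycles
    where the trend itself moves more than half the cycle's residual
    excursion (the sensor's rise after odor onset, or its decay near window
    end; a running median tracks monotone segments exactly and suppresses
    the ripple there) are excluded unless fewer than 3 cycles would remain.
    """
    if trace.sample_rate < 20.0 * frequency:
        raise ValueError("sample_rate must be at least 20x the sniff frequency")
    baseline = float(np.median(_pre_odor_segment(trace)))
    t_on, t_off = trace.odor_windows[0]

    plateau_mask = (trace.times >= (t_on + t_off) / 2.0) & (trace.times < t_off)
    if not np.any(plateau_mask):
        raise InsufficientDataError("odor window not covered by the trace")
    response = max(0.0, float(np.median(trace.current[plateau_mask])) - baseline)

    period_samples = max(3, int(round(trace.sample_rate / frequency)))
    trend = median_filter(trace.current, size=period_samples, mode="nearest")
    residual = trace.current - trend

    all_amps, settled_amps = [], []
    for a, b in trace.odor_windows:
        n_cycles = int(math.floor((min(b, trace.times[-1]) - a) * frequency))
        for k in range(n_cycles):
            sel = (trace.times >= a + k / frequency) & \
                  (trace.times < a + (k + 1) / frequency)
            if np.count_nonzero(sel) >= 3:
                seg, t_seg = residual[sel], trace.times[sel]
                phasor = np.exp(-2j * math.pi * frequency * t_seg)
                amp = 2.0 * abs(np.mean(seg * phasor))
                all_amps.append(amp)
                if float(np.ptp(trend[sel])) <= amp:
                    settled_amps.append(amp)
    amplitudes = settled_amps if len(settled_amps) >= 3 else all_amps
    if len(amplitudes) < 3:
        raise InsufficientDataError(
            f"need >= 3 complete sniff cycles inside odor windows, "
            f"got {len(amplitudes)}")
    amplitudes = np.asarray(amplitudes)
    mean_a = float(np.mean(amplitudes))

    onset = detect_onset(trace, onset_threshold)
    return TraceFeatures(
        baseline=baseline,
        response_magnitude=response,
        per_cycle_amplitudes=amplitudes,
        mean_amplitude=mean_a,
        amplitude_sd=float(np.std(amplitudes, ddof=1)),
        onset_time=onset,
        above_noise=mean_a >= noise_floor,
    )


def detect_onset(trace: SensorTrace,
                 threshold_fraction: float = 0.5) -> float | None:
    """First time the current exceeds baseline + fraction * response.

    Linearly interpolates between samples; returns None when the trace
    never crosses the threshold (e.g. a flat trace).
    """
    baseline = float(np.median(_pre_odor_segment(trace)))
    t_on, t_off = trace.odor_windows[0]
    plateau_mask = (trace.times >= (t_on + t_off) / 2.0) & (trace.times < t_off)
    if not np.any(plateau_mask):
        return None
    response = float(np.median(trace.current[plateau_mask])) - baseline
    if response <= 0:
        return None
    threshold = baseline + threshold_fraction * response

    above = trace.current > threshold
    if not np.any(above):
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(trace.times[0])
    t0, t1 = trace.times[i - 1], trace.times[i]
    c0, c1 = trace.current[i - 1], trace.current[i]
    return float(t0 + (threshold - c0) / (c1 - c0) * (t1 - t0))


def sniff_frequency_from_envelope(signal, rate: float,
                                  prominence: float | None = None,
                                  window_s: float = 1.0,
                                  window_step_s: float = 0.1,
                                  smoothing_s: float = 0.025) -> float:
    """Sniff frequency from an audio amplitude envelope by peak counting.

    The envelope is lightly smoothed (moving average, default 25 ms, short
    enough to preserve sniff rates up to rate/10), then prominence-filtered
    local maxima are counted in sliding windows of ``window_s`` seconds; the
    maximum count per second is the estimate.  Default prominence is 5x the
    smoothed envelope's noise sd, estimated from the median absolute first
    difference of the raw signal (|diff| of Gaussian noise has median
    0.6745 * sigma * sqrt(2)) scaled by the smoothing gain.  A constant
    signal returns 0.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 2 * rate:
        raise ValueError("signal must cover at least 2 seconds")
    w = max(1, int(round(smoothing_s * rate)))
    noise_sd = float(np.median(np.abs(np.diff(x)))) / (0.6745 * math.sqrt(2.0))
    if w > 1:
        x = uniform_filter1d(x, w)
    if float(np.ptp(x)) == 0.0:
        return 0.0
    if prominence is None:
        prominence = max(5.0 * noise_sd / math.sqrt(w),
                         1e-3 * float(np.ptp(x)))
    peaks, _ = find_peaks(x, prominence=prominence)
    if peaks.size == 0:
        return 0.0
    peak_times = peaks / rate
    duration = len(x) / rate
    best = 0
    t = 0.0
    while t + window_s <= duration + 1e-9:
        best = max(best, int(np.count_nonzero(
            (peak_times >= t) & (peak_times < t + window_s))))
        t += window_step_s
    return best / window_s


def read_trace_csv(path, odor_windows=None) -> SensorTrace:
    """Read a trace CSV (time_s, current_mA); odor windows from a JSON
    sidecar ``<path>.json`` when not given explicitly."""
    df = pd.read_csv(path)
    for col in ("time_s", "current_mA"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
    if odor_windows is None:
        sidecar = str(path) + ".json"
        try:
            with open(sidecar) as fh:
                odor_windows = [tuple(w) for w in json.load(fh)["odor_windows"]]
        except FileNotFoundError:
            odor_windows = []
    t = df["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t)))
    return SensorTrace(t, df["current_mA"].to_numpy(), rate,
                       tuple(odor_windows))


def write_trace_csv(trace: SensorTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times,
                  "current_mA": trace.current}).to_csv(path, index=False)
    with open(str(path) + ".json", "w") as fh:
        json.dump({"odor_windows": [list(w) for w in trace.odor_windows],
                   "sample_rate_hz": trace.sample_rate}, fh, indent=2)
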