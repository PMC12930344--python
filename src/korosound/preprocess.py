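"""Cleaning and segmentation of cuff recordings.

Pipeline order: zero-phase high-pass to kill baseline wander, wavelet
shrinkage to attenuate wide-band noise, then Korotkoff-window location
from the cuff-pressure channel and beat segmentation from the smoothed
analytic-signal envelope.  Beats are detected once here and shared by
every envelope-based feature downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pywt
from scipy import signal

from .io import Recording

__all__ = [
    "BeatSegment",
    "KorotkoffWindow",
    "remove_baseline",
    "wavelet_denoise",
    "smoothed_envelope",
    "detect_window",
    "segment_beats",
]


@dataclass(frozen=True)
class BeatSegment:
    """One detected Korotkoff beat (half-open sample range)."""

    onset: int
    peak: int
    end: int
    amplitude: float  # envelope magnitude at the peak, signal units
    peak_time: float  # s from record start
    cuff_pressure: float  # mmHg at the peak (NaN if no pressure channel)

    def __post_init__(self):
        if not (self.onset <= self.peak < self.end):
            raise ValueError(f"invalid beat segment [{self.onset}, {self.peak}, {self.end})")
        if self.amplitude < 0:
            raise ValueError("beat amplitude is a magnitude and must be >= 0")


@dataclass(frozen=True)
class KorotkoffWindow:
    """Half-open sample range covering DBP < cuff pressure < SBP."""

    start: int
    end: int
    method: str  # "pressure-derived" | "envelope-derived" | "annotated"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def midpoint_time(self, fs: float) -> float:
        return 0.5 * (self.start + self.end) / fs


def remove_baseline(sound: np.ndarray, fs: float, cutoff: float = 5.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass.

    DC gain is zero and the passband (>= 2x cutoff) is within 1% of
    unity after forward-backward filtering; output length equals input.
    """
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, {fs / 2}), got {cutoff}")
    sos = signal.butter(4, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(sound, dtype=float))


def baseline_filter_response(fs: float, cutoff: float, freqs: np.ndarray) -> np.ndarray:
    """Theoretical magnitude response of :func:`remove_baseline` at ``freqs``."""
    sos = signal.butter(4, cutoff, btype="highpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs) / fs)
    return np.abs(h) ** 2  # filtfilt applies the filter twice


def wavelet_denoise(
    sound: np.ndarray,
    wavelet: str = "db6",
    level: int = 4,
    rule: str = "universal-soft",
) -> np.ndarray:
    """Discrete-wavelet shrinkage of wide-band noise.

    Detail coefficients at every level are soft- (or hard-) thresholded
    at the universal threshold ``sigma * sqrt(2 ln N)``, with the noise
    scale ``sigma`` taken from the median absolute deviation of the
    finest detail level.  Approximation coefficients pass untouched.
    """
    x = np.asarray(sound, dtype=float)
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet {wavelet!r}")
    if level < 1:
        raise ValueError("decomposition level must be >= 1")
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet).dec_len)
    if level > max_level:
        raise ValueError(
            f"level {level} infeasible for signal of length {x.size} "
            f"(max {max_level})"
        )
    if rule not in ("universal-soft", "universal-hard"):
        raise ValueError(f"unknown threshold rule {rule!r}")
    coeffs = pywt.wavedec(x, wavelet, level=level)
    sigma = np.median(np.abs(coeffs[-1])) / 0.6744897501960817
    thr = sigma * np.sqrt(2.0 * np.log(max(x.size, 2)))

    def shrink(c):
        if thr == 0.0:
            return c
        if rule.endswith("soft"):
            return np.sign(c) * np.maximum(np.abs(c) - thr, 0.0)
        return np.where(np.abs(c) > thr, c, 0.0)

    coeffs = [coeffs[0]] + [shrink(c) for c in coeffs[1:]]
    out = pywt.waverec(coeffs, wavelet)
    return out[: x.size]


def smoothed_envelope(sound: np.ndarray, fs: float, smooth_ms: float = 50.0) -> np.ndarray:
    """Magnitude of the analytic signal, moving-average smoothed."""
    env = np.abs(signal.hilbert(np.asarray(sound, dtype=float)))
    w = max(1, int(round(smooth_ms / 1000.0 * fs)))
    kernel = np.ones(w) / w
    return signal.convolve(env, kernel, mode="same")


def _envelope_peaks(
    env: np.ndarray,
    fs: float,
    threshold_frac: float,
    min_separation: float,
) -> np.ndarray:
    top = float(np.max(env)) if env.size else 0.0
    if top <= 0:
        return np.array([], dtype=int)
    # beat-likeness guard: a window whose maximum barely clears the bulk of
    # the envelope (noise floor) holds no beats; for real beat trains the
    # max exceeds the median envelope by well over an order of magnitude
    noise_floor = 5.0 * float(np.median(env))
    if top < noise_floor:
        return np.array([], dtype=int)
    height = max(threshold_frac * top, noise_floor)
    peaks, _ = signal.find_peaks(
        env,
        height=height,
        prominence=0.5 * threshold_frac * top,
        distance=max(1, int(round(min_separation * fs))),
    )
    return peaks


def detect_window(
    rec: Recording,
    threshold_frac: float = 0.10,
    min_separation: float = 0.3,
    smooth_ms: float = 50.0,
) -> KorotkoffWindow:
    """Locate the Korotkoff window of one recording.

    An annotated recording returns its annotation verbatim.  Otherwise
    the first and last beat-like envelope excursions above an adaptive
    threshold estimate the SBP/DBP crossings; with a usable (deflating)
    pressure channel the window is the sample range where the cuff
    pressure lies strictly between those crossing pressures, padded by
    half a beat interval to recover the threshold-trimmed window edges.
    """
    if rec.annotations is not None:
        return KorotkoffWindow(*rec.annotations, method="annotated")

    fs = rec.fs
    clean = wavelet_denoise(remove_baseline(rec.sound, fs))
    env = smoothed_envelope(clean, fs, smooth_ms)
    peaks = _envelope_peaks(env, fs, threshold_frac, min_separation)
    if peaks.size == 0:
        raise ValueError("no beats detected in recording")

    # extend the strong-beat span outward over fainter beats: a lower,
    # noise-floor-aware threshold, accepting peaks only while they stay
    # contiguous (within ~2 beat intervals) with the detected train
    median_int = float(np.median(np.diff(peaks))) if peaks.size > 2 else 0.8 * fs
    top = float(np.max(env))
    edge = max(0.4 * threshold_frac * top, 2.0 * float(np.median(env)))
    peaks_lo = _envelope_peaks(env, fs, edge / top, min_separation)
    first, last = int(peaks[0]), int(peaks[-1])
    for q in peaks_lo[peaks_lo < first][::-1]:
        if first - q <= 2.0 * median_int:
            first = int(q)
        else:
            break
    for q in peaks_lo[peaks_lo > last]:
        if q - last <= 2.0 * median_int:
            last = int(q)
        else:
            break
    peaks = np.array([first, last])
    pad = int(round(0.5 * median_int))
    p = rec.cuff_pressure
    pressure_usable = float(np.ptp(p)) > 1.0
    if pressure_usable and p[-1] > p[0]:
        raise ValueError("cuff pressure is increasing: inflation-only record")
    start = max(0, int(peaks[0]) - pad)
    end = min(rec.sound.size, int(peaks[-1]) + pad + 1)
    method = "pressure-derived" if pressure_usable else "envelope-derived"
    if pressure_usable:
        # refine against the pressure channel: keep samples strictly between
        # the estimated SBP (pressure at first beat + pad) and DBP bounds
        sbp_est = float(p[start])
        dbp_est = float(p[min(end, p.size) - 1])
        inside = np.flatnonzero((p < sbp_est + 1e-9) & (p > dbp_est - 1e-9))
        if inside.size:
            start, end = int(inside[0]), int(inside[-1]) + 1
    return KorotkoffWindow(start, end, method=method)


def segment_beats(
    sound: np.ndarray,
    window: KorotkoffWindow,
    fs: float,
    min_separation: float = 0.3,
    threshold_frac: float = 0.2,
    smooth_ms: float = 50.0,
    cuff_pressure: Optional[np.ndarray] = None,
) -> list[BeatSegment]:
    """Segment individual beats inside the Korotkoff window.

    Peaks are local maxima of the smoothed magnitude envelope above
    ``threshold_frac`` of the window's envelope maximum, separated by at
    least ``min_separation`` seconds (of two closer peaks the larger
    survives, via peak prominence/distance pruning).  Segments tile the
    window without overlap, split at inter-peak midpoints.
    """
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    x = np.asarray(sound, dtype=float)
    if window.end > x.size:
        raise ValueError("window extends past the signal")
    seg = x[window.start : window.end]
    if seg.size == 0:
        raise ValueError("empty Korotkoff window")
    env = smoothed_envelope(seg, fs, smooth_ms)
    peaks = _envelope_peaks(env, fs, threshold_frac, min_separation)
    beats: list[BeatSegment] = []
    if peaks.size == 0:
        return beats
    bounds = np.concatenate(
        [[0], ((peaks[:-1] + peaks[1:]) // 2 + 1), [seg.size]]
    )
    for k, pk in enumerate(peaks):
        onset = int(bounds[k]) + window.start
        end = int(bounds[k + 1]) + window.start
        peak = int(pk) + window.start
        pressure = float(cuff_pressure[peak]) if cuff_pressure is not None else float("nan")
        beats.append(
            BeatSegment(
                onset=onset,
                peak=peak,
                end=end,
                amplitude=float(env[pk]),
                peak_time=peak / fs,
                cuff_pressure=pressure,
            )
        )
    return beats
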