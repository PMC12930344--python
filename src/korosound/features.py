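"""The ten-feature acoustic characterization of a Korotkoff recording.

Six time-domain features (maximum amplitude, kurtosis, envelope temporal
skewness, peak/crest factor, pulse/impulse factor, form factor), the
center-of-mass statistic, and three frequency-domain features (peak
frequency, spectral centroid a.k.a. center-of-gravity frequency, and
mean-square frequency).

Definitions, fixed in one place:

* ``max_amplitude``  = max |x|
* ``kurtosis``       = fourth standardized central moment (non-excess)
* ``peak_factor``    = max |x| / RMS            (RMS about zero)
* ``pulse_factor``   = max |x| / mean |x|
* ``form_factor``    = RMS / mean |x|           (so pulse = peak * form)
* ``center_of_mass`` = amplitude-weighted beat-time mean, measured from
  the window midpoint **along the deflation direction**: positive values
  mean the sound mass sits at higher cuff pressures (earlier in the
  window), the compliant-artery pattern; negative values mean the mass
  sits late (stiff-artery pattern).  Units: seconds.
* ``skewness``       = amplitude-weighted third standardized moment of
  beat peak times; amplitude mass early in the window gives a long late
  tail, hence positive skewness — the same sign convention as
  ``center_of_mass``.
* spectral features  = argmax and first/second power-weighted moments of
  the Welch PSD of the concatenated beat segments.

Amplitude units are arbitrary sensor counts; every feature except
``max_amplitude`` is invariant to positive amplitude scaling.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .io import Recording
from .preprocess import (
    BeatSegment,
    KorotkoffWindow,
    detect_window,
    remove_baseline,
    segment_beats,
    wavelet_denoise,
)

__all__ = [
    "FeatureVector",
    "FeatureConfig",
    "FEATURE_NAMES",
    "amplitude_stats",
    "envelope_moments",
    "spectral_features",
    "extract_features",
]

FEATURE_NAMES = [
    "max_amplitude",
    "kurtosis",
    "skewness",
    "peak_factor",
    "pulse_factor",
    "form_factor",
    "center_of_mass",
    "peak_frequency",
    "centroid_frequency",
    "mean_square_frequency",
]


@dataclass(frozen=True)
class FeatureVector:
    """The ten named acoustic features of one recording."""

    max_amplitude: float
    kurtosis: float
    skewness: float
    peak_factor: float
    pulse_factor: float
    form_factor: float
    center_of_mass: float  # s, positive = mass at higher cuff pressures
    peak_frequency: float  # Hz
    centroid_frequency: float  # Hz
    mean_square_frequency: float  # Hz^2

    def as_dict(self) -> dict:
        return asdict(self)

    def as_array(self) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[k] for k in FEATURE_NAMES])


@dataclass(frozen=True)
class FeatureConfig:
    """Every tunable of the feature pipeline, config-frozen."""

    highpass_cutoff: float = 5.0  # Hz
    wavelet: str = "db6"
    wavelet_level: int = 4
    threshold_rule: str = "universal-soft"
    window_threshold: float = 0.10  # envelope fraction for window edges
    beat_threshold: float = 0.20  # envelope fraction for beat peaks
    min_separation: float = 0.3  # s between beat peaks
    smooth_ms: float = 50.0
    psd_segment: float = 1.0  # s, Welch segment length


def amplitude_stats(x: np.ndarray) -> tuple[float, float, float, float, float]:
    """Time-domain amplitude statistics of a (beat-train) sample window.

    Returns ``(max_amplitude, kurtosis, peak_factor, pulse_factor,
    form_factor)``.  The three factors use raw moments (RMS and mean
    absolute value about zero), the vibration-analysis convention, so
    the identity ``pulse = peak * form`` is exact.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    abs_x = np.abs(x)
    max_amp = float(np.max(abs_x))
    rms = float(np.sqrt(np.mean(x**2)))
    mean_abs = float(np.mean(abs_x))
    if rms == 0.0 or mean_abs == 0.0:
        raise ValueError("zero-energy window: factor ratios undefined")
    mu = float(np.mean(x))
    m2 = float(np.mean((x - mu) ** 2))
    if m2 == 0.0:
        raise ValueError("constant window: kurtosis undefined")
    kurt = float(np.mean((x - mu) ** 4) / m2**2)
    return max_amp, kurt, max_amp / rms, max_amp / mean_abs, rms / mean_abs


def envelope_moments(
    beats: Sequence[BeatSegment],
    window: KorotkoffWindow,
    fs: float,
) -> tuple[float, float]:
    """Center of mass and temporal skewness of the beat-amplitude envelope.

    With weights ``w_i = A_i / sum(A)`` over beat peak times ``t_i``::

        mu             = sum(w_i t_i)
        center_of_mass = t_mid - mu        (deflation-direction sign:
                                            mass early/high-pressure => +)
        skewness       = sum(w_i (t_i-mu)^3) / (sum(w_i (t_i-mu)^2))^1.5

    Time-reversing the beats within the window negates both outputs.
    """
    if len(beats) < 3:
        raise ValueError(f"need >= 3 beats for envelope moments, got {len(beats)}")
    t = np.array([b.peak_time for b in beats])
    a = np.array([b.amplitude for b in beats])
    total = a.sum()
    if total <= 0:
        raise ValueError("all beat amplitudes are zero")
    w = a / total
    mu = float(np.sum(w * t))
    t_mid = window.midpoint_time(fs)
    m2 = float(np.sum(w * (t - mu) ** 2))
    m3 = float(np.sum(w * (t - mu) ** 3))
    skew = 0.0 if m2 == 0.0 else m3 / m2**1.5
    return t_mid - mu, skew


def spectral_features(
    x: np.ndarray,
    fs: float,
    segment_s: float = 1.0,
) -> tuple[float, float, float]:
    """Peak, centroid, and mean-square frequency of a sample window.

    The power spectral density is an averaged periodogram (Hann taper,
    50% overlap, ``segment_s``-second segments, capped at half the
    window so at least two segments average).  Returns frequencies in
    Hz and Hz^2; all three are invariant to amplitude scaling.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("window too short for a spectral estimate")
    if float(np.max(np.abs(x))) == 0.0:
        raise ValueError("zero-energy input")
    nperseg = min(int(round(segment_s * fs)), x.size // 2)
    nperseg = max(nperseg, 8)
    f, p = signal.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    total = float(np.sum(p))
    peak = float(f[int(np.argmax(p))])
    centroid = float(np.sum(f * p) / total)
    msf = float(np.sum(f**2 * p) / total)
    return peak, centroid, msf


@dataclass(frozen=True)
class FeatureExtraction:
    """Feature vector plus the intermediates it was computed from."""

    features: FeatureVector
    window: KorotkoffWindow
    beats: tuple
    clean: np.ndarray


class StageError(RuntimeError):
    """Pipeline failure carrying the name of the stage that raised."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"[{stage}] {error}")
        self.stage = stage
        self.error = error


def extract_features(
    rec: Recording,
    config: FeatureConfig = FeatureConfig(),
    return_intermediates: bool = False,
):
    """Full deterministic pipeline from raw recording to FeatureVector.

    Order: baseline removal -> wavelet denoising -> window detection ->
    beat segmentation -> amplitude/envelope/spectral statistics.  The
    amplitude and spectral statistics are computed on the concatenated
    denoised beat segments; the envelope moments on the beat peak train.
    """

    def _run(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ValueError, RuntimeError) as exc:
            raise StageError(stage, exc) from exc

    clean = _run("remove_baseline", remove_baseline, rec.sound, rec.fs, config.highpass_cutoff)
    clean = _run(
        "wavelet_denoise",
        wavelet_denoise,
        clean,
        config.wavelet,
        config.wavelet_level,
        config.threshold_rule,
    )
    cleaned_rec = Recording(
        clean, rec.cuff_pressure, rec.fs, rec.subject_id, annotations=rec.annotations
    )
    window = _run(
        "detect_window",
        detect_window,
        cleaned_rec,
        threshold_frac=config.window_threshold,
        min_separation=config.min_separation,
        smooth_ms=config.smooth_ms,
    )
    beats = _run(
        "segment_beats",
        segment_beats,
        clean,
        window,
        rec.fs,
        min_separation=config.min_separation,
        threshold_frac=config.beat_threshold,
        smooth_ms=config.smooth_ms,
        cuff_pressure=rec.cuff_pressure,
    )
    if len(beats) < 3:
        raise StageError("segment_beats", ValueError(f"only {len(beats)} beats detected"))

    concat = np.concatenate([clean[b.onset : b.end] for b in beats])
    max_amp, kurt, peak_f, pulse_f, form_f = _run("amplitude_stats", amplitude_stats, concat)
    com, skew = _run("envelope_moments", envelope_moments, beats, window, rec.fs)
    pf, cf, msf = _run("spectral_features", spectral_features, concat, rec.fs, config.psd_segment)
    fv = FeatureVector(
        max_amplitude=max_amp,
        kurtosis=kurt,
        skewness=skew,
        peak_factor=peak_f,
        pulse_factor=pulse_f,
        form_factor=form_f,
        center_of_mass=com,
        peak_frequency=pf,
        centroid_frequency=cf,
        mean_square_frequency=msf,
    )
    if return_intermediates:
        return FeatureExtraction(features=fv, window=window, beats=tuple(beats), clean=clean)
    return fv
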