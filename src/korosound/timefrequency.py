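"""Continuous-wavelet scalograms and their fixed-size RGB rendering.

The scalogram is the magnitude of an analytic (complex Morlet) wavelet
transform on log-spaced center frequencies; the RGB rendering min-max
normalizes the log-magnitude, resizes bilinearly, and applies a fixed
perceptually-uniform colormap so images are bit-identical across runs
and plotting backends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from skimage.transform import resize as _resize

__all__ = ["Scalogram", "cwt_scalogram", "scalogram_to_rgb"]

#: analytic Morlet: bandwidth 1.5, center frequency 1.0 (cycles/sample at scale 1)
_WAVELET = "cmor1.5-1.0"


@dataclass(frozen=True)
class Scalogram:
    """CWT magnitude matrix with axes.

    ``magnitude`` has shape (n_scales, n_samples); ``frequencies`` is
    ascending in Hz; ``times`` in seconds from window start.
    """

    magnitude: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        if self.magnitude.shape != (self.frequencies.size, self.times.size):
            raise ValueError("axis lengths do not match magnitude shape")
        if np.any(self.magnitude < 0):
            raise ValueError("scalogram magnitudes must be non-negative")


def cwt_scalogram(
    sound: np.ndarray,
    fs: float,
    f_min: float = 5.0,
    f_max: float = 100.0,
    n_scales: int = 64,
) -> Scalogram:
    """Analytic-wavelet scalogram on log-spaced center frequencies.

    Linear in input amplitude.  Frequencies run ascending from ``f_min``
    to ``f_max`` (rows of ``magnitude`` in the same order).
    """
    x = np.asarray(sound, dtype=float)
    if not (0 < f_min < f_max <= fs / 2):
        raise ValueError(f"invalid band [{f_min}, {f_max}] for fs={fs}")
    if n_scales < 8:
        raise ValueError("need at least 8 scales")
    # longest wavelet support ~ 2 * bandwidth-sigma at the lowest frequency
    min_len = int(2.0 * fs / f_min)
    if x.size < min_len:
        raise ValueError(
            f"signal of {x.size} samples shorter than the longest wavelet "
            f"support (~{min_len} samples at {f_min} Hz)"
        )
    freqs = np.geomspace(f_min, f_max, n_scales)
    fc = pywt.central_frequency(_WAVELET)
    scales = fc * fs / freqs
    coef, _ = pywt.cwt(x, scales, _WAVELET, sampling_period=1.0 / fs)
    # scales descend with ascending freqs, so rows already ascend in frequency
    mag = np.abs(coef)
    return Scalogram(magnitude=mag, frequencies=freqs, times=np.arange(x.size) / fs)


def _colormap_lut(name: str) -> np.ndarray:
    import matplotlib

    cmap = matplotlib.colormaps[name]
    return (np.asarray(cmap(np.linspace(0.0, 1.0, 256)))[:, :3] * 255).round().astype(np.uint8)


def scalogram_to_rgb(
    sc: Scalogram,
    height: int = 224,
    width: int = 224,
    colormap: str = "viridis",
) -> np.ndarray:
    """Render a scalogram as a fixed-size 8-bit RGB image.

    Log-magnitude is min-max normalized per image (so global amplitude
    scale drops out), bilinearly resized to (height, width), and mapped
    through a fixed 256-entry colormap lookup table.  A degenerate
    (constant) scalogram renders as a mid-colormap fill.  Row 0 of the
    image is the highest frequency (spectrogram orientation).
    """
    if height <= 0 or width <= 0:
        raise ValueError("image size must be positive")
    mag = sc.magnitude[::-1]  # high frequencies on top
    top = float(np.max(mag))
    if top <= 0 or float(np.min(mag)) == top:
        v = np.full((height, width), 0.5)
    else:
        logmag = np.log10(mag + 1e-6 * top)
        v = _resize(logmag, (height, width), order=1, mode="edge", anti_aliasing=False)
        lo, hi = float(np.min(v)), float(np.max(v))
        v = (v - lo) / (hi - lo) if hi > lo else np.full_like(v, 0.5)
    lut = _colormap_lut(colormap)
    idx = np.clip((v * 255.0).round().astype(int), 0, 255)
    return lut[idx]
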