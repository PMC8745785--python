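"""Morlet continuous-wavelet-transform scalograms of ECG windows.

Each window x(t) is transformed with a complex Morlet wavelet (the
conventional omega_0 ~ 6 parameterization, i.e. a unit-variance Gaussian
envelope with center frequency f_c = 6/(2*pi) ~ 0.9549 cycles/sample at
scale 1); the scalogram is |X_w(s, tau)| on a log-spaced scale set, mapped
to Hz through the wavelet's center frequency.

Four analysis bands are preset:

* ``overall`` 0.1–50 Hz, ``high`` 8–50 Hz, ``middle`` 0.8–10 Hz,
  ``low`` 0–0.8 Hz (the low band's 0 Hz edge is floored at 0.05 Hz, the
  lowest scale the default set resolves).

Normal breathing shows markedly stronger spectral intensity than apnea in
the mid-band (around 5–10 Hz), which is what downstream bag-of-features
classification exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt

from .errors import BandError
from .preprocessing import EcgWindow

#: Complex Morlet, Gaussian-envelope variance 1 (B=2), f_c = 6/(2*pi).
DEFAULT_WAVELET = "cmor2.0-0.9549"
#: Effective lower edge used for the "0 Hz" boundary of the low band.
MIN_FREQ_HZ = 0.05
DEFAULT_VOICES_PER_OCTAVE = 12
DEFAULT_IMAGE_WIDTH = 256


@dataclass(frozen=True)
class BandSpec:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError(f"need 0 <= f_lo < f_hi, got {self.f_lo}, {self.f_hi}")


BAND_PRESETS: dict[str, BandSpec] = {
    "overall": BandSpec("overall", 0.1, 50.0),
    "high": BandSpec("high", 8.0, 50.0),
    "middle": BandSpec("middle", 0.8, 10.0),
    "low": BandSpec("low", 0.0, 0.8),
}


@dataclass(frozen=True)
class WindowRef:
    """Provenance of the window a scalogram/image was computed from."""

    record_id: str
    start_sec: float
    duration_sec: int
    label: str
    stage: str = "UNKNOWN"


@dataclass
class Scalogram:
    """|CWT| magnitude over (frequency, time) for one window, one band."""

    values: np.ndarray  # (n_freqs, n_times), >= 0
    freqs: np.ndarray  # Hz, strictly decreasing
    times: np.ndarray  # seconds within the window
    band: BandSpec
    source_window: WindowRef

    def __post_init__(self):
        if (self.values < 0).any():
            raise ValueError("scalogram values must be non-negative magnitudes")
        d = np.diff(self.freqs)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("frequency axis must be strictly monotone")


@dataclass
class SpectrogramImage:
    """Fixed-size 8-bit grayscale rendering of a scalogram.

    ``split`` tags train/test membership for the bag-of-features leakage
    guard; ``None`` means unassigned.
    """

    pixels: np.ndarray  # uint8, (height, width); row 0 = highest frequency
    provenance: WindowRef
    band: BandSpec
    split: str | None = None

    @property
    def label(self) -> str:
        return self.provenance.label


def band_frequencies(
    band: BandSpec, voices_per_octave: int = DEFAULT_VOICES_PER_OCTAVE
) -> np.ndarray:
    """Log-spaced analysis frequencies (Hz, descending) covering a band."""
    f_lo = max(band.f_lo, MIN_FREQ_HZ)
    n = int(np.ceil(voices_per_octave * np.log2(band.f_hi / f_lo))) + 1
    return np.geomspace(band.f_hi, f_lo, n)


def cwt_scalogram(
    window: EcgWindow,
    band: BandSpec | str = "overall",
    voices_per_octave: int = DEFAULT_VOICES_PER_OCTAVE,
    wavelet: str = DEFAULT_WAVELET,
) -> Scalogram:
    """Morlet-CWT magnitude scalogram of one window, restricted to a band."""
    if isinstance(band, str):
        band = BAND_PRESETS[band]
    nyq = window.fs / 2
    if band.f_hi > nyq:
        raise BandError(
            f"band {band.name!r} upper edge {band.f_hi} Hz exceeds Nyquist "
            f"{nyq} Hz at fs={window.fs} Hz"
        )
    freqs = band_frequencies(band, voices_per_octave)
    dt = 1.0 / window.fs
    wav = pywt.ContinuousWavelet(wavelet)
    scales = pywt.frequency2scale(wav, freqs * dt)
    coef, freqs_hz = pywt.cwt(
        window.samples, scales, wav, sampling_period=dt, method="fft"
    )
    # Rescale the library's L2-normalized output to the 1/s (L1) convention
    # of the transform definition: a pure tone then has a scale-independent
    # ridge amplitude, so the ridge is not biased toward larger scales.
    coef = coef / np.sqrt(scales)[:, None]
    return Scalogram(
        values=np.abs(coef),
        freqs=np.asarray(freqs_hz),
        times=np.arange(len(window.samples)) * dt,
        band=band,
        source_window=WindowRef(
            window.record_id, window.start_sec, window.duration_sec,
            window.label, window.stage,
        ),
    )


def extract_band(scal: Scalogram, band: BandSpec | str) -> Scalogram:
    """Slice a scalogram to the rows with f_lo <= f <= f_hi, order preserved."""
    if isinstance(band, str):
        band = BAND_PRESETS[band]
    f_lo = max(band.f_lo, 0.0)
    mask = (scal.freqs >= f_lo) & (scal.freqs <= band.f_hi)
    if not mask.any():
        raise BandError(
            f"no scale falls inside band {band.name!r} [{band.f_lo}, {band.f_hi}] Hz; "
            "use denser scales (more voices per octave)"
        )
    return replace(
        scal, values=scal.values[mask], freqs=scal.freqs[mask], band=band
    )


def render_image(
    scal: Scalogram,
    width: int = DEFAULT_IMAGE_WIDTH,
    compression: str = "log1p",
    split: str | None = None,
) -> SpectrogramImage:
    """Render a scalogram as a fixed-width 8-bit grayscale image.

    Magnitudes are compressed (``log1p`` by default, matching the dB-like
    dynamic range of scalogram plots, or ``linear``), per-image min-max
    normalized to [0, 255], and the time axis is linearly resampled to
    ``width`` columns.  Rows are ordered by descending frequency (high
    frequencies at the top).  A constant scalogram renders all-zero.
    """
    if scal.values.size == 0:
        raise ValueError("cannot render an empty scalogram")
    if compression == "log1p":
        v = np.log1p(scal.values)
    elif compression == "linear":
        v = scal.values.astype(np.float64)
    else:
        raise ValueError(f"unknown compression {compression!r}")
    if scal.freqs[0] < scal.freqs[-1]:  # ensure descending
        v = v[::-1]
    n = v.shape[1]
    if n != width:
        idx = np.linspace(0, n - 1, width)
        lo = np.floor(idx).astype(int)
        hi = np.minimum(lo + 1, n - 1)
        frac = idx - lo
        v = v[:, lo] * (1 - frac) + v[:, hi] * frac
    vmin, vmax = v.min(), v.max()
    if vmax - vmin <= 0:
        pixels = np.zeros(v.shape, dtype=np.uint8)
    else:
        pixels = np.round((v - vmin) / (vmax - vmin) * 255).astype(np.uint8)
    return SpectrogramImage(
        pixels=pixels, provenance=scal.source_window, band=scal.band, split=split
    )


def save_png(image: SpectrogramImage, path) -> None:
    """Optional PNG export for visual inspection."""
    import imageio.v3 as iio

    iio.imwrite(path, image.pixels)
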