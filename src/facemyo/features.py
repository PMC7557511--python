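"""Band-energy feature extraction.

For each epoch the decoder receives 12 features: the signal energy in
three frequency bands (64-128, 128-256, 256-500 Hz) on each of the four
channels.  The FFT features sum squared DFT coefficient magnitudes over
the bins of each band, P = sum_i y_i^2, computed on the raw unwindowed
epoch (no taper).  A discrete-wavelet alternative decomposes each channel
three levels deep (Daubechies-5, Mallat pyramid) and uses the energies of
the three detail subbands, ordered low-to-high frequency (D3, D2, D1) to
mirror the FFT layout.

Feature layout is channel-major: for channels (F7, F8, FC5, FC6) and
ascending bands b1 < b2 < b3 the vector is
[F7:b1, F7:b2, F7:b3, F8:b1, ...].  Band intervals are half-open
[low, high) so shared edges (128, 256 Hz) are not double counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .preprocess import Epoch
from .synth_emg import DEFAULT_BANDS, ActionClass

__all__ = [
    "BandSet",
    "FeatureScaler",
    "fft_band_energy",
    "wt_band_energy",
    "build_feature_table",
    "feature_names",
]


@dataclass(frozen=True)
class BandSet:
    """Ordered, non-overlapping frequency bands (Hz)."""

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        prev_high = 0.0
        for low, high in self.bands:
            if not 0 < low < high:
                raise ValueError(f"invalid band ({low}, {high})")
            if low < prev_high:
                raise ValueError("bands must be ascending and non-overlapping")
            prev_high = high

    def __len__(self) -> int:
        return len(self.bands)


def fft_band_energy(epoch: Epoch, bands: BandSet | None = None) -> np.ndarray:
    """FFT band energies, channel-major, length n_channels * n_bands.

    Per channel, the DFT of the unwindowed epoch is taken and, for each
    band, the squared coefficient magnitudes are summed over the bins
    whose frequency lies in [low, high).
    """
    bands = bands or BandSet()
    n = epoch.n_samples
    if n < 2:
        raise ValueError("epoch must contain at least 2 samples")
    nyq = epoch.sampling_rate / 2.0
    for low, high in bands.bands:
        if high > nyq:
            raise ValueError(
                f"band ({low}, {high}) exceeds Nyquist ({nyq} Hz)"
            )
    spec = np.fft.rfft(epoch.signal, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / epoch.sampling_rate)
    power = np.abs(spec) ** 2
    out = np.empty(epoch.signal.shape[0] * len(bands))
    for ci in range(epoch.signal.shape[0]):
        for bi, (low, high) in enumerate(bands.bands):
            mask = (freqs >= low) & (freqs < high)
            out[ci * len(bands) + bi] = power[ci, mask].sum()
    return out


def wt_band_energy(
    epoch: Epoch,
    wavelet: str = "db5",
    level: int = 3,
) -> np.ndarray:
    """Detail-subband energies of a level-deep DWT, channel-major.

    Subbands are ordered low-to-high frequency (D_level, ..., D1) so the
    layout mirrors :func:`fft_band_energy`.  Periodized boundary handling
    keeps the transform (near-)orthogonal so total subband energy matches
    signal energy.
    """
    if level < 1:
        raise ValueError("decomposition level must be >= 1")
    n = epoch.n_samples
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if level > max_level:
        raise ValueError(
            f"epoch of {n} samples supports at most {max_level} levels "
            f"for wavelet {wavelet}, requested {level}"
        )
    n_ch = epoch.signal.shape[0]
    out = np.empty(n_ch * level)
    for ci in range(n_ch):
        coeffs = pywt.wavedec(epoch.signal[ci], wavelet, level=level,
                              mode="periodization")
        # coeffs = [A_L, D_L, D_{L-1}, ..., D_1]; details are already
        # ordered low-to-high frequency.
        for bi, d in enumerate(coeffs[1:]):
            out[ci * level + bi] = float(np.sum(d ** 2))
    return out


def feature_names(
    channels: tuple[str, ...],
    bands: BandSet | None = None,
    method: str = "fft",
    level: int = 3,
) -> list[str]:
    """Column names matching the channel-major feature layout."""
    if method == "fft":
        bands = bands or BandSet()
        tags = [f"{int(lo)}-{int(hi)}Hz" for lo, hi in bands.bands]
    elif method == "wt":
        tags = [f"D{level - i}" for i in range(level)]
    else:
        raise ValueError(f"unknown feature method {method!r}")
    return [f"{ch}:{tag}" for ch in channels for tag in tags]


def build_feature_table(
    epochs: list[Epoch],
    method: str = "fft",
    bands: BandSet | None = None,
    wavelet: str = "db5",
    level: int = 3,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table (rows = epochs, in order) and aligned label array."""
    if not epochs:
        raise ValueError("epoch list is empty")
    fs0 = epochs[0].sampling_rate
    ch0 = epochs[0].channels
    for ep in epochs:
        if ep.sampling_rate != fs0:
            raise ValueError("epochs mix different sampling rates")
        if ep.channels != ch0:
            raise ValueError("epochs mix different channel layouts")
    if method == "fft":
        rows = [fft_band_energy(ep, bands) for ep in epochs]
    elif method == "wt":
        rows = [wt_band_energy(ep, wavelet=wavelet, level=level) for ep in epochs]
    else:
        raise ValueError(f"unknown feature method {method!r}")
    table = pd.DataFrame(
        np.vstack(rows),
        columns=feature_names(ch0, bands, method=method, level=level),
    )
    labels = np.array([ep.label for ep in epochs], dtype=object)
    return table, labels


class FeatureScaler:
    """Per-feature z-scoring, fit on training folds only.

    Raw band energies span orders of magnitude; sigmoid networks need
    bounded inputs.  Constant features are passed through unscaled.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray | pd.DataFrame) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler is not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        return self.fit(X).transform(X)
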