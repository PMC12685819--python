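"""Per-segment ECG feature extraction: an ordered 33-value vector.

Each segment yields 11 statistical features (mean, median, SD, IQR, skewness,
excess kurtosis, min, max, range, RMS, Shannon entropy), 12 wavelet features
(db4 decomposition to level 3; mean, SD and RMS energy for sub-bands A3, D3,
D2, D1 in that order), and 10 spectral features (mean power of the 10 lowest
STFT frequency bins, Hann window of 64 samples with 50% overlap).

Conventions, fixed so every value is exactly reproducible:

* moments are population moments; skewness = m3/m2^1.5 and excess (Fisher)
  kurtosis = m4/m2² − 3, both defined as 0 on a constant segment;
* the published feature list names ten statistical quantities but counts
  eleven; the eleventh here is the range (max − min), consistent with the
  "range-based metrics" grouping — a reconstruction, documented as such;
* entropy uses a 16-bin equal-width histogram over the segment's own
  [min, max], log base 2, 0·log 0 := 0;
* DWT boundary handling is symmetric extension;
* STFT power is the squared magnitude of the windowed one-sided FFT with no
  window normalisation (``power="magnitude"`` switches to |·|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "EntropySpec",
    "STAT_FEATURE_NAMES",
    "WAVELET_FEATURE_NAMES",
    "STFT_FEATURE_NAMES",
    "FEATURE_NAMES",
    "statistical_features",
    "shannon_entropy",
    "wavelet_features",
    "stft_features",
    "extract_features",
]


@dataclass
class EntropySpec:
    n_bins: int = 16

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


STAT_FEATURE_NAMES = [
    "mean", "median", "sd", "iqr", "skewness", "kurtosis",
    "min", "max", "range", "rms", "entropy",
]
WAVELET_FEATURE_NAMES = [
    f"{band}_{stat}" for band in ("a3", "d3", "d2", "d1")
    for stat in ("mean", "sd", "rms")
]
STFT_FEATURE_NAMES = [f"stft_bin{k}" for k in range(10)]
FEATURE_NAMES = STAT_FEATURE_NAMES + WAVELET_FEATURE_NAMES + STFT_FEATURE_NAMES


def shannon_entropy(segment: np.ndarray, spec: EntropySpec | None = None) -> float:
    """Shannon entropy (bits) of the normalised amplitude histogram."""
    spec = spec or EntropySpec()
    x = np.asarray(segment, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("segment must be non-empty")
    lo, hi = x.min(), x.max()
    if hi == lo or (hi - lo) / spec.n_bins == 0.0:
        # constant (or below float resolution): a single occupied bin
        return 0.0
    counts, _ = np.histogram(x, bins=spec.n_bins, range=(lo, hi))
    p = counts / x.size
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def statistical_features(segment: np.ndarray,
                         entropy_spec: EntropySpec | None = None) -> np.ndarray:
    """The 11 order-fixed statistical features of one segment."""
    x = np.asarray(segment, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("segment must have at least 2 samples")
    mean = x.mean()
    sd = x.std()
    m2 = sd ** 2
    if m2 == 0:
        skew = kurt = 0.0
    else:
        centred = x - mean
        skew = float((centred ** 3).mean() / m2 ** 1.5)
        kurt = float((centred ** 4).mean() / m2 ** 2 - 3.0)
    q25, q75 = np.percentile(x, [25, 75])  # linear-interpolation percentiles
    mn, mx = x.min(), x.max()
    return np.array([
        mean,
        np.median(x),
        sd,
        q75 - q25,
        skew,
        kurt,
        mn,
        mx,
        mx - mn,
        np.sqrt((x ** 2).mean()),
        shannon_entropy(x, entropy_spec),
    ])


def wavelet_features(segment: np.ndarray, *, wavelet: str = "db4",
                     level: int = 3) -> np.ndarray:
    """Mean, SD and RMS energy of each wavelet sub-band, ordered A3, D3, D2, D1."""
    x = np.asarray(segment, dtype=float).ravel()
    min_len = 2 ** level
    if x.size < min_len:
        raise ValueError(f"segment of {x.size} samples too short for level-{level} DWT")
    coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=level)
    out = []
    for band in coeffs:  # wavedec order: [A3, D3, D2, D1]
        out.extend([band.mean(), band.std(), np.sqrt((band ** 2).mean())])
    return np.array(out)


def stft_features(segment: np.ndarray, *, nperseg: int = 64, n_bands: int = 10,
                  power: str = "squared") -> np.ndarray:
    """Mean power of the ``n_bands`` lowest STFT frequency bins.

    Hann window of ``nperseg`` samples, hop ``nperseg // 2`` (50% overlap), no
    boundary padding; one output per bin, averaged over time frames.
    """
    x = np.asarray(segment, dtype=float).ravel()
    if x.size < nperseg:
        raise ValueError(f"segment of {x.size} samples shorter than nperseg={nperseg}")
    if power not in ("squared", "magnitude"):
        raise ValueError("power must be 'squared' or 'magnitude'")
    hop = nperseg // 2
    n_frames = (x.size - nperseg) // hop + 1
    idx = np.arange(nperseg)[None, :] + hop * np.arange(n_frames)[:, None]
    window = np.hanning(nperseg)
    spec = np.fft.rfft(x[idx] * window, axis=1)
    mag = np.abs(spec[:, :n_bands])
    pw = mag ** 2 if power == "squared" else mag
    return pw.mean(axis=0)


def extract_features(segment: np.ndarray,
                     entropy_spec: EntropySpec | None = None) -> np.ndarray:
    """Concatenate statistical ∥ wavelet ∥ STFT features for one segment, or for
    a batch of segments (2-D input → rows of 33)."""
    seg = np.asarray(segment, dtype=float)
    if seg.ndim == 2:
        return np.stack([extract_features(row, entropy_spec) for row in seg])
    return np.concatenate([
        statistical_features(seg, entropy_spec),
        wavelet_features(seg),
        stft_features(seg),
    ])
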