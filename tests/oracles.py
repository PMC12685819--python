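"""Independent reference implementations used only by the test suite.

Every function here recomputes a quantity by the most literal route available
(explicit loops, textbook formulas, direct convolution), deliberately avoiding
the code paths of the package itself.
"""

import math

import numpy as np
import pywt


def stat_features_naive(x):
    """The 11 statistical features via pure-python formulas."""
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    xs = sorted(x)
    median = (xs[n // 2] if n % 2 == 1
              else 0.5 * (xs[n // 2 - 1] + xs[n // 2]))
    m2 = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(m2)
    if m2 == 0:
        skew = kurt = 0.0
    else:
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2 - 3.0

    def percentile(q):
        # linear interpolation between order statistics
        pos = q / 100.0 * (n - 1)
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return xs[lo] * (1 - frac) + xs[hi] * frac

    iqr = percentile(75) - percentile(25)
    mn, mx = xs[0], xs[-1]
    rms = math.sqrt(sum(v * v for v in x) / n)
    return [mean, median, sd, iqr, skew, kurt, mn, mx, mx - mn, rms,
            entropy_naive(x)]


def entropy_naive(x, n_bins=16):
    """Shannon entropy by explicit bin counting."""
    x = [float(v) for v in x]
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    width = (hi - lo) / n_bins
    counts = [0] * n_bins
    for v in x:
        b = int((v - lo) / width)
        if b == n_bins:  # the maximum lands in the last bin
            b = n_bins - 1
        counts[b] += 1
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / len(x)
            h -= p * math.log2(p)
    return h


def dwt_step_conv(x, wavelet="db4"):
    """One DWT level by symmetric extension, full convolution, downsampling."""
    w = pywt.Wavelet(wavelet)
    g, h = np.array(w.dec_lo), np.array(w.dec_hi)
    filt_len = len(g)
    out_len = (len(x) + filt_len - 1) // 2
    ext = np.pad(np.asarray(x, float), (filt_len - 1, filt_len - 1),
                 mode="symmetric")
    approx = np.convolve(ext, g)[filt_len::2][:out_len]
    detail = np.convolve(ext, h)[filt_len::2][:out_len]
    return approx, detail


def wavedec_conv(x, wavelet="db4", level=3):
    """Multi-level decomposition by repeated single-level convolution steps;
    returns [A_level, D_level, ..., D1] like a wavelet decomposition."""
    details = []
    approx = np.asarray(x, float)
    for _ in range(level):
        approx, detail = dwt_step_conv(approx, wavelet)
        details.append(detail)
    return [approx] + details[::-1]


def wavelet_features_naive(x, wavelet="db4", level=3):
    out = []
    for band in wavedec_conv(x, wavelet, level):
        n = len(band)
        mean = sum(band) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in band) / n)
        rms = math.sqrt(sum(v * v for v in band) / n)
        out.extend([mean, sd, rms])
    return out


def stft_features_naive(x, nperseg=64, n_bands=10):
    """Mean power of the lowest bins via an explicit DFT sum per frame."""
    x = np.asarray(x, float)
    hop = nperseg // 2
    n_frames = (len(x) - nperseg) // hop + 1
    window = np.hanning(nperseg)
    powers = np.zeros((n_frames, n_bands))
    for f in range(n_frames):
        frame = x[f * hop:f * hop + nperseg] * window
        for k in range(n_bands):
            re = sum(frame[t] * math.cos(-2 * math.pi * k * t / nperseg)
                     for t in range(nperseg))
            im = sum(frame[t] * math.sin(-2 * math.pi * k * t / nperseg)
                     for t in range(nperseg))
            powers[f, k] = re * re + im * im
    return powers.mean(axis=0)


def features33_naive(x):
    return np.array(stat_features_naive(x) + wavelet_features_naive(x)
                    + list(stft_features_naive(x)))
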