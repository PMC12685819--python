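"""Front-half transforms shared by both pipelines.

Column dropping, z-score standardisation (population-SD convention, the
standard-scaler default), stratified 70/15/15 splitting with the two-stage
floor convention, fixed-length windowing with overlap, per-trial label
inheritance, zero-phase Butterworth/notch filtering, and SAM 1–5 → [0, 1]
normalisation of valence/arousal/dominance ratings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .io_formats import FeatureTable, SignalRecord

__all__ = [
    "ZScoreParams",
    "SplitSpec",
    "WindowSpec",
    "FilterSpec",
    "drop_nonfeature_columns",
    "zscore_fit",
    "zscore_apply",
    "zscore_signal",
    "stratified_split",
    "segment_signal",
    "inherit_labels",
    "apply_filter",
    "normalize_vad",
    "denormalize_vad",
]


@dataclass
class ZScoreParams:
    """Per-feature standardisation parameters: z = (X − μ) / σ."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive for every feature")


@dataclass
class SplitSpec:
    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")


@dataclass
class WindowSpec:
    window_samples: int
    step_samples: int

    def __post_init__(self) -> None:
        if not (1 <= self.step_samples <= self.window_samples):
            raise ValueError("need 1 <= step_samples <= window_samples")


@dataclass
class FilterSpec:
    """Zero-phase filter description: Butterworth band-pass or IIR notch."""

    kind: str  # "butterworth_bandpass" | "notch"
    order: int = 4
    band_hz: tuple[float, float] | None = None
    center_hz: float | None = None
    q: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("butterworth_bandpass", "notch"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "butterworth_bandpass" and self.band_hz is None:
            raise ValueError("butterworth_bandpass requires band_hz")
        if self.kind == "notch" and self.center_hz is None:
            raise ValueError("notch requires center_hz")


def drop_nonfeature_columns(table: FeatureTable, names: list[str]) -> FeatureTable:
    """Remove metadata columns (subject id, condition, questionnaire labels, …)
    from a feature table, preserving the order of what remains.

    Names not present are skipped with a warning; removing every column is an
    error.
    """
    present = [n for n in names if n in table.column_names]
    absent = [n for n in names if n not in table.column_names]
    if absent:
        warnings.warn(f"columns not present, skipped: {absent}", stacklevel=2)
    keep = [i for i, n in enumerate(table.column_names) if n not in set(present)]
    if not keep:
        raise ValueError("dropping these columns would leave zero feature columns")
    return FeatureTable(
        column_names=[table.column_names[i] for i in keep],
        values=table.values[:, keep],
        labels=table.labels.copy(),
    )


def zscore_fit(data: np.ndarray) -> ZScoreParams:
    """Fit per-feature mean and population SD (divide by n). Constant features
    are rejected — they carry no information and make σ zero."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("fit data must be 2-D with at least 2 rows")
    mu = data.mean(axis=0)
    sigma = data.std(axis=0)  # population (ddof=0), standard-scaler convention
    const = np.flatnonzero(sigma == 0)
    if const.size:
        raise ValueError(f"constant feature(s) at column index {const.tolist()}")
    return ZScoreParams(mu=mu, sigma=sigma)


def zscore_apply(data: np.ndarray, params: ZScoreParams) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.shape[-1] != params.mu.shape[0]:
        raise ValueError(
            f"dimension mismatch: data has {data.shape[-1]} features, "
            f"params have {params.mu.shape[0]}"
        )
    return (data - params.mu) / params.sigma


def zscore_signal(x: np.ndarray) -> np.ndarray:
    """Per-signal standardisation (the per-trace mode used for ECG): centre one
    trace to mean 0, SD 1. A constant trace is returned centred but unscaled."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def _allocate(counts: np.ndarray, frac_taken: float, n_take: int) -> np.ndarray:
    """Largest-remainder allocation of ``n_take`` across classes proportionally
    to ``counts``."""
    ideal = counts * frac_taken
    base = np.floor(ideal).astype(int)
    base = np.minimum(base, counts)
    short = n_take - base.sum()
    if short > 0:
        order = np.argsort(-(ideal - np.floor(ideal)), kind="stable")
        for idx in order:
            if short == 0:
                break
            if base[idx] < counts[idx]:
                base[idx] += 1
                short -= 1
    elif short < 0:
        order = np.argsort(ideal - np.floor(ideal), kind="stable")
        for idx in order:
            if short == 0:
                break
            if base[idx] > 0:
                base[idx] -= 1
                short += 1
    return base


def stratified_split(
    table: FeatureTable, spec: SplitSpec
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Two-stage train/validation/test split.

    Stage 1 holds out ``floor(train_frac · n)`` rows for training; stage 2
    splits the remainder with validation taking the floor of its share and
    test the rest (so a 70/15/15 split of 135,650 rows gives
    94,955 / 20,347 / 20,348).  With ``stratified`` on, rows are allocated per
    class by largest remainder, keeping class proportions within one row per
    class per part.
    """
    n = table.n_rows
    rng = np.random.default_rng(spec.seed)
    n_train = int(np.floor(spec.train_frac * n))
    n_rest = n - n_train
    rest_val_share = spec.val_frac / (spec.val_frac + spec.test_frac)
    n_val = int(np.floor(n_rest * rest_val_share))

    if spec.stratified:
        classes, class_counts = np.unique(table.labels, return_counts=True)
        if np.any(class_counts < 3):
            small = classes[class_counts < 3]
            raise ValueError(f"class(es) {small.tolist()} too small to stratify")
        train_alloc = _allocate(class_counts, spec.train_frac, n_train)
        rest_counts = class_counts - train_alloc
        val_alloc = _allocate(rest_counts, rest_val_share, n_val)
        tr_idx, va_idx, te_idx = [], [], []
        for ci, cls in enumerate(classes):
            idx = np.flatnonzero(table.labels == cls)
            rng.shuffle(idx)
            a, b = train_alloc[ci], train_alloc[ci] + val_alloc[ci]
            tr_idx.append(idx[:a])
            va_idx.append(idx[a:b])
            te_idx.append(idx[b:])
        train_idx = np.concatenate(tr_idx)
        val_idx = np.concatenate(va_idx)
        test_idx = np.concatenate(te_idx)
    else:
        perm = rng.permutation(n)
        train_idx = perm[:n_train]
        val_idx = perm[n_train:n_train + n_val]
        test_idx = perm[n_train + n_val:]

    def take(idx: np.ndarray) -> FeatureTable:
        idx = np.sort(idx)
        return FeatureTable(
            column_names=list(table.column_names),
            values=table.values[idx],
            labels=table.labels[idx],
        )

    return take(train_idx), take(val_idx), take(test_idx)


def segment_signal(sequence: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Slice a 1-D sequence into overlapping fixed-length windows.

    Windows start at 0, S, 2S, …; the incomplete tail is dropped, giving
    ``floor((N − W) / S) + 1`` rows.
    """
    x = np.asarray(sequence, dtype=float).ravel()
    w, s = spec.window_samples, spec.step_samples
    if x.size < w:
        raise ValueError(f"sequence length {x.size} shorter than window {w}")
    n_windows = (x.size - w) // s + 1
    starts = np.arange(n_windows) * s
    return np.stack([x[st:st + w] for st in starts])


def inherit_labels(
    trial_labels: tuple[float, float, float],
    n_windows: int,
    *,
    subject_id: str | None = None,
    trial_id: int | None = None,
) -> dict[str, np.ndarray]:
    """Replicate a trial's label triple onto each of its windows, carrying
    subject/trial provenance."""
    if n_windows < 0:
        raise ValueError("n_windows must be >= 0")
    labels = np.tile(np.asarray(trial_labels, dtype=float), (n_windows, 1))
    out: dict[str, np.ndarray] = {"labels": labels}
    if subject_id is not None:
        out["subject_id"] = np.array([subject_id] * n_windows)
    if trial_id is not None:
        out["trial_id"] = np.full(n_windows, trial_id, dtype=int)
    return out


def apply_filter(record: SignalRecord, spec: FilterSpec) -> SignalRecord:
    """Zero-phase (forward–backward) filtering per channel; shape preserved."""
    nyq = record.rate_hz / 2.0
    if spec.kind == "butterworth_bandpass":
        lo, hi = spec.band_hz
        if not (0 < lo < hi < nyq):
            raise ValueError(f"band {spec.band_hz} invalid for Nyquist {nyq} Hz")
        sos = scipy.signal.butter(spec.order, [lo, hi], btype="bandpass",
                                  fs=record.rate_hz, output="sos")
        filt = np.stack([scipy.signal.sosfiltfilt(sos, ch) for ch in record.data])
    else:
        if not (0 < spec.center_hz < nyq):
            raise ValueError(f"notch centre {spec.center_hz} invalid for Nyquist {nyq} Hz")
        b, a = scipy.signal.iirnotch(spec.center_hz, spec.q, fs=record.rate_hz)
        filt = np.stack([scipy.signal.filtfilt(b, a, ch) for ch in record.data])
    return SignalRecord(
        channel_names=list(record.channel_names),
        data=filt,
        rate_hz=record.rate_hz,
        start_offset_s=record.start_offset_s,
    )


def normalize_vad(raw) -> np.ndarray:
    """Map SAM ratings on the 1–5 scale to [0, 1]: (x − 1) / 4."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 1.0) or np.any(raw > 5.0):
        raise ValueError(f"VAD components must lie in [1, 5], got {raw}")
    return (raw - 1.0) / 4.0


def denormalize_vad(norm) -> np.ndarray:
    """Inverse of :func:`normalize_vad`: x·4 + 1 back onto the 1–5 scale."""
    norm = np.asarray(norm, dtype=float)
    return norm * 4.0 + 1.0
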