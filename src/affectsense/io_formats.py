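"""Readers and writers for the formats the framework touches.

Four surfaces:

* EDF/EDF+ multichannel recordings (:class:`SignalRecord`) — read through
  :mod:`mne`, written by a minimal built-in EDF writer (16-bit continuous
  signals, one data record per second).
* DREAMER-style nested MAT v5 containers (:class:`TrialSet`) — per-subject,
  per-trial ECG plus SAM valence/arousal/dominance ratings on a 1–5 scale.
* CSV feature tables (:class:`FeatureTable`) — rows × features with one
  designated label column.
* Checkpoint archives (:class:`CheckpointBundle`) — named weight arrays plus a
  structured architecture descriptor, the transfer-learning hand-off format.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import scipy.io

__all__ = [
    "SignalRecord",
    "Trial",
    "TrialSet",
    "FeatureTable",
    "CheckpointBundle",
    "read_edf",
    "write_edf",
    "read_dreamer_mat",
    "write_dreamer_mat",
    "read_csv_table",
    "write_csv_table",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class SignalRecord:
    """A multichannel uniformly sampled recording.

    ``data`` is channels × samples; every channel shares ``rate_hz``.
    """

    channel_names: list[str]
    data: np.ndarray
    rate_hz: float
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class Trial:
    """One stimulus presentation: an ECG trace and its SAM VAD rating."""

    subject_id: str
    trial_id: int
    ecg: np.ndarray
    vad_raw: tuple[float, float, float]  # (valence, arousal, dominance), 1-5

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float).ravel()
        if self.ecg.size == 0:
            raise ValueError("ecg must be non-empty")
        v = np.asarray(self.vad_raw, dtype=float)
        if v.shape != (3,):
            raise ValueError("vad_raw must have exactly 3 components")
        if np.any(v < 1.0) or np.any(v > 5.0):
            raise ValueError(f"vad_raw components must lie in [1, 5], got {tuple(v)}")
        self.vad_raw = tuple(v)


@dataclass
class TrialSet:
    """A flat collection of trials across subjects."""

    trials: list[Trial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]


@dataclass
class FeatureTable:
    """A labelled feature matrix: rows × named columns plus an integer label per row."""

    column_names: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names length must equal column count")
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("labels length must equal row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df[label_column] = self.labels
        return df


@dataclass
class CheckpointBundle:
    """Architecture descriptor + ordered named weight arrays + run metadata.

    The descriptor is a JSON-serialisable structure listing layer kinds, sizes
    and order; every weight name must resolve against it.
    """

    architecture: dict[str, Any]
    weights: dict[str, np.ndarray]
    metadata: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        declared = _declared_weight_shapes(self.architecture)
        for name, arr in self.weights.items():
            if name not in declared:
                raise ValueError(f"weight {name!r} not declared in architecture descriptor")
            if tuple(arr.shape) != tuple(declared[name]):
                raise ValueError(
                    f"weight {name!r} has shape {tuple(arr.shape)}, descriptor "
                    f"declares {tuple(declared[name])}"
                )
        missing = set(declared) - set(self.weights)
        if missing:
            raise ValueError(f"weights missing for declared names: {sorted(missing)}")


def _declared_weight_shapes(architecture: dict[str, Any]) -> dict[str, tuple]:
    shapes: dict[str, tuple] = {}
    for layer in architecture.get("layers", []):
        for wname, shape in layer.get("weights", {}).items():
            shapes[f"{layer['name']}/{wname}"] = tuple(shape)
    return shapes


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_header_fields(path: Path) -> tuple[int, float, list[int], list[str], str]:
    """Peek the fixed-width EDF header: (n_records, record_dur, samples-per-record,
    labels, starttime).  Used for rate validation only; signal decoding is mne's."""
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise ValueError(f"{path}: corrupt EDF header") from exc
        starttime = head[176:184].decode("ascii", errors="replace")
        sig = f.read(ns * 256)
        if len(sig) < ns * 256:
            raise ValueError(f"{path}: truncated EDF signal headers")
        labels = [sig[16 * i: 16 * (i + 1)].decode("ascii").strip() for i in range(ns)]
        off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
        samples = []
        for i in range(ns):
            fld = sig[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip()
            samples.append(int(fld))
    return n_records, record_dur, samples, labels, starttime


def read_edf(path: str | Path, *, resample: bool = False) -> SignalRecord:
    """Read an EDF/EDF+ file into a :class:`SignalRecord`.

    Channels recorded at different rates are an error unless ``resample=True``,
    in which case every channel is brought to the highest rate present.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    n_records, record_dur, samples_per_record, labels, starttime = _edf_header_fields(path)
    rates = {int(round(s / record_dur)) for s in samples_per_record}
    if len(rates) > 1 and not resample:
        raise ValueError(
            f"{path}: channels have mixed sampling rates {sorted(rates)}; "
            "pass resample=True to bring them to a common rate"
        )
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    data = raw.get_data()
    try:
        hh, mm, ss = (int(x) for x in starttime.replace(":", ".").split("."))
        offset = hh * 3600.0 + mm * 60.0 + ss
    except ValueError:
        offset = 0.0
    return SignalRecord(
        channel_names=list(raw.ch_names),
        data=data,
        rate_hz=float(raw.info["sfreq"]),
        start_offset_s=offset,
    )


def write_edf(record: SignalRecord, path: str | Path) -> Path:
    """Write a :class:`SignalRecord` as a 16-bit EDF file.

    One data record per second; requires an integer sampling rate and a whole
    number of seconds of data.  Values are scaled to each channel's physical
    range, so the round-trip is exact to 16-bit quantisation.
    """
    path = Path(path)
    rate = record.rate_hz
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    rate = int(round(rate))
    n = record.n_samples
    if n % rate != 0:
        raise ValueError(
            f"EDF writer requires whole seconds of data; {n} samples at {rate} Hz"
        )
    n_records = n // rate
    ns = record.n_channels

    offset = int(round(record.start_offset_s)) % 86400
    hh, rem = divmod(offset, 3600)
    mm, ss = divmod(rem, 60)

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate 01-JAN-2000 X X X", 80),
        pad("01.01.00", 8),
        pad(f"{hh:02d}.{mm:02d}.{ss:02d}", 8),
        pad(str(256 * (1 + ns)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(ns), 4),
    ])

    phys_min, phys_max, scaled = [], [], []
    dig_min, dig_max = -32768, 32767
    for ch in record.data:
        lo, hi = float(np.min(ch)), float(np.max(ch))
        if hi - lo < 1e-12:  # constant channel: widen to a degenerate-safe range
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        gain = (dig_max - dig_min) / (hi - lo)
        dig = np.round((ch - lo) * gain + dig_min).astype("<i2")
        scaled.append(dig)

    def fmt8(x: float) -> str:
        s = f"{x:.6g}"
        return s if len(s) <= 8 else f"{x:.2e}"

    sig_header = b"".join(
        [pad(name, 16) for name in record.channel_names]
        + [pad("", 80)] * ns
        + [pad("", 8)] * ns  # physical dimension left blank: dimensionless
        + [pad(fmt8(v), 8) for v in phys_min]
        + [pad(fmt8(v), 8) for v in phys_max]
        + [pad(str(dig_min), 8)] * ns
        + [pad(str(dig_max), 8)] * ns
        + [pad("", 80)] * ns
        + [pad(str(rate), 8)] * ns
        + [pad("", 32)] * ns
    )

    with open(path, "wb") as f:
        f.write(header)
        f.write(sig_header)
        for r in range(n_records):
            for ch in scaled:
                f.write(ch[r * rate:(r + 1) * rate].tobytes())
    return path


# ---------------------------------------------------------------------------
# DREAMER-style MAT v5
# ---------------------------------------------------------------------------

def _unwrap(obj: Any) -> Any:
    """Iteratively unwrap the nested 1×1 object arrays scipy.io produces for
    MATLAB cell/struct nesting."""
    while isinstance(obj, np.ndarray) and obj.dtype == object and obj.size == 1:
        obj = obj.item()
    return obj


def _struct_field(struct_arr: Any, name: str, context: str) -> Any:
    struct_arr = _unwrap(struct_arr)
    is_struct = (isinstance(struct_arr, (np.ndarray, np.void))
                 and struct_arr.dtype.names)
    if not is_struct:
        raise ValueError(f"expected a MATLAB struct at {context}")
    if name not in struct_arr.dtype.names:
        raise ValueError(f"missing field {context}/{name}")
    return struct_arr[name]


def read_dreamer_mat(path: str | Path, *, lead: str = "first") -> TrialSet:
    """Read a DREAMER-layout MAT v5 file into a flat :class:`TrialSet`.

    The container holds ``DREAMER.Data`` — one struct per subject with
    ``ECG.stimuli`` (a cell array of samples × 2 lead matrices) and per-trial
    ``ScoreValence`` / ``ScoreArousal`` / ``ScoreDominance`` vectors on the SAM
    1–5 scale.  Two-lead ECG is reduced to one channel: ``lead='first'`` keeps
    lead I, ``lead='mean'`` averages both.
    """
    if lead not in ("first", "mean"):
        raise ValueError("lead must be 'first' or 'mean'")
    mat = scipy.io.loadmat(str(path), simplify_cells=False)
    top = None
    for key, val in mat.items():
        if not key.startswith("__"):
            top = _unwrap(val)
            break
    if top is None:
        raise ValueError(f"{path}: no MATLAB variable found")
    data = _unwrap(_struct_field(top, "Data", "DREAMER"))
    if isinstance(data, (np.void,)) or (
            isinstance(data, np.ndarray) and data.dtype.names):
        subjects = [data]  # single-subject container unwraps to the struct itself
    else:
        subjects = np.atleast_1d(np.asarray(data, dtype=object)).ravel()

    trials: list[Trial] = []
    for si, subj in enumerate(subjects):
        subj = _unwrap(subj)
        ecg = _struct_field(subj, "ECG", f"Data[{si}]")
        stimuli = _unwrap(_struct_field(ecg, "stimuli", f"Data[{si}]/ECG"))
        stim_list = np.atleast_1d(np.asarray(stimuli, dtype=object)).ravel()
        scores = {}
        for fld in ("ScoreValence", "ScoreArousal", "ScoreDominance"):
            vec = np.asarray(_unwrap(_struct_field(subj, fld, f"Data[{si}]")), dtype=float).ravel()
            scores[fld] = vec
        for ti, stim in enumerate(stim_list):
            arr = np.asarray(_unwrap(stim))
            if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
                raise ValueError(
                    f"Data[{si}]/ECG/stimuli[{ti}]: non-numeric leaf after unwrapping"
                )
            arr = np.atleast_2d(arr.astype(float))
            if arr.shape[0] < arr.shape[1]:
                arr = arr.T  # samples x leads
            trace = arr[:, 0] if (lead == "first" or arr.shape[1] == 1) else arr.mean(axis=1)
            vad = (
                float(scores["ScoreValence"][ti]),
                float(scores["ScoreArousal"][ti]),
                float(scores["ScoreDominance"][ti]),
            )
            trials.append(Trial(subject_id=f"S{si:02d}", trial_id=ti, ecg=trace, vad_raw=vad))
    return TrialSet(trials=trials)


def write_dreamer_mat(trial_set: TrialSet, path: str | Path) -> Path:
    """Write a :class:`TrialSet` in the DREAMER nested MAT v5 layout.

    ECG traces are stored as samples × 2 matrices (both leads identical) to
    mirror the two-lead layout of the real container.
    """
    by_subject: dict[str, list[Trial]] = {}
    for tr in trial_set:
        by_subject.setdefault(tr.subject_id, []).append(tr)

    subj_structs = []
    for sid in sorted(by_subject):
        trs = sorted(by_subject[sid], key=lambda t: t.trial_id)
        stimuli = np.empty((len(trs), 1), dtype=object)
        for i, tr in enumerate(trs):
            stimuli[i, 0] = np.column_stack([tr.ecg, tr.ecg])
        ecg_struct = np.array([[(stimuli,)]], dtype=[("stimuli", object)])
        val = np.array([[t.vad_raw[0]] for t in trs], dtype=float)
        aro = np.array([[t.vad_raw[1]] for t in trs], dtype=float)
        dom = np.array([[t.vad_raw[2]] for t in trs], dtype=float)
        subj_structs.append((ecg_struct, val, aro, dom))

    data = np.empty((1, len(subj_structs)), dtype=object)
    dt = [("ECG", object), ("ScoreValence", object), ("ScoreArousal", object),
          ("ScoreDominance", object)]
    for i, tup in enumerate(subj_structs):
        data[0, i] = np.array([[tup]], dtype=dt)
    dreamer = np.array([[(data,)]], dtype=[("Data", object)])
    scipy.io.savemat(str(path), {"DREAMER": dreamer})
    return Path(path)


# ---------------------------------------------------------------------------
# CSV feature tables
# ---------------------------------------------------------------------------

def read_csv_table(path: str | Path, *, label_column: str = "label") -> FeatureTable:
    """Read a headered CSV into a :class:`FeatureTable`; ``label_column`` becomes
    the integer label vector."""
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"{path}: missing label column {label_column!r}")
    feats = df.drop(columns=[label_column])
    for col in feats.columns:
        bad = pd.to_numeric(feats[col], errors="coerce").isna() & feats[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{path}: non-numeric feature cell at row {row}, column {col!r}"
            )
        if feats[col].isna().any():
            row = int(np.argmax(feats[col].isna().to_numpy()))
            raise ValueError(f"{path}: missing value at row {row}, column {col!r}")
    return FeatureTable(
        column_names=list(feats.columns),
        values=feats.to_numpy(dtype=float),
        labels=df[label_column].to_numpy(),
    )


def write_csv_table(table: FeatureTable, path: str | Path,
                    *, label_column: str = "label") -> Path:
    """Write a :class:`FeatureTable` as CSV; 17 significant digits make the
    float round-trip exact."""
    df = table.to_frame(label_column=label_column)
    df.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(bundle: CheckpointBundle, path: str | Path) -> Path:
    """Persist a checkpoint as a single npz archive: weight arrays plus a JSON
    descriptor and metadata."""
    bundle.validate()
    payload: dict[str, np.ndarray] = {
        f"weight::{name}": arr for name, arr in bundle.weights.items()
    }
    payload["__descriptor__"] = np.array(
        json.dumps({"format_version": CHECKPOINT_FORMAT_VERSION,
                    "architecture": bundle.architecture})
    )
    payload["__metadata__"] = np.array(json.dumps(bundle.metadata))
    np.savez(path, **payload)
    p = Path(path)
    return p if p.suffix == ".npz" else p.with_suffix(p.suffix + ".npz")


def load_checkpoint(path: str | Path) -> CheckpointBundle:
    """Load and shape-validate a checkpoint archive written by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as npz:
        desc = json.loads(str(npz["__descriptor__"]))
        if desc.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format version {desc.get('format_version')}"
            )
        metadata = json.loads(str(npz["__metadata__"]))
        weights = {
            key[len("weight::"):]: npz[key]
            for key in npz.files if key.startswith("weight::")
        }
    bundle = CheckpointBundle(architecture=desc["architecture"], weights=weights,
                              metadata=metadata)
    bundle.validate()
    return bundle
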