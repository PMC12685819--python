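"""End-to-end study pipelines wiring the modules together.

Three runnable flows, all fully seeded and returning plain dictionaries of
computed metrics:

* :func:`run_stress_pipeline` — synthetic HRV-style table → z-score →
  stratified 70/15/15 split → 1-D CNN with class weights → classification
  report + checkpoint bundle;
* :func:`run_activity_pipeline` — synthetic imbalanced activity windows →
  per-window standardisation → transfer-learned CNN (backbone from the
  stress checkpoint, new 4-class head, reduced learning rate) → report;
* :func:`run_vad_pipeline` — synthetic DREAMER-style trials → per-signal
  z-score → 5 s windows with 50% overlap → label inheritance → 33-feature
  extraction → segment-level split → Temporal Conformer with smooth-L1 →
  regression report + rule-based diagnostics.
"""

from __future__ import annotations

import numpy as np

from .diagnostics import diagnose
from .evaluation import (classification_report, confusion_matrix,
                         regression_metrics)
from .features import extract_features
from .io_formats import CheckpointBundle
from .models import (Cnn1dSpec, ConformerSpec, Model, build_cnn,
                     build_conformer, compute_class_weights, fine_tune,
                     train_classifier, train_vad_regressor)
from .nn import TrainConfig
from .preprocessing import (SplitSpec, WindowSpec, normalize_vad,
                            stratified_split, zscore_apply, zscore_fit,
                            zscore_signal, segment_signal)
from .synthetic import (StressTableConfig, VadLatentMap, gen_activity_windows,
                        gen_dreamer_like, gen_stress_table)

__all__ = [
    "run_stress_pipeline",
    "run_activity_pipeline",
    "run_vad_pipeline",
    "build_vad_dataset",
]


def _report_dict(report) -> dict:
    return {
        "accuracy": report.accuracy,
        "macro_precision": report.macro_precision,
        "macro_recall": report.macro_recall,
        "macro_f1": report.macro_f1,
        "weighted_precision": report.weighted_precision,
        "weighted_recall": report.weighted_recall,
        "weighted_f1": report.weighted_f1,
    }


def run_stress_pipeline(
    seed: int = 0,
    *,
    n_rows: int = 3000,
    effect_size: float = 3.0,
    max_epochs: int = 15,
    loss: str = "sparse_ce",
) -> dict:
    """Train the stress classifier on a synthetic separable table; returns
    metrics, history and the checkpoint bundle for transfer learning."""
    table = gen_stress_table(StressTableConfig(
        n_rows=n_rows, effect_size=effect_size, seed=seed))
    train, val, test = stratified_split(table, SplitSpec(seed=seed))
    scaler = zscore_fit(train.values)
    x_tr, x_va, x_te = (zscore_apply(part.values, scaler)
                        for part in (train, val, test))
    model = build_cnn(Cnn1dSpec(input_len=table.n_features, n_classes=3),
                      seed=seed)
    config = TrainConfig(lr=1e-3, max_epochs=max_epochs, seed=seed, loss=loss,
                         class_weights=compute_class_weights(train.labels))
    model, history = train_classifier(model, (x_tr, train.labels),
                                      (x_va, val.labels), config)
    pred = model.predict_batched(x_te).argmax(axis=-1)
    report = classification_report(confusion_matrix(test.labels, pred, 3))
    bundle = model.to_bundle({"source": "synthetic-stress", "seed": seed,
                              "epochs": len(history.train_loss)})
    return {"model": model, "bundle": bundle, "history": history,
            "report": report, "metrics": _report_dict(report)}


def _standardize_windows(w: np.ndarray) -> np.ndarray:
    mu = w.mean(axis=1, keepdims=True)
    sd = w.std(axis=1, keepdims=True)
    return (w - mu) / np.where(sd > 0, sd, 1.0)


def run_activity_pipeline(
    pretrained: CheckpointBundle,
    seed: int = 0,
    *,
    n_total: int = 2000,
    window_samples: int = 250,
    effect_size: float = 2.0,
    max_epochs: int = 12,
    freeze_backbone: bool = False,
) -> dict:
    """Fine-tune the pretrained stress backbone on imbalanced synthetic
    activity windows (single channel) and report test metrics."""
    x, y = gen_activity_windows(n_total, window_samples=window_samples,
                                n_channels=1, effect_size=effect_size,
                                seed=seed)
    x = _standardize_windows(x)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    n_tr = int(0.7 * len(y))
    n_va = int(0.15 * len(y))
    i_tr, i_va, i_te = (idx[:n_tr], idx[n_tr:n_tr + n_va], idx[n_tr + n_va:])
    config = TrainConfig(lr=1e-4, max_epochs=max_epochs, seed=seed,
                         class_weights=compute_class_weights(y[i_tr]))
    model, history = fine_tune(
        pretrained, (x[i_tr], y[i_tr]), (x[i_va], y[i_va]), config,
        n_classes=4, input_len=window_samples, seed=seed,
        freeze_backbone=freeze_backbone)
    pred = model.predict_batched(x[i_te]).argmax(axis=-1)
    report = classification_report(confusion_matrix(y[i_te], pred, 4))
    return {"model": model, "history": history, "report": report,
            "metrics": _report_dict(report)}


def build_vad_dataset(
    seed: int = 0,
    *,
    n_subjects: int = 16,
    trials_per_subject: int = 12,
    trial_duration_s: float = 61.25,
    rate_hz: float = 128.0,
    window_s: float = 5.0,
    overlap: float = 0.5,
    vad_map: VadLatentMap | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate trials, z-score each ECG trace, window it, inherit labels and
    extract the 33 features.  Returns (features, normalised VAD targets,
    trial index per window)."""
    trials = gen_dreamer_like(n_subjects, trials_per_subject, trial_duration_s,
                              vad_map=vad_map, seed=seed, rate_hz=rate_hz)
    window = int(round(window_s * rate_hz))
    spec = WindowSpec(window, int(round(window * (1.0 - overlap))))
    feats, targets, groups = [], [], []
    for gi, trial in enumerate(trials):
        windows = segment_signal(zscore_signal(trial.ecg), spec)
        feats.append(extract_features(windows))
        targets.append(np.tile(normalize_vad(trial.vad_raw), (len(windows), 1)))
        groups.append(np.full(len(windows), gi))
    return np.concatenate(feats), np.concatenate(targets), np.concatenate(groups)


def run_vad_pipeline(
    seed: int = 0,
    *,
    n_subjects: int = 16,
    trials_per_subject: int = 12,
    max_epochs: int = 40,
    split_by_trial: bool = False,
    diagnose_k: int = 4,
) -> dict:
    """Full valence/arousal/dominance flow on synthetic latent-driven trials.

    Splitting is at the segment level by default (the study's protocol:
    windows inherit their trial's labels and are shuffled before splitting);
    ``split_by_trial`` switches to the stricter grouped split in which no
    trial spans train and test.
    """
    x, y, groups = build_vad_dataset(
        seed=seed, n_subjects=n_subjects, trials_per_subject=trials_per_subject)
    rng = np.random.default_rng(seed)
    if split_by_trial:
        trial_ids = rng.permutation(groups.max() + 1)
        n_tr = int(0.7 * len(trial_ids))
        n_va = int(0.15 * len(trial_ids))
        m_tr = np.isin(groups, trial_ids[:n_tr])
        m_va = np.isin(groups, trial_ids[n_tr:n_tr + n_va])
        m_te = ~(m_tr | m_va)
    else:
        idx = rng.permutation(len(x))
        n_tr = int(0.7 * len(x))
        n_va = int(0.15 * len(x))
        m_tr = np.zeros(len(x), bool)
        m_va = np.zeros(len(x), bool)
        m_tr[idx[:n_tr]] = True
        m_va[idx[n_tr:n_tr + n_va]] = True
        m_te = ~(m_tr | m_va)
    scaler = zscore_fit(x[m_tr])
    x_tr, x_va, x_te = (zscore_apply(x[m], scaler) for m in (m_tr, m_va, m_te))
    model = build_conformer(ConformerSpec(), seed=seed)
    config = TrainConfig(lr=1e-3, loss="smooth_l1", max_epochs=max_epochs,
                         batch_size=64, seed=seed)
    model, history = train_vad_regressor(model, (x_tr, y[m_tr]),
                                         (x_va, y[m_va]), config)
    pred = model.predict_batched(x_te)
    report = regression_metrics(pred, y[m_te])
    # diagnostics expect (arousal, valence, dominance) order in [0, 1]
    avd = np.clip(pred[:, [1, 0, 2]], 0.0, 1.0)
    rows = diagnose(avd, k=diagnose_k, seed=seed)
    return {
        "model": model, "history": history, "report": report,
        "diagnostics": rows,
        "metrics": {
            "mae": report.mae, "rmse": report.rmse, "r2": report.r2,
            "r2_per_dim": report.r2_per_dim.tolist(),
            "rounded_accuracy_all": report.rounded_accuracy_all,
            "rounded_accuracy_per_dim": report.rounded_accuracy_per_dim.tolist(),
            "smooth_l1": report.smooth_l1,
        },
    }
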