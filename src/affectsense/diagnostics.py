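"""Rule-based interpretation of predicted valence/arousal/dominance.

Maps normalised VAD triples to six interpretable affective states, computes
two scalar indices (Fatigue Index = 1 − arousal; Motion Quality =
valence · dominance), and profiles the predicted VAD space with k-means
(k = 4 by default).

The state rules follow a fixed precedence — Happy/Excited, Stressed, Relaxed,
Fatigued, Passive, Neutral — with thresholds on arousal and valence, and
dominance consulted only by the passivity rule.  The numeric thresholds are a
reconstruction fitted to the published worked examples (the rule structure is
published, the numbers are not); any consistent alternative can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .evaluation import round_half_away

__all__ = [
    "RuleThresholds",
    "DiagnosticRow",
    "STATES",
    "rule_based_state",
    "fatigue_index",
    "motion_quality",
    "cluster_states",
    "diagnose",
    "diagnostics_frame",
]

STATES = ("Happy/Excited", "Stressed", "Relaxed", "Fatigued", "Passive", "Neutral")


@dataclass
class RuleThresholds:
    """Arousal/valence thresholds per state; ``*_min``/``*_max`` comparisons are
    inclusive, ``*_below`` comparisons strict."""

    happy_arousal_min: float = 0.6
    happy_valence_min: float = 0.7
    stressed_arousal_min: float = 0.6
    stressed_valence_max: float = 0.4
    relaxed_arousal_max: float = 0.3
    relaxed_valence_min: float = 0.7
    fatigued_arousal_max: float = 0.3
    fatigued_valence_max: float = 0.3
    passive_arousal_below: float = 0.4
    passive_dominance_below: float = 0.5

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"threshold {name} must lie in [0, 1]")


@dataclass
class DiagnosticRow:
    arousal: float
    valence: float
    dominance: float
    state: str
    cluster: int
    fatigue_index: float
    motion_quality: float


def _check_unit(name: str, *values: float) -> None:
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} component {v} outside [0, 1]")


def rule_based_state(vad, thresholds: RuleThresholds | None = None) -> str:
    """Classify one normalised (arousal, valence, dominance) triple.

    The first matching rule in precedence order wins; anything unmatched is
    Neutral.
    """
    th = thresholds or RuleThresholds()
    arousal, valence, dominance = (float(x) for x in np.asarray(vad, dtype=float))
    _check_unit("vad", arousal, valence, dominance)
    if arousal >= th.happy_arousal_min and valence >= th.happy_valence_min:
        return "Happy/Excited"
    if arousal >= th.stressed_arousal_min and valence <= th.stressed_valence_max:
        return "Stressed"
    if arousal <= th.relaxed_arousal_max and valence >= th.relaxed_valence_min:
        return "Relaxed"
    if arousal <= th.fatigued_arousal_max and valence <= th.fatigued_valence_max:
        return "Fatigued"
    if arousal < th.passive_arousal_below and dominance < th.passive_dominance_below:
        return "Passive"
    return "Neutral"


def fatigue_index(arousal: float) -> float:
    """Inverse of the normalised arousal score: 1 − arousal."""
    _check_unit("arousal", float(arousal))
    return 1.0 - float(arousal)


def motion_quality(valence: float, dominance: float) -> float:
    """Product of valence and dominance — engagement/assertiveness proxy."""
    _check_unit("valence/dominance", float(valence), float(dominance))
    return float(valence) * float(dominance)


def cluster_states(vad_matrix, k: int = 4, seed: int = 0) -> np.ndarray:
    """k-means profiling of the VAD space (k-means++ seeding, 10 restarts)."""
    x = np.atleast_2d(np.asarray(vad_matrix, dtype=float))
    if x.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {x.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(x)


def diagnose(vad_matrix, thresholds: RuleThresholds | None = None,
             k: int = 4, seed: int = 0) -> list[DiagnosticRow]:
    """Full diagnostic pass over an n×3 matrix of (arousal, valence, dominance).

    Values are kept at full precision internally; use
    :func:`diagnostics_frame` for the 2-decimal display table.
    """
    x = np.atleast_2d(np.asarray(vad_matrix, dtype=float))
    if x.size == 0:
        return []
    if x.shape[1] != 3:
        raise ValueError("vad_matrix must have 3 columns (arousal, valence, dominance)")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("vad values must lie in [0, 1]")
    clusters = cluster_states(x, k=k, seed=seed) if x.shape[0] >= k else np.zeros(len(x), int)
    rows = []
    for (a, v, d), c in zip(x, clusters):
        rows.append(DiagnosticRow(
            arousal=a, valence=v, dominance=d,
            state=rule_based_state((a, v, d), thresholds),
            cluster=int(c),
            fatigue_index=fatigue_index(a),
            motion_quality=motion_quality(v, d),
        ))
    return rows


def diagnostics_frame(rows: list[DiagnosticRow]) -> pd.DataFrame:
    """Display table mirroring the diagnostic-output layout, rounded to
    2 decimals (half away from zero)."""
    return pd.DataFrame({
        "Arousal": [float(round_half_away(r.arousal, 2)) for r in rows],
        "Valence": [float(round_half_away(r.valence, 2)) for r in rows],
        "Dominance": [float(round_half_away(r.dominance, 2)) for r in rows],
        "Rule-based state": [r.state for r in rows],
        "Cluster": [r.cluster for r in rows],
        "Fatigue index": [float(round_half_away(r.fatigue_index, 2)) for r in rows],
        "Motion quality": [float(round_half_away(r.motion_quality, 2)) for r in rows],
    })
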