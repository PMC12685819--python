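"""Synthetic stand-ins for the three study datasets.

Three generators, all bit-reproducible under a fixed seed:

* :func:`gen_stress_table` — a 62-feature, 3-class imbalanced HRV-style table
  (class-conditional Gaussians, mean-shifted on half the features);
* :func:`gen_ecg` / :func:`gen_dreamer_like` — 128 Hz ECG traces built from
  Gaussian R-wave pulses with controllable heart rate, RR variability and
  noise, whose latent parameters deterministically set SAM-scale
  valence/arousal/dominance labels through an affine map;
* :func:`gen_activity_windows` — imbalanced 4-class multichannel windows with
  a class-specific dominant oscillation.

None of these aim at physiological realism (no PQRST morphology, no real
inter-subject structure); they exist so every downstream stage is trainable
and testable without the real recordings, with known recoverable structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import FeatureTable, Trial, TrialSet

__all__ = [
    "StressTableConfig",
    "EcgConfig",
    "VadLatentMap",
    "gen_stress_table",
    "gen_ecg",
    "gen_dreamer_like",
    "gen_activity_windows",
    "ACTIVITY_PROPORTIONS",
]

# imbalance profile of the four retained activity classes
# (run, walk_after, baseline, walk_before_downstairs)
ACTIVITY_PROPORTIONS = (12137 / 13936, 969 / 13936, 699 / 13936, 131 / 13936)


@dataclass
class StressTableConfig:
    n_rows: int = 135_650
    n_features: int = 62
    class_proportions: tuple[float, float, float] = (0.5281, 0.1700, 0.3019)
    effect_size: float = 1.0  # between-class mean shift, within-class SD units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")


@dataclass
class EcgConfig:
    """Synthetic ECG parameters.

    The waveform is a PQRST-like pulse train: a narrow R wave (unit
    amplitude), a small P wave before it and a broader T wave after it, all
    Gaussian-shaped.  Two physiological couplings make the latent parameters
    observable in short windows: beat amplitude is modulated by the
    beat-to-beat RR deviation (respiratory sinus arrhythmia modulates both
    timing and amplitude), and a respiratory baseline component at 0.25 Hz
    has depth proportional to ``rr_sd_s`` (the shared vagal/respiratory
    driver behind RR variability).
    """

    duration_s: float = 10.0
    rate_hz: float = 128.0
    heart_rate_bpm: float = 70.0
    rr_sd_s: float = 0.05
    noise_sd: float = 0.1
    seed: int = 0
    # morphology (amplitudes relative to the R wave; widths are Gaussian σ, s)
    p_amp: float = 0.15
    p_width_s: float = 0.04
    p_lead_s: float = 0.15
    t_amp: float = 0.50
    t_width_s: float = 0.06
    t_lag_s: float = 0.30
    r_width_s: float = 0.02
    wander_amp: float = 0.1
    wander_hz: float = 0.2
    resp_hz: float = 0.25
    resp_coupling: float = 2.5  # respiratory baseline amplitude per unit rr_sd_s
    amp_coupling: float = 1.0   # beat-amplitude modulation per relative RR deviation

    def __post_init__(self) -> None:
        if not (20.0 < self.heart_rate_bpm < 240.0):
            raise ValueError("heart_rate_bpm must lie in (20, 240)")
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("rate_hz and duration_s must be positive")
        if self.rr_sd_s < 0 or self.noise_sd < 0:
            raise ValueError("rr_sd_s and noise_sd must be non-negative")


# latent ranges the DREAMER-like generator draws from (uniform); chosen on
# physiological grounds: resting-to-aroused heart rates, the realistic SDNN
# range, and mild-to-heavy measurement noise relative to unit R-wave amplitude
HR_RANGE = (55.0, 110.0)
RR_SD_RANGE = (0.02, 0.12)
NOISE_SD_RANGE = (0.05, 0.40)


@dataclass
class VadLatentMap:
    """Affine map from ECG latents to SAM-scale labels, clipped to [1, 5].

    Defaults give each output an independent recoverable signal: arousal rises
    with heart rate, valence falls with noise, dominance falls with RR
    variability.
    """

    hr_range: tuple[float, float] = HR_RANGE
    rr_sd_range: tuple[float, float] = RR_SD_RANGE
    noise_sd_range: tuple[float, float] = NOISE_SD_RANGE
    label_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.label_jitter_sd < 0:
            raise ValueError("label_jitter_sd must be non-negative")

    def __call__(self, heart_rate_bpm: float, rr_sd_s: float,
                 noise_sd: float) -> tuple[float, float, float]:
        """Return (valence, arousal, dominance) on the 1–5 scale, without jitter."""
        def affine(x, lo, hi, rising):
            t = (x - lo) / (hi - lo)
            if not rising:
                t = 1.0 - t
            return float(np.clip(1.0 + 4.0 * t, 1.0, 5.0))

        arousal = affine(heart_rate_bpm, *self.hr_range, rising=True)
        valence = affine(noise_sd, *self.noise_sd_range, rising=False)
        dominance = affine(rr_sd_s, *self.rr_sd_range, rising=False)
        return valence, arousal, dominance


def _class_counts(n_total: int, proportions: np.ndarray) -> np.ndarray:
    """Round class counts to proportions; any remainder goes to the largest class."""
    counts = np.rint(np.asarray(proportions) * n_total).astype(int)
    counts[np.argmax(proportions)] += n_total - counts.sum()
    return counts


def gen_stress_table(config: StressTableConfig) -> FeatureTable:
    """Class-conditionally Gaussian feature table with 3 imbalanced classes.

    Each class's mean is shifted by ``effect_size`` (in within-class SD units)
    on a seeded random subset of half the features; rows are shuffled.
    """
    rng = np.random.default_rng(config.seed)
    counts = _class_counts(config.n_rows, np.asarray(config.class_proportions))
    k_shift = config.n_features // 2
    blocks, labels = [], []
    for c, n_c in enumerate(counts):
        shift = np.zeros(config.n_features)
        cols = rng.choice(config.n_features, size=k_shift, replace=False)
        # alternate shift sign across chosen columns so classes separate in
        # several directions rather than along one diagonal
        shift[cols] = config.effect_size * np.where(np.arange(k_shift) % 2 == 0, 1.0, -1.0)
        blocks.append(rng.standard_normal((n_c, config.n_features)) + shift)
        labels.append(np.full(n_c, c, dtype=int))
    values = np.concatenate(blocks)
    y = np.concatenate(labels)
    perm = rng.permutation(config.n_rows)
    return FeatureTable(
        column_names=[f"hrv_feat_{i:02d}" for i in range(config.n_features)],
        values=values[perm],
        labels=y[perm],
    )


def gen_ecg(config: EcgConfig) -> np.ndarray:
    """Synthetic single-lead ECG (see :class:`EcgConfig` for the model).

    The first R peak sits at 0.5 s; subsequent intervals are
    Normal(60/heart_rate, rr_sd) truncated positive by redraw.  Deterministic
    under seed.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.rate_hz))
    t = np.arange(n) / config.rate_hz
    mean_rr = 60.0 / config.heart_rate_bpm

    peaks: list[float] = []
    rrs: list[float] = []
    t_peak = 0.5
    while t_peak < config.duration_s:
        peaks.append(t_peak)
        if config.rr_sd_s == 0:
            rr = mean_rr
        else:
            rr = rng.normal(mean_rr, config.rr_sd_s)
            while rr <= 0:  # truncate positive by redraw
                rr = rng.normal(mean_rr, config.rr_sd_s)
        rrs.append(rr)
        t_peak += rr

    sig = np.zeros(n)
    for tp, rr in zip(peaks, rrs):
        amp = max(0.3, 1.0 + config.amp_coupling * (rr - mean_rr) / mean_rr)
        sig += amp * np.exp(-0.5 * ((t - tp) / config.r_width_s) ** 2)
        sig += config.p_amp * np.exp(
            -0.5 * ((t - tp + config.p_lead_s) / config.p_width_s) ** 2)
        sig += amp * config.t_amp * np.exp(
            -0.5 * ((t - tp - config.t_lag_s) / config.t_width_s) ** 2)
    if config.resp_coupling > 0 and config.rr_sd_s > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig += config.resp_coupling * config.rr_sd_s * np.sin(
            2 * np.pi * config.resp_hz * t + phase)
    sig += config.wander_amp * np.sin(2 * np.pi * config.wander_hz * t)
    if config.noise_sd > 0:
        sig += rng.normal(0.0, config.noise_sd, size=n)
    return sig


def gen_dreamer_like(
    n_subjects: int = 23,
    trials_per_subject: int = 18,
    trial_duration_s: float = 61.25,
    vad_map: VadLatentMap | None = None,
    seed: int = 0,
    rate_hz: float = 128.0,
) -> TrialSet:
    """DREAMER-style trial collection with latent-driven labels.

    Per trial, latents (heart rate, RR SD, noise SD) are drawn uniformly from
    the map's stated ranges, the ECG is generated from them, and the SAM
    labels are the affine map of the latents plus optional jitter, clipped to
    [1, 5].  With zero jitter the labels are an exact deterministic function
    of the latents — the basis of the regressor's parameter-recovery tests.
    """
    vad_map = vad_map or VadLatentMap()
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for s in range(n_subjects):
        for ti in range(trials_per_subject):
            hr = rng.uniform(*vad_map.hr_range)
            rr_sd = rng.uniform(*vad_map.rr_sd_range)
            noise = rng.uniform(*vad_map.noise_sd_range)
            ecg = gen_ecg(EcgConfig(
                duration_s=trial_duration_s, rate_hz=rate_hz, heart_rate_bpm=hr,
                rr_sd_s=rr_sd, noise_sd=noise,
                seed=int(rng.integers(0, 2**31 - 1)),
            ))
            vad = np.asarray(vad_map(hr, rr_sd, noise))
            if vad_map.label_jitter_sd > 0:
                vad = vad + rng.normal(0.0, vad_map.label_jitter_sd, size=3)
            vad = np.clip(vad, 1.0, 5.0)
            trials.append(Trial(subject_id=f"S{s:02d}", trial_id=ti, ecg=ecg,
                                vad_raw=tuple(vad)))
    return TrialSet(trials=trials)


def gen_activity_windows(
    n_total: int,
    proportions: tuple[float, ...] = ACTIVITY_PROPORTIONS,
    window_samples: int = 500,
    n_channels: int = 3,
    effect_size: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Imbalanced multichannel activity windows.

    Class ``c`` receives a dominant sinusoid at a class-specific normalised
    frequency and amplitude, scaled by ``effect_size``, on top of unit white
    noise.  Returns (windows of shape n × window_samples × n_channels, labels).
    """
    rng = np.random.default_rng(seed)
    proportions = np.asarray(proportions, dtype=float)
    counts = _class_counts(n_total, proportions)
    # distinct dominant normalised frequencies (cycles/sample) and amplitudes
    freqs = 0.02 + 0.05 * np.arange(len(counts))
    amps = 1.0 + 0.3 * np.arange(len(counts))
    t = np.arange(window_samples)
    xs, ys = [], []
    for c, n_c in enumerate(counts):
        phase = rng.uniform(0, 2 * np.pi, size=(n_c, 1, n_channels))
        carrier = np.sin(2 * np.pi * freqs[c] * t[None, :, None] + phase)
        noise = rng.standard_normal((n_c, window_samples, n_channels))
        xs.append(effect_size * amps[c] * carrier + noise)
        ys.append(np.full(n_c, c, dtype=int))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    perm = rng.permutation(n_total)
    return x[perm], y[perm]
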