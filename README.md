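# affectsense

Stress classification and continuous emotion regression from wearable
biosignals, for researchers in affective computing and mental-health
monitoring who want a fully inspectable, dependency-light reference
implementation they can run end to end without access to the original
recordings.

The package implements two complementary pipelines:

1. **Discrete stress recognition.** A 1-D convolutional network
   (Conv 64 → BatchNorm → MaxPool → Dropout → Conv 128 → … →
   GlobalAveragePooling → Dense 64 → softmax) classifies
   heart-rate-variability feature rows into baseline / stress / amusement,
   with balanced class weights w_c = n/(k·n_c), optional focal loss
   −α_y (1 − p_y)^γ log p_y, early stopping and reduce-on-plateau
   scheduling. The trained backbone transfers to 4-class activity
   recognition by reloading its weights and fine-tuning at a reduced
   learning rate under severe (~93:1) class imbalance.
2. **Continuous valence–arousal–dominance (VAD) regression.** ECG is
   standardised per trace, cut into 5 s windows (640 samples at 128 Hz,
   50% overlap) that inherit their trial's SAM ratings, and summarised by a
   33-value feature vector (11 statistical + 12 db4-wavelet + 10 STFT
   band-power features). A Temporal Conformer — a convolutional front-end
   feeding a transformer encoder with retrievable attention — regresses the
   normalised VAD triple under smooth-L1 loss. Predictions are then
   interpreted by rule-based states (Happy/Excited, Stressed, Relaxed,
   Fatigued, Passive, Neutral), a Fatigue Index (1 − arousal), a Motion
   Quality score (valence × dominance) and k-means profiling.

Both neural architectures, their losses and training loops are implemented
from scratch in numpy with hand-derived, finite-difference-verified
backpropagation (`affectsense.nn`). Explainability tools (1-D Grad-CAM,
Integrated Gradients with completeness reporting, attention extraction,
t-SNE of pooled embeddings), format I/O (EDF, DREAMER-style nested MAT v5,
CSV feature tables, versioned weight checkpoints) and seeded synthetic
generators for all three data modalities are included, so the whole
framework is exercisable offline. See `docs/methods.md` for the models,
conventions and design decisions.

## Worked example

Rule-based diagnostics of predicted VAD triples (arousal, valence,
dominance on [0, 1]):

```python
>>> import numpy as np
>>> from affectsense.diagnostics import diagnose, diagnostics_frame
>>> vad = np.array([[0.54, 0.56, 0.38], [0.34, 0.02, 0.33],
...                 [0.09, 0.93, 0.38], [0.63, 0.09, 0.04]])
>>> print(diagnostics_frame(diagnose(vad, k=2, seed=0)).to_string(index=False))
 Arousal  Valence  Dominance Rule-based state  Cluster  Fatigue index  Motion quality
    0.54     0.56       0.38          Neutral        0           0.46            0.21
    0.34     0.02       0.33          Passive        1           0.66            0.01
    0.09     0.93       0.38          Relaxed        0           0.91            0.35
    0.63     0.09       0.04         Stressed        1           0.37            0.00
```

The first row is Neutral because arousal 0.54 sits below every activation
threshold while dominance 0.38 alone cannot trigger passivity (that rule
also needs arousal < 0.4); the last row crosses the stress rule
(arousal ≥ 0.6 with valence ≤ 0.4). Fatigue is the arousal complement and
Motion Quality the valence–dominance product, e.g. 0.56 × 0.38 = 0.21.

A classification report computed from a confusion matrix of counts:

```python
>>> from affectsense.evaluation import classification_report
>>> cm = np.array([[10401, 247, 98], [21, 3438, 1], [18, 8, 6116]])
>>> print(classification_report(cm).to_text())
 Class  Precision   Recall  F1-score  Support
     0       1.00     0.97      0.98    10746
     1       0.93     0.99      0.96     3460
     2       0.98     1.00      0.99     6142
Accuracy       0.98                       20348
 Macro       0.97     0.99      0.98    20348
   Wgt       0.98     0.98      0.98    20348
```

End-to-end training on synthetic data, from the shell:

```bash
affectsense train-stress --seed 1 --out runs/stress
affectsense finetune-activity --checkpoint runs/stress/checkpoint.npz --seed 1
affectsense train-vad --seed 1 --out runs/vad
```

Each run writes metrics, a per-epoch history CSV, a reusable checkpoint and
a manifest. `affectsense simulate {stress|dreamer|activity|edf}` writes
dataset fixtures; `explain`, `diagnose` and `evaluate` cover attribution,
diagnostics and metric reports.

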