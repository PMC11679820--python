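"""Train the transformer classifier end to end and evaluate it.

Generates a small balanced dataset, standardizes and featurizes it, fits
normalization on the training split only, trains the transformer preset
with cosine-decayed Adam and early stopping, and reports per-class metrics
plus the fall-vs-rest ROC AUC on the held-out test split.
"""

import numpy as np

from posefall import GeneratorConfig, apply_minmax, build_preset, fit_minmax, generate_dataset
from posefall import predict, prepare_features, split_dataset, train
from posefall.evaluation import evaluate_predictions

ds = generate_dataset(GeneratorConfig(clips_per_class=20, seed=0))
feats = prepare_features(ds, seed=1)
T, D = feats[0].values.shape
print(f"{len(feats)} clips, each {T} frames x {D} channels")

model, cfg = build_preset("transformer2", D, T, seed=0, max_epochs=80)
tr, va, te = split_dataset(feats, cfg)
norm = fit_minmax(tr)  # fitted on the training split only (no leakage)
tr, va, te_n = ([apply_minmax(m, norm) for m in part] for part in (tr, va, te))

model, history = train(model, tr, va, cfg)
print(f"trained for {len(history['train_loss'])} epochs "
      f"(early stopping on validation loss, best weights restored)")

probs = predict(model, te_n)
report = evaluate_predictions([m.label for m in te], probs)
print(f"test macro-F1: {report.macro_f1:.3f}   accuracy: {report.accuracy:.3f}   "
      f"fall-vs-rest AUC: {report.auc:.3f}")
print("confusion matrix (rows = true, columns = predicted):")
print(report.confusion.to_frame())
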