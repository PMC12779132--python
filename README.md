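# modalcoder

Multimodal medical-record coding: a transformer-style classifier that
fuses an image, a clinical-text token sequence and a structured-feature
vector into one multi-label coding decision, together with the
evaluation metrics and robustness/ablation harnesses needed to study
it.

The package is aimed at researchers in clinical informatics who want a
small, fully inspectable implementation of three mechanisms that are
usually buried inside large training codebases:

* **Causal masked self-attention** — scaled dot-product attention
  `softmax(QKᵀ/√d_k + M)V` with the additive mask `M_ij = 0` for
  `i ≥ j` and `−∞` for `i < j`, so each token attends only to itself
  and earlier tokens, with *exactly* zero weight on masked positions.
* **Constrained cross-modal attention fusion** — cross-attention
  restricted to an explicit whitelist `P` of ordered
  (query-modality, key-modality) pairs,
  `LayerNorm(X_t + Concat(head_1,…,head_h)W_O)`, so modalities
  interact only where allowed and interference is structurally
  impossible rather than merely penalized.
* **LoRA multi-task training** — frozen base weights `W₀` with
  trainable rank-r updates `ΔW = BA` on the attention q/v projections,
  optimized under a weighted joint objective
  `Σ_k λ_k L_k` combining the coding cross-entropy with a cross-modal
  InfoNCE contrastive task and a mild/moderate/severe severity task.

Evaluation uses five multi-label metrics — subset accuracy, macro F1,
macro one-vs-rest AUC-ROC (midrank ties), sample-averaged Jaccard
index, and Hamming loss — implemented from their definitions and
cross-checked against scikit-learn, plus the relative-change /
absolute-drop arithmetic used in comparison and ablation tables.

Everything is exercised end-to-end on a seeded synthetic case
generator (class-conditional Gaussian structured features, class
templates in the image, class-skewed token distributions), so the whole
study — training, +20% input-noise robustness, −30% training-data
reduction, module ablations — runs in minutes on one CPU with no
external data.  The network runs on a small NumPy reverse-mode autodiff
engine included in the package and validated against finite
differences.

## Worked example

```python
from modalcoder import (GeneratorConfig, MultimodalCodingClassifier,
                        generate_dataset, relative_change)

dataset = generate_dataset(GeneratorConfig())          # n=600, C=3, delta=4
clf = MultimodalCodingClassifier(random_state=0).fit(dataset)
report = clf.evaluate(dataset.split("test"))

print("stopped at epoch", clf.history_.best_epoch,
      "val subset accuracy", round(clf.history_.best_val_accuracy, 3))
print(report.as_percent_row())
```

prints

```
stopped at epoch 6 val subset accuracy 1.0
{'Subset Accuracy(%)': 98.9, 'Macro F1(%)': 98.8, 'Macro AUC-ROC': 100.0,
 'Jaccard Index(%)': 98.9, 'Hamming Loss(%)': 0.7}
```

Training early-stopped after the validation subset accuracy (the
fraction of cases whose whole label vector is predicted exactly)
plateaued at 1.0; on the held-out test split 98.9% of cases are coded
exactly, macro AUC rounds to 100.0%, and 0.7% of individual label
entries are wrong.  The synthetic classes are well separated
(pairwise class-mean distance 4 in structured-feature space), so
near-ceiling numbers are the expected behaviour — the run demonstrates
that the full pipeline trains and fuses correctly, not that the task is
hard.  The estimator follows the scikit-learn contract
(`fit` / `predict` / `predict_proba`, `get_params` / `set_params`), so
it composes with sklearn tooling.

Comparison arithmetic works on printed table values, e.g.
`relative_change(49.0, 55.2)` → `12.7` (percent improvement over a
baseline) and `absolute_drop(64.8, 63.2)` → `1.6` (points lost under a
perturbation).

## Command line

```bash
modalcoder simulate --seed 0 --out-dir fixtures     # write JSONL case records
modalcoder train --seed 0 --fixtures fixtures --out-dir run
modalcoder evaluate --model run/model.pkl --fixtures fixtures --split test
modalcoder robustness --seed 0 --n-seeds 3          # Standard / +20% Noise / -30% Data
modalcoder ablate --seed 0 --n-seeds 3              # module-switch ablations
modalcoder report --table run/robustness.csv --baseline Standard
```

A YAML/JSON `--config` file can override any generator, architecture
or training parameter (see `docs/methods.md` for the full list and the
rationale behind the defaults).

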