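"""scikit-learn style estimator wrapping the multimodal coding network.

:class:`MultimodalCodingClassifier` follows the sklearn estimator
contract — keyword-only constructor that stores parameters verbatim,
``fit`` / ``predict`` / ``predict_proba``, ``get_params`` /
``set_params``, trailing-underscore fitted attributes — so it composes
with sklearn model selection.  ``X`` is a list of
:class:`~modalcoder.records.CaseRecord` (or a
:class:`~modalcoder.simulate.SyntheticDataset`, whose train/val splits
are then respected); ``y`` defaults to the class index encoded in each
record's one-hot label vector.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .fusion import DEFAULT_POLICY_PAIRS
from .metrics import MetricsReport, evaluate_all
from .model import CodingNetwork, ModelConfig
from .records import CaseRecord
from .simulate import SyntheticDataset
from .train import TrainConfig, predict_labels, train

__all__ = ["MultimodalCodingClassifier"]


class MultimodalCodingClassifier(BaseEstimator, ClassifierMixin):
    """Multimodal case-coding classifier.

    Parameters mirror the architecture and training knobs: attention
    geometry, the cross-modal allowed-pair policy, LoRA adaptation, the
    auxiliary-task weights, and the optimizer settings.  The three
    ``use_*`` switches realize the module ablations as strict
    configuration changes.
    """

    def __init__(self, *, d_model: int = 64, n_heads: int = 4,
                 n_causal_blocks: int = 2, ffn_hidden: int = 128,
                 patch_size: int = 4, vocab_size: int = 32,
                 structured_dim: int = 8,
                 policy_pairs: tuple = DEFAULT_POLICY_PAIRS,
                 use_causal_mask: bool = True, use_pcma: bool = True,
                 use_mtl: bool = True, lora: bool = False, lora_rank: int = 4,
                 lambda_contrastive: float = 0.3, lambda_severity: float = 0.3,
                 temperature: float = 0.1, learning_rate: float = 1e-3,
                 batch_size: int = 32, max_epochs: int = 50, patience: int = 5,
                 val_fraction: float = 0.15, multi_label: bool = False,
                 random_state: int = 0):
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_causal_blocks = n_causal_blocks
        self.ffn_hidden = ffn_hidden
        self.patch_size = patch_size
        self.vocab_size = vocab_size
        self.structured_dim = structured_dim
        self.policy_pairs = policy_pairs
        self.use_causal_mask = use_causal_mask
        self.use_pcma = use_pcma
        self.use_mtl = use_mtl
        self.lora = lora
        self.lora_rank = lora_rank
        self.lambda_contrastive = lambda_contrastive
        self.lambda_severity = lambda_severity
        self.temperature = temperature
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.multi_label = multi_label
        self.random_state = random_state

    # -- helpers --------------------------------------------------------------
    def _as_dataset(self, X) -> SyntheticDataset:
        if isinstance(X, SyntheticDataset):
            return X
        records = list(X)
        if not records:
            raise ValueError("X must contain at least one case record")
        rng = np.random.default_rng(self.random_state)
        perm = rng.permutation(len(records))
        n_val = max(1, int(round(self.val_fraction * len(records))))
        return SyntheticDataset(
            records=records, class_means=np.zeros((0, 0)),
            templates=np.zeros((0, 0, 0)), token_probs=np.zeros((0, 0)),
            train_idx=perm[n_val:], val_idx=perm[:n_val],
            test_idx=np.asarray([], dtype=np.int64), config=None)

    def _model_config(self, n_labels: int) -> ModelConfig:
        return ModelConfig(
            n_labels=n_labels, d_model=self.d_model, n_heads=self.n_heads,
            n_causal_blocks=self.n_causal_blocks, ffn_hidden=self.ffn_hidden,
            patch_size=self.patch_size, vocab_size=self.vocab_size,
            structured_dim=self.structured_dim,
            policy_pairs=tuple(tuple(p) for p in self.policy_pairs),
            use_causal_mask=self.use_causal_mask, use_pcma=self.use_pcma,
            use_mtl=self.use_mtl, lora_enabled=self.lora,
            lora_rank=self.lora_rank)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.max_epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, patience=self.patience,
            seed=self.random_state,
            lambda_contrastive=self.lambda_contrastive,
            lambda_severity=self.lambda_severity,
            temperature=self.temperature, multi_label=self.multi_label)

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y=None) -> "MultimodalCodingClassifier":
        """Train on case records; ``y`` may override the encoded labels."""
        dataset = self._as_dataset(X)
        if y is not None:
            y = np.asarray(y)
            if len(y) != len(dataset.records):
                raise ValueError("y length must match the number of records")
            for rec, cls in zip(dataset.records, y):
                rec.labels = np.zeros_like(rec.labels)
                rec.labels[int(cls)] = 1
        n_labels = len(dataset.records[0].labels)
        self.classes_ = np.arange(n_labels)
        self.n_labels_ = n_labels
        rng = np.random.default_rng(self.random_state)
        self.network_ = CodingNetwork(self._model_config(n_labels), rng)
        self.history_ = train(self.network_, dataset, self._train_config())
        return self

    def _records(self, X) -> list[CaseRecord]:
        if isinstance(X, SyntheticDataset):
            return X.records
        return list(X)

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self.network_.predict_scores(self._records(X))

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def predict_label_matrix(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Per-label scores and the hard binary label matrix."""
        self._check_fitted()
        return predict_labels(self.network_, self._records(X), self.multi_label)

    def evaluate(self, X) -> MetricsReport:
        """All five multi-label metrics against the records' own labels."""
        records = self._records(X)
        truth = np.stack([r.labels for r in records])
        scores, yhat = self.predict_label_matrix(records)
        return evaluate_all(truth, scores, yhat)

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted; call fit first")
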