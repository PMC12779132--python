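"""Shared fixtures.

Training runs are expensive relative to the rest of the suite, so the
default-scale dataset and the seed-replicated training runs used by the
end-to-end, robustness and ablation tests are computed once per session
and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from modalcoder import (GeneratorConfig, MultimodalCodingClassifier,
                        generate_dataset)
from modalcoder.pipeline import evaluate_split
from modalcoder.simulate import apply_input_noise

ROBUSTNESS_SEEDS = (0, 1, 2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default study conditions: n=600, C=3, delta=4."""
    return generate_dataset(GeneratorConfig())


@pytest.fixture(scope="session")
def small_dataset():
    """A fast dataset for unit-level training checks."""
    return generate_dataset(GeneratorConfig(n_samples=120, seed=7))


def _fit(dataset, seed: int, **overrides):
    clf = MultimodalCodingClassifier(random_state=seed, **overrides)
    clf.fit(dataset)
    return clf


@pytest.fixture(scope="session")
def seed_runs(default_dataset):
    """Per-seed trained models and test metrics under the study settings.

    For each seed: the full model on the standard dataset, the full
    model on the +20% input-noise dataset, and the three single-module
    ablations on the standard dataset.
    """
    runs: dict[int, dict] = {}
    for seed in ROBUSTNESS_SEEDS:
        noisy = apply_input_noise(default_dataset, 0.2, seed=seed + 1000)
        entry: dict = {}
        full = _fit(default_dataset, seed)
        entry["full"] = {
            "val_accuracy": full.history_.best_val_accuracy,
            "test": evaluate_split(full, default_dataset, "test"),
        }
        noise_clf = _fit(noisy, seed)
        entry["noise"] = {
            "val_accuracy": noise_clf.history_.best_val_accuracy,
            "test": evaluate_split(noise_clf, noisy, "test"),
        }
        for name, switch in (("no_causal", "use_causal_mask"),
                             ("no_pcma", "use_pcma"),
                             ("no_mtl", "use_mtl")):
            ab = _fit(default_dataset, seed, **{switch: False})
            entry[name] = {
                "val_accuracy": ab.history_.best_val_accuracy,
                "test": evaluate_split(ab, default_dataset, "test"),
            }
        runs[seed] = entry
    return runs
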