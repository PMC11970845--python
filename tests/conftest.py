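"""Shared fixtures.

The expensive end-to-end image models (separable task and zero-contrast
null) are trained once per session and shared by the tests that exercise
training outcomes and the set-size robustness sweep.
"""

from __future__ import annotations

import numpy as np
import pytest

from picaso import (AggregatorConfig, EncoderSpec, LesionImageSpec,
                    SetNetwork, TrainConfig, build_one_positive_sets,
                    gen_lesion_image_sets, materialize, train)


def make_vector_sets(n_sets: int, seed: int, d: int = 16, offset: float = 3.0,
                     m_range=(4, 8)):
    """One-positive vector sets: the positive instance is offset in mean."""
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        m = int(rng.integers(m_range[0], m_range[1] + 1))
        x = rng.standard_normal((m, d)).astype(np.float32)
        j = int(rng.integers(m))
        x[j] += offset
        t = np.zeros(m, dtype=np.float32)
        t[j] = 1.0
        sets.append((x, t))
    return sets


def lesion_train_val_sets(spec: LesionImageSpec, n_train: int, n_val: int,
                          val_fraction: float = 0.2, seed: int = 1):
    """Monte Carlo train/val sets from group-disjoint case pools."""
    pool, _, _ = gen_lesion_image_sets(spec, task="one_positive")
    groups = sorted({r.group_id for r in pool.values()})
    n_val_groups = max(1, int(len(groups) * val_fraction))
    val_groups = set(groups[-n_val_groups:])
    train_recs = [r for r in pool.values() if r.group_id not in val_groups]
    val_recs = [r for r in pool.values() if r.group_id in val_groups]
    tsets = [materialize(b, pool)
             for b in build_one_positive_sets(train_recs, n_train, seed=seed)]
    vsets = [materialize(b, pool)
             for b in build_one_positive_sets(val_recs, n_val, seed=seed + 1)]
    return tsets, vsets


def default_image_network(seed: int = 0) -> SetNetwork:
    return SetNetwork(
        "one_positive",
        agg=AggregatorConfig(operator="picaso", dim=64, n_steps=3),
        encoder=EncoderSpec(name="tiny_cnn", out_dim=64),
        seed=seed,
    )


@pytest.fixture(scope="session")
def image_task_sets():
    """Separable planted-crescent train/val sets at the study conditions."""
    spec = LesionImageSpec(n_cases=200, seed=0)
    tsets, vsets = lesion_train_val_sets(spec, n_train=600, n_val=150)
    return {"train": tsets, "val": vsets, "spec": spec}


@pytest.fixture(scope="session")
def trained_image_model(image_task_sets):
    """The cascade trained end-to-end on images with the clinical schedule
    (BCE, Adam, lr 1e-4, 20 epochs, batch 32). Shared across tests."""
    net = default_image_network(seed=0)
    train(net, image_task_sets["train"], TrainConfig(epochs=20, seed=0))
    return net


@pytest.fixture(scope="session")
def trained_null_model():
    """Model trained on the zero-contrast null (no learnable signal).

    Reduced scale (120 cases, 6 epochs): a null has nothing to learn, the
    check is only that its validation AUROC stays at chance.
    """
    spec = LesionImageSpec(n_cases=120, contrast=0.0, seed=10)
    tsets, vsets = lesion_train_val_sets(spec, n_train=360, n_val=150, seed=11)
    net = default_image_network(seed=1)
    train(net, tsets, TrainConfig(epochs=6, seed=1))
    return net, vsets
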