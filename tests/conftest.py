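"""Shared fixtures: small synthetic datasets rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from focusscore import evalstat as ev
from focusscore import synthgen as sg


@pytest.fixture(scope="session")
def small_balanced_manifest():
    """In-memory balanced dataset (20 + 20) at the minimum canvas size."""
    return sg.generate_dataset(20, 20, rng_seed=123, canvas=(224, 224))


@pytest.fixture(scope="session")
def tiny_split_manifest():
    """40-image manifest with train/val/test splits for quick training runs."""
    man = sg.generate_dataset(20, 20, rng_seed=321, canvas=(224, 224))
    return ev.stratified_split(
        man, ev.SplitSpec(fractions=(0.6, 0.2, 0.2), seed=7))


@pytest.fixture(scope="session")
def recovery_data(tmp_path_factory):
    """Maximal-contrast images on disk: 200 train-pool + 100 test.

    Written to disk so that label permutations can be applied to the
    manifest without changing the underlying pixels (in-memory manifests
    re-render from the label).
    """
    root = tmp_path_factory.mktemp("recovery")
    train = sg.generate_dataset(100, 100, rng_seed=2024, canvas=(224, 224),
                                out_dir=root / "train")
    test = sg.generate_dataset(50, 50, rng_seed=77777, canvas=(224, 224),
                               out_dir=root / "test")
    return train, test


def permute_labels(manifest: sg.DatasetManifest, seed: int) -> sg.DatasetManifest:
    """Return a copy with the label column randomly permuted (on-disk data only)."""
    df = manifest.records.copy()
    assert (df["path"] != "").all(), "label permutation needs on-disk images"
    rng = np.random.default_rng(seed)
    df["label"] = df["label"].to_numpy()[rng.permutation(len(df))]
    return sg.DatasetManifest(df)
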