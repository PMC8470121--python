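"""Shared fixtures: small synthetic datasets and classification problems."""

from __future__ import annotations

import numpy as np
import pytest

import semgkit as sk


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


def gaussian_blobs(seed: int, n_per: int = 20, d: int = 8, spread: float = 2.2,
                   scale: float = 1.0, n_classes: int = 6):
    """Seeded Gaussian-cluster classification problem, one cluster per
    action label. ``spread`` controls class overlap (larger = harder)."""
    g = np.random.default_rng(seed)
    centers = g.standard_normal((n_classes, d))
    X = np.vstack([c + spread * g.standard_normal((n_per, d)) for c in centers]) * scale
    y = np.repeat([f"y{i + 1}" for i in range(n_classes)], n_per)
    return X, y


def separable_blobs(seed: int, n_per: int = 10, d: int = 8):
    """Well-separated clusters: any reasonable (c, g) classifies them."""
    return gaussian_blobs(seed, n_per=n_per, d=d, spread=0.15)


@pytest.fixture(scope="session")
def short_sim():
    """4 s trials: rest, burst at 1.0 s for 2.6 s — the main feature
    segment (onset+0.5 s .. onset+2.5 s) fits with margin."""
    return dict(
        config=sk.SimConfig(n_per_class=2, duration=4.0, seed=5),
        profiles=sk.default_profiles(burst_onset=1.0, burst_duration=2.6),
    )


@pytest.fixture(scope="session")
def small_manifest(short_sim):
    """12 labelled synthetic recordings (2 per action)."""
    return sk.generate_dataset(short_sim["config"], short_sim["profiles"])
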