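"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from btrlearn import (AbundanceMatrix, SampleTarget, PlantedModel,
                      SyntheticSpec, generate_dataset)


def brute_force_threshold(scores, y_pos):
    """Independent oracle: minimum training error over all cuts x directions.

    Enumerates every midpoint between consecutive distinct scores plus
    -inf/+inf sentinels and counts misclassifications by direct comparison.
    Returns the minimal error count only (the cut itself may tie).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_pos, dtype=bool)
    uniq = np.unique(scores[np.isfinite(scores)])
    cuts = [-np.inf, np.inf]
    cuts += [0.5 * (a + b) for a, b in zip(uniq[:-1], uniq[1:])]
    if np.isinf(scores).any() and uniq.size:
        cuts.append(uniq[-1] + 1.0)
    best = scores.size
    for cut in cuts:
        for greater in (True, False):
            pred = scores > cut if greater else scores < cut
            best = min(best, int((pred != y).sum()))
    return best


@pytest.fixture
def threshold_oracle():
    return brute_force_threshold


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_matrix():
    """3 features x 4 samples, relative scale, hand-checkable numbers."""
    values = np.array([
        [0.10, 0.40, 0.25, 0.05],
        [0.05, 0.10, 0.25, 0.15],
        [0.85, 0.50, 0.50, 0.80],
    ])
    return AbundanceMatrix(values, ["f_a", "f_b", "f_c"],
                           ["s1", "s2", "s3", "s4"], scale="relative")


@pytest.fixture
def small_dataset():
    """Synthetic 12-feature, 60-sample cohort with a planted bin signal."""
    spec = SyntheticSpec(n_samples=60, p_features=12, label_noise=0.0,
                         planted_model=PlantedModel(language="bin",
                                                    feature_indices=(0, 1, 2)),
                         seed=11)
    return generate_dataset(spec)


@pytest.fixture
def separable_dataset():
    """One feature perfectly separates the classes; others are noise."""
    gen = np.random.default_rng(5)
    p, n = 8, 40
    x = gen.lognormal(0.0, 1.0, size=(p, n))
    labels = np.array(["neg"] * (n // 2) + ["pos"] * (n // 2), dtype=object)
    x[0, labels == "pos"] += 50.0  # dominant, perfectly separating feature
    x = x / x.sum(axis=0)
    m = AbundanceMatrix(x, [f"feat_{i}" for i in range(p)],
                        [f"s{j}" for j in range(n)], scale="relative")
    y = SampleTarget(list(m.sample_ids), "binary_class", labels,
                     positive_class="pos")
    return m, y
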