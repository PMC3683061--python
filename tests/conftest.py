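"""Shared fixtures: small in-memory cohorts and a session-scoped synthetic
cohort on disk used by the heavier end-to-end tests."""

import numpy as np
import pytest

from pmfusion import pipeline
from pmfusion.simulate import SimulationConfig, render_fundus, simulate_cohort
from pmfusion.types import CohortBundle, FeatureView


def make_bundle(
    n: int = 40,
    prevalence: float = 0.25,
    seed: int = 0,
    separations=(0.6, 1.2, 2.4),
    n_features=(6, 10, 8),
) -> CohortBundle:
    """Direct-feature cohort: three Gaussian views whose class-mean
    separation (in within-class SDs) differs per modality."""
    rng = np.random.default_rng(seed)
    n_pos = max(2, round(n * prevalence))
    labels = np.r_[np.ones(n_pos, int), -np.ones(n - n_pos, int)]
    labels = labels[rng.permutation(n)]
    ids = [f"T{i:03d}" for i in range(n)]
    views = {}
    for tag, sep, p in zip(("D", "G", "I"), separations, n_features):
        X = rng.normal(size=(n, p))
        X[labels == 1] += sep / np.sqrt(p)
        views[tag] = FeatureView(tag, ids, X)
    return CohortBundle(subject_ids=ids, labels=labels, views=views)


@pytest.fixture
def bundle40():
    return make_bundle(n=40, prevalence=0.25, seed=3)


@pytest.fixture(scope="session")
def fundus_set():
    """200 rendered fundus images (100 positive at contrast 0.8, 100
    negative) with one RNG stream per image for reproducibility."""
    images, labels = [], []
    for i in range(200):
        label = 1 if i < 100 else -1
        rng = np.random.default_rng([42, i])
        images.append(render_fundus(label, rng, contrast=0.8))
        labels.append(label)
    return images, np.array(labels)


@pytest.fixture(scope="session")
def cohort600_dir(tmp_path_factory):
    """Default-condition synthetic cohort scaled to 600 subjects."""
    out = tmp_path_factory.mktemp("cohort600")
    simulate_cohort(SimulationConfig(n_subjects=600, seed=11), out)
    return out


@pytest.fixture(scope="session")
def cohort600_bundle(cohort600_dir):
    return pipeline.load_cohort(cohort600_dir)
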