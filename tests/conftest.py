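"""Shared fixtures: synthetic worlds at two scales plus derived training data.

Session scope keeps the expensive default world (600 planted loops) to a
single generation + featurization for the whole suite.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import loopforest as lf

# reduced forest for test runtime; the model default (500 trees) is config-exposed
FAST_FOREST = {"n_estimators": 150}


@pytest.fixture(scope="session")
def default_fixture() -> lf.Fixture:
    """The default planted world: ~600 positives, strong effects."""
    return lf.generate_fixture()


@pytest.fixture(scope="session")
def small_fixture() -> lf.Fixture:
    """A fast, smaller world for structural (non-statistical) checks."""
    spec = replace(
        lf.FixtureSpec(),
        n_sites=300,
        n_loop_sites=100,
        n_true_loops=80,
        n_subthreshold_calls=60,
        n_genes=120,
        seed=7,
    )
    return lf.generate_fixture(spec)


@pytest.fixture(scope="session")
def default_training(default_fixture):
    """Positives, 5x negatives and the featurized matrix of the default world."""
    fx = default_fixture
    sites = fx.sites()
    positives = lf.select_positives(fx.loop_calls)
    negatives = lf.build_negatives(
        sites, positives, fx.loop_calls, fx.hic_loops, ratio=5.0, seed=11
    )
    bundle = fx.bundle()
    X = lf.featurize(positives + negatives, bundle)
    y = np.r_[np.ones(len(positives), dtype=int), np.zeros(len(negatives), dtype=int)]
    return {
        "fixture": fx,
        "sites": sites,
        "bundle": bundle,
        "positives": positives,
        "negatives": negatives,
        "X": X,
        "y": y,
    }


@pytest.fixture(scope="session")
def default_model(default_training):
    return lf.train(
        default_training["X"], default_training["y"], seed=3, **FAST_FOREST
    )
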