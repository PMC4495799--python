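"""Shared fixtures: a small fast cohort and the default-scale cohort.

All fixtures are generated programmatically and seeded, so the suite needs
no data files and is fully reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import methclass as mc


def make_matrix(values, probes=None, samples=None) -> mc.BetaMatrix:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return mc.BetaMatrix(pd.DataFrame(values, index=probes, columns=samples))


@pytest.fixture(scope="session")
def small_cohort():
    """3 classes x 8 samples, 300 probes, 10 markers/class, no missing."""
    cfg = mc.SimConfig(
        n_classes=3,
        samples_per_class=8,
        n_probes=300,
        markers_per_class=10,
        heterogeneity={},
        missing_fraction=0.0,
        seed=7,
    )
    return (*mc.simulate_cohort(cfg), cfg)


@pytest.fixture(scope="session")
def small_clf(small_cohort):
    m, labels, truth, cfg = small_cohort
    panel = mc.build_panel(mc.rank_all_classes(m, labels), 10)
    clf = mc.train(m, labels, mc.ForestConfig(n_trees=101, seed=7), panel)
    return clf, m, labels, panel


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 9 classes x 20 samples, 5000 probes,
    50 markers/class, 1% missing cells, one heterogeneous class; seed 1."""
    cfg = mc.SimConfig(seed=1)
    return (*mc.simulate_cohort(cfg), cfg)


@pytest.fixture(scope="session")
def default_imputed(default_cohort):
    m, labels, truth, cfg = default_cohort
    return mc.knn_impute(m)


@pytest.fixture(scope="session")
def default_panel(default_cohort, default_imputed):
    _, labels, _, _ = default_cohort
    return mc.build_panel(mc.rank_all_classes(default_imputed, labels), 100)


@pytest.fixture(scope="session")
def default_clf(default_cohort, default_imputed, default_panel):
    _, labels, _, _ = default_cohort
    cfg = mc.ForestConfig(seed=1)
    mtry = mc.tune_mtry(default_imputed, labels, cfg, default_panel)
    from methclass.forest import _with_mtry

    return mc.train(default_imputed, labels, _with_mtry(cfg, mtry), default_panel)
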