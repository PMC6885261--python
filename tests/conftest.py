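"""Shared fixtures: small feature tables and the full synthetic benchmark."""

from __future__ import annotations

import numpy as np
import pytest

import emgkit as ek


@pytest.fixture(scope="session")
def gaussian_table() -> ek.FeatureTable:
    """Separable 3-class Gaussian blob table (no signal processing involved)."""
    rng = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
    n_per = 60
    X = np.vstack([rng.normal(c, 0.5, size=(n_per, 2)) for c in centers])
    labels = np.repeat(list(ek.CLASSES), n_per)
    return ek.FeatureTable(
        X=X,
        labels=labels,
        feature_names=["f0", "f1"],
        class_labels=ek.CLASSES,
    )


@pytest.fixture(scope="session")
def benchmark_table() -> ek.FeatureTable:
    """The full synthetic benchmark: 3x17 recordings at seed 42 -> 2448x95."""
    recordings = ek.simulate_dataset(
        ek.default_profiles(), 17, ek.SimulationConfig(seed=42)
    )
    frames = []
    for rec in recordings:
        frames.extend(ek.frame_signal(rec))
    return ek.extract_features(frames)


def run_benchmark_cv(table: ek.FeatureTable) -> dict[str, ek.MetricsReport]:
    """Stratified 10-fold CV of AdaBoost(T=10) over a 25-tree random forest,
    the single-forest baseline on the same folds, and a k-NN label-permutation
    control.  Shared by the acceptance tests and the determinism check."""
    cv = ek.CvConfig(k_folds=10, seed=42)
    forest = ek.make_learner("random_forest", n_trees=25)
    reports = {
        "adaboost_rf": ek.cross_validate(
            lambda ds, seed: ek.adaboost_m1_train(forest, ds, T=10, seed=seed),
            table,
            cv,
        ),
        "rf_baseline": ek.cross_validate(
            lambda ds, seed: forest.train(ds, seed), table, cv
        ),
    }
    rng = np.random.default_rng(ek.derive_seed(42, "permutation"))
    permuted = ek.FeatureTable(
        X=table.X,
        labels=table.labels[rng.permutation(table.n)],
        feature_names=table.feature_names,
        class_labels=table.class_labels,
        groups=table.groups,
    )
    knn = ek.make_learner("knn", k=5)
    reports["permutation_control"] = ek.cross_validate(
        lambda ds, seed: knn.train(ds, seed), permuted, cv
    )
    return reports


@pytest.fixture(scope="session")
def benchmark_reports(benchmark_table) -> dict[str, ek.MetricsReport]:
    return run_benchmark_cv(benchmark_table)
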