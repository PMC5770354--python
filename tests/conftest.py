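import numpy as np
import pandas as pd
import pytest

from qsarflow import CompoundRecord, SyntheticSpec, make_regression_dataset, make_smiles_fixture

# the study conditions used throughout: a sparse nonlinear response over a
# wide mixed descriptor/fingerprint-like matrix
BENCHMARK_SPEC = SyntheticSpec(n=300, p=200, n_informative=10, noise_sd=0.05, seed=1)


@pytest.fixture(scope="session")
def benchmark():
    """(features, activities, informative names) for the standard benchmark."""
    return make_regression_dataset(BENCHMARK_SPEC)


@pytest.fixture(scope="session")
def fixture_records():
    return [CompoundRecord(*row) for row in make_smiles_fixture()]


@pytest.fixture()
def small_feature_csv(tmp_path):
    """A small synthetic feature-table input for fast pipeline runs."""
    spec = SyntheticSpec(n=120, p=60, n_informative=8, noise_sd=0.05, seed=5)
    fm, acts, _ = make_regression_dataset(spec)
    df = fm.values.copy()
    df.insert(0, "activity", acts.values)
    path = tmp_path / "features.csv"
    df.to_csv(path, index_label="compound_id")
    return path


def brute_force_knn_loo(X, y, k):
    """Exhaustive pairwise-distance LOO kNN oracle (explicit loops)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            dists.append((float(np.sqrt(((X[i] - X[j]) ** 2).sum())), j))
        dists.sort(key=lambda t: (t[0], t[1]))
        preds[i] = float(np.mean([y[j] for _, j in dists[:k]]))
    return preds
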