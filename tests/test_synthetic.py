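import numpy as np
import pandas as pd
import pytest

from qsarflow import (
    SyntheticSpec,
    make_activity_cliff_dataset,
    make_regression_dataset,
    make_smiles_fixture,
    modi,
)
from qsarflow.errors import ConfigurationError


class TestRegressionGenerator:
    def test_shape_and_ground_truth_bookkeeping(self):
        spec = SyntheticSpec(n=300, p=200, n_informative=10, noise_sd=0.05, seed=1)
        fm, acts, informative = make_regression_dataset(spec)
        assert fm.shape == (300, 200)
        assert len(informative) == 10
        assert set(informative) <= set(fm.column_names)
        assert acts.values.between(0, 1).all()

    def test_reproducible_from_spec(self):
        spec = SyntheticSpec(n=50, p=30, n_informative=5, seed=9)
        a_fm, a_y, a_inf = make_regression_dataset(spec)
        b_fm, b_y, b_inf = make_regression_dataset(spec)
        pd.testing.assert_frame_equal(a_fm.values, b_fm.values)
        assert a_y.values.equals(b_y.values) and a_inf == b_inf

    def test_noiseless_linear_response_reconstructible(self):
        spec = SyntheticSpec(n=80, p=40, n_informative=6, noise_sd=0.0,
                             seed=2, response_form="linear")
        fm, acts, informative = make_regression_dataset(spec)
        V = fm.values[informative].to_numpy()
        design = np.column_stack([V, np.ones(len(V))])
        _, residual, *_ = np.linalg.lstsq(design, acts.values.to_numpy(), rcond=None)
        resid = float(residual[0]) if residual.size else 0.0
        assert resid == pytest.approx(0.0, abs=1e-16)

    def test_binarized_fraction_of_columns(self):
        spec = SyntheticSpec(n=100, p=60, n_informative=6, seed=3)
        fm, _, _ = make_regression_dataset(spec)
        n_binary = int((fm.column_kind == "fingerprint").sum())
        assert n_binary == 30  # half of p by default

    def test_smooth_dense_data_is_highly_modelable(self):
        spec = SyntheticSpec(n=200, p=200, n_informative=10, noise_sd=0.0, seed=3)
        fm, acts, _ = make_regression_dataset(spec)
        assert modi(fm, acts.values.to_numpy(), k=5).score > 0.9

    def test_cliff_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            make_regression_dataset(SyntheticSpec(cliff_fraction=0.5))
        with pytest.raises(ConfigurationError):
            SyntheticSpec(n_informative=50, p=20)


class TestCliffGenerator:
    def test_zero_fraction_delegates_to_regression(self):
        spec = SyntheticSpec(n=50, p=30, n_informative=5, seed=4)
        fm_c, y_c = make_activity_cliff_dataset(spec)
        fm_r, y_r, _ = make_regression_dataset(spec)
        pd.testing.assert_frame_equal(fm_c.values, fm_r.values)
        assert y_c.values.equals(y_r.values)

    def test_pairs_are_near_duplicates_with_divergent_activities(self):
        spec = SyntheticSpec(n=100, p=60, n_informative=6, cliff_fraction=1.0, seed=5)
        fm, acts = make_activity_cliff_dataset(spec)
        X = fm.to_numpy()
        y = acts.values.to_numpy()
        n_pairs = 50
        base, twin = X[:n_pairs], X[n_pairs:]
        y_lo, y_hi = y[:n_pairs], y[n_pairs:]
        pair_dist = np.sqrt(((base - twin) ** 2).sum(axis=1))
        # perturbation far below typical inter-point distance
        others = np.sqrt(((base[0] - base[1:]) ** 2).sum(axis=1))
        assert pair_dist.max() < 0.1 * others.min()
        assert (y_lo <= 0.05).all() and (y_hi >= 0.95).all()

    def test_cliffs_depress_modelability(self):
        spec = SyntheticSpec(n=100, p=200, n_informative=10, cliff_fraction=1.0, seed=1)
        fm, acts = make_activity_cliff_dataset(spec)
        y = acts.values.to_numpy()
        assert modi(fm, y, k=3).score < 0.2
        assert modi(fm, y, k=5).score < 0.2


class TestSmilesFixture:
    def test_planted_irregularities_present(self):
        rows = make_smiles_fixture()
        assert len(rows) >= 40
        smiles = [r[1] for r in rows]
        assert sum("." in s for s in smiles) == 1  # exactly one salt form
        assert sum(s == "notasmiles" for s in smiles) == 1
        assert sum(r[3] is None for r in rows) == 1
        assert sum(r[2] != "Ki" for r in rows) == 1
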