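import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarflow import (
    LearnerConfig,
    ModelBundle,
    applicability_domain,
    compute_pve,
    compute_rmse,
    fit_and_validate,
)
from qsarflow.errors import AlignmentError, ConfigurationError, DomainError, TooSmallError
from qsarflow.featurize import FeatureMatrix
from qsarflow.transform import apply_minmax, fit_minmax


def _brute_pve(y, yh):
    sse = sum((a - b) ** 2 for a, b in zip(y, yh))
    ybar = sum(y) / len(y)
    sst = sum((a - ybar) ** 2 for a in y)
    return 1 - sse / sst


def _brute_rmse(y, yh):
    return (sum((a - b) ** 2 for a, b in zip(y, yh)) / len(y)) ** 0.5


class TestMetrics:
    def test_hand_worked_examples(self):
        y = np.array([0.0, 1.0, 2.0])
        assert compute_pve(y, y) == pytest.approx(1.0)
        assert compute_pve(y, np.full(3, y.mean())) == pytest.approx(0.0)
        assert compute_pve(y, [0, 1, 1]) == pytest.approx(0.5)
        assert compute_rmse(y, y) == 0.0
        assert compute_rmse([0, 0], [1, 1]) == pytest.approx(1.0)
        assert compute_rmse([0, 2], [1, 1]) == pytest.approx(1.0)

    def test_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 1000))
            y = rng.normal(size=n)
            yh = y + rng.normal(scale=0.5, size=n)
            assert compute_pve(y, yh) == pytest.approx(_brute_pve(y, yh), abs=1e-10)
            assert compute_rmse(y, yh) == pytest.approx(_brute_rmse(y, yh), abs=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(
        scale=st.floats(min_value=0.1, max_value=100),
        shift=st.floats(min_value=-50, max_value=50),
    )
    def test_pve_invariant_under_joint_affine_transform(self, scale, shift):
        rng = np.random.default_rng(7)
        y = rng.normal(size=30)
        yh = y + rng.normal(scale=0.3, size=30)
        assert compute_pve(scale * y + shift, scale * yh + shift) == pytest.approx(
            compute_pve(y, yh), rel=1e-9
        )

    def test_degenerate_inputs(self):
        with pytest.raises(DomainError):
            compute_pve([1.0, 1.0], [1.0, 0.5])
        with pytest.raises(DomainError):
            compute_rmse([], [])


class TestApplicabilityDomain:
    def test_identical_external_row_is_inside(self):
        train = np.array([[0.0, 0.0], [1.0, 1.0], [0.5, 0.5]])
        report = applicability_domain(train, train[:1])
        assert report.table["nn_distance"].iloc[0] == 0.0
        assert not report.table["outside"].iloc[0]

    def test_zero_spread_threshold_and_strict_exceed(self):
        # all training NN distances are exactly 1 -> threshold 1 for any Z
        train = np.array([[0.0], [1.0], [2.0], [3.0]])
        report = applicability_domain(train, np.array([[8.0], [3.5], [4.0]]), z=0.5)
        assert report.threshold == pytest.approx(1.0)
        assert list(report.table["outside"]) == [True, False, False]  # boundary value inside

    def test_flags_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        train = rng.uniform(size=(20, 4))
        ivs = rng.uniform(size=(8, 4)) * 1.5
        base = applicability_domain(train, ivs)
        perm_t = rng.permutation(20)
        perm_i = rng.permutation(8)
        shuffled = applicability_domain(train[perm_t], ivs[perm_i])
        assert shuffled.threshold == pytest.approx(base.threshold)
        assert list(shuffled.table["outside"]) == [bool(base.table["outside"].iloc[i]) for i in perm_i]

    def test_too_small_training_set(self):
        with pytest.raises(TooSmallError):
            applicability_domain(np.zeros((1, 2)), np.zeros((1, 2)))


def _scaled_split(seed=0, n=60, p=8):
    rng = np.random.default_rng(seed)
    arr = rng.uniform(size=(n, p))
    df = pd.DataFrame(arr, index=[f"r{i}" for i in range(n)], columns=[f"f{i}" for i in range(p)])
    fm = FeatureMatrix(df, pd.Series("descriptor", index=df.columns))
    y = np.clip(arr[:, 0] * 0.7 + 0.15 + 0.05 * rng.normal(size=n), 0, 1)
    train = fm.subset_rows(df.index[:45])
    ivs = fm.subset_rows(df.index[45:])
    scaler = fit_minmax(train)
    return (
        apply_minmax(train, scaler),
        y[:45],
        apply_minmax(ivs, scaler),
        y[45:],
        scaler,
    )


class TestFitAndValidate:
    def test_full_subset_equals_full_model(self):
        X_tr, y_tr, X_iv, y_iv, scaler = _scaled_split()
        rep_all, _ = fit_and_validate(X_tr, y_tr, X_iv, y_iv, X_tr.column_names, model_name="m")
        rep_full, _ = fit_and_validate(X_tr, y_tr, X_iv, y_iv, None, model_name="m")
        assert rep_all.lookup("m", "ivs") == rep_full.lookup("m", "ivs")

    def test_empty_subset_rejected(self):
        X_tr, y_tr, X_iv, y_iv, _ = _scaled_split()
        with pytest.raises(ConfigurationError):
            fit_and_validate(X_tr, y_tr, X_iv, y_iv, [])

    def test_bundle_roundtrip_reproduces_predictions(self, tmp_path):
        X_tr, y_tr, X_iv, y_iv, scaler = _scaled_split(seed=1)
        subset = X_tr.column_names[:5]
        _, bundle = fit_and_validate(
            X_tr, y_tr, X_iv, y_iv, subset,
            learner=LearnerConfig(), scaler=scaler, bundle_dir=tmp_path / "bundle",
        )
        # re-predict from the in-memory bundle and from the reloaded one
        raw_ivs = X_iv.values * (scaler.maxs - scaler.mins) + scaler.mins
        first = bundle.predict(raw_ivs)
        reloaded = ModelBundle.load(tmp_path / "bundle")
        second = reloaded.predict(raw_ivs)
        pd.testing.assert_frame_equal(first, second)
        assert reloaded.feature_subset == subset

    def test_missing_subset_column_named_in_error(self, tmp_path):
        X_tr, y_tr, X_iv, y_iv, scaler = _scaled_split(seed=2)
        _, bundle = fit_and_validate(
            X_tr, y_tr, X_iv, y_iv, X_tr.column_names[:3], scaler=scaler,
        )
        raw_ivs = X_iv.values * (scaler.maxs - scaler.mins) + scaler.mins
        with pytest.raises(AlignmentError, match="f0"):
            bundle.predict(raw_ivs.drop(columns=["f0"]))
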