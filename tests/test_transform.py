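import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarflow import apply_minmax, fit_minmax, partition_data, scale_activities, scale_activity
from qsarflow.errors import (
    AlignmentError,
    DomainError,
    InternalConsistencyError,
    TooSmallError,
)
from qsarflow.featurize import FeatureMatrix


def _fm(values, names=None):
    arr = np.asarray(values, dtype=float)
    names = names or [f"c{i}" for i in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=[f"r{i}" for i in range(arr.shape[0])], columns=names)
    return FeatureMatrix(df, pd.Series("descriptor", index=df.columns))


class TestScaleActivity:
    def test_cutoff_values(self):
        assert scale_activity(10_000) == 0.0
        assert scale_activity(1) == 1.0
        assert scale_activity(100) == pytest.approx(0.5)

    def test_continuous_at_cutoffs(self):
        assert scale_activity(10_000 - 1e-6) == pytest.approx(0.0, abs=1e-9)
        assert scale_activity(1 + 1e-9) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            scale_activity(bad)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.floats(min_value=1e-3, max_value=1e7),
        b=st.floats(min_value=1e-3, max_value=1e7),
    )
    def test_monotone_non_increasing_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        assert scale_activity(lo) >= scale_activity(hi)
        assert 0.0 <= scale_activity(a) <= 1.0

    def test_skip_flag_passes_prenormalized_through(self):
        raw = pd.Series([0.1, 0.9], index=["a", "b"])
        out = scale_activities(raw, skip=True)
        assert out.skip_flag and list(out.values) == [0.1, 0.9]
        with pytest.raises(DomainError):
            scale_activities(pd.Series([1.5]), skip=True)


class TestMinMax:
    def test_fit_and_apply(self):
        fm = _fm([[0.0], [5.0], [10.0]])
        params = fit_minmax(fm)
        assert params.mins["c0"] == 0.0 and params.maxs["c0"] == 10.0
        scaled = apply_minmax(fm, params)
        assert list(scaled.values["c0"]) == [0.0, 0.5, 1.0]

    def test_external_rows_not_clipped(self):
        params = fit_minmax(_fm([[0.0], [10.0]]))
        out = apply_minmax(_fm([[12.0]]), params)
        assert out.values.iloc[0, 0] == pytest.approx(1.2)

    def test_training_columns_land_exactly_on_unit_interval(self):
        rng = np.random.default_rng(0)
        fm = _fm(rng.normal(size=(20, 5)) * 10)
        scaled = apply_minmax(fm, fit_minmax(fm))
        assert np.allclose(scaled.values.min(), 0.0)
        assert np.allclose(scaled.values.max(), 1.0)

    def test_constant_column_is_internal_error(self):
        with pytest.raises(InternalConsistencyError):
            fit_minmax(_fm([[1.0, 2.0]]))  # single row: every column constant

    def test_column_mismatch(self):
        params = fit_minmax(_fm([[0.0], [1.0]], names=["a"]))
        with pytest.raises(AlignmentError):
            apply_minmax(_fm([[0.0], [1.0]], names=["b"]), params)

    def test_identical_columns_get_identical_params(self):
        fm = _fm([[0.0, 0.0], [4.0, 4.0]], names=["a", "b"])
        params = fit_minmax(fm)
        assert params.mins["a"] == params.mins["b"]
        assert params.maxs["a"] == params.maxs["b"]


class TestPartition:
    def test_exact_75_25_for_n100(self):
        for seed in (0, 1, 42):
            split = partition_data([f"id{i}" for i in range(100)], 0.75, seed)
            assert len(split.train_ids) == 75 and len(split.ivs_ids) == 25
            assert set(split.train_ids).isdisjoint(split.ivs_ids)

    def test_reproducible_from_seed(self):
        ids = [f"id{i}" for i in range(30)]
        assert partition_data(ids, 0.75, 7).train_ids == partition_data(ids, 0.75, 7).train_ids

    def test_minimum_size_split(self):
        split = partition_data(list("abcd"), 0.75, 0)
        assert len(split.train_ids) == 3 and len(split.ivs_ids) == 1

    def test_different_seeds_differ(self):
        ids = [f"id{i}" for i in range(20)]
        assert partition_data(ids, 0.75, 1).train_ids != partition_data(ids, 0.75, 2).train_ids

    def test_too_small_and_bad_fraction(self):
        with pytest.raises(TooSmallError):
            partition_data(list("abc"), 0.75, 0)
        with pytest.raises(DomainError):
            partition_data(list("abcd"), 1.0, 0)

    @pytest.mark.parametrize("n,fraction", [(10, 0.5), (11, 0.75), (97, 0.8), (5, 0.9)])
    def test_counts_exact_and_exhaustive(self, n, fraction):
        ids = list(range(n))
        split = partition_data(ids, fraction, 3)
        expected = min(max(int(np.floor(fraction * n + 0.5)), 1), n - 1)
        assert len(split.train_ids) == expected
        assert sorted(split.train_ids + split.ivs_ids) == ids
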