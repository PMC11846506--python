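"""Monthly aggregation, moving averages, z-scoring, species filtering,
lag designs, and text round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gamvar import preprocess as pp


class TestAggregateMonthly:
    def test_constant_month(self):
        idx = pd.date_range("2001-03-01", "2001-03-30", freq="D")
        out = pp.aggregate_monthly(pd.Series(4.0, index=idx))
        assert out.iloc[0] == pytest.approx(4.0)

    def test_january_mean(self):
        idx = pd.date_range("2001-01-01", "2001-01-31", freq="D")
        out = pp.aggregate_monthly(pd.Series(np.arange(1.0, 32.0), index=idx))
        assert out.iloc[0] == pytest.approx(16.0)

    def test_empty_month_is_missing_not_zero(self):
        idx = pd.DatetimeIndex(["2001-01-15", "2001-03-15"])
        out = pp.aggregate_monthly(pd.Series([1.0, 2.0], index=idx))
        assert np.isnan(out.loc["2001-02-01"])

    def test_requires_dates(self):
        with pytest.raises(ValueError):
            pp.aggregate_monthly(pd.Series([1.0, 2.0]))


class TestMovingAverage:
    def test_constant_series(self):
        out = pp.moving_average(np.full(30, 3.5), window=12)
        assert np.allclose(out[11:], 3.5)
        assert np.isnan(out[:11]).all()

    def test_ramp(self):
        out = pp.moving_average(np.arange(1.0, 13.0), window=12)
        assert out[11] == pytest.approx(6.5)

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=25)
        assert np.allclose(pp.moving_average(x, window=1), x)

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            pp.moving_average(np.arange(5.0), window=6)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=5, max_size=60),
        st.integers(1, 5),
    )
    def test_matches_bruteforce(self, xs, w):
        x = np.array(xs)
        out = pp.moving_average(x, window=w)
        for t in range(x.size):
            if t < w - 1:
                assert np.isnan(out[t])
            else:
                assert out[t] == pytest.approx(x[t - w + 1 : t + 1].mean(), abs=1e-8)


class TestZscore:
    def test_hand_example(self):
        x = np.array([1.0, 2.0, 3.0])
        out = pp.zscore(x)
        assert np.allclose(out, np.array([-1.0, 0.0, 1.0]))  # sample sd = 1

    def test_sample_sd_convention(self):
        x = np.array([1.0, 2.0, 3.0, 10.0])
        out = pp.zscore(x)
        assert out[0] == pytest.approx((1 - x.mean()) / x.std(ddof=1))

    def test_training_moments_only(self):
        x = np.concatenate([np.arange(10.0), np.full(5, 100.0)])
        out = pp.zscore(x, reference=slice(0, 10))
        # training window has mean ~0; test values keep the training scale
        assert out[:10].mean() == pytest.approx(0.0, abs=1e-12)
        assert out[10] > 30.0  # not re-centered on the test window

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pp.zscore(np.ones(10))


class TestFilterSpecies:
    def _make(self, presence_rows):
        counts = np.array(presence_rows)
        return pp.CommunityTimeSeries(
            counts=counts,
            mask=np.ones_like(counts, dtype=bool),
            species_ids=[f"s{i}" for i in range(counts.shape[0])],
        )

    def test_absent_species_dropped(self):
        cts = self._make([[1] * 10, [0] * 10])
        out = pp.filter_species(cts)
        assert out.species_ids == ["s0"]

    def test_boundary_exactly_at_threshold_kept(self):
        # present in exactly 1/10 sessions at threshold 0.10: exclusion is
        # strictly below threshold
        cts = self._make([[1] * 10, [1] + [0] * 9])
        out = pp.filter_species(cts, min_presence=0.10)
        assert out.species_ids == ["s0", "s1"]

    def test_twenty_species_reduce_to_nine(self):
        # 9 common species + 11 below the 10% presence threshold
        T = 100
        rows = []
        for i in range(20):
            n_present = 50 if i < 9 else 5  # 50% vs 5% of sessions
            row = np.zeros(T, dtype=int)
            row[:n_present] = 1
            rows.append(row)
        cts = self._make(rows)
        out = pp.filter_species(cts, min_presence=0.10)
        assert out.n_species == 9
        assert out.species_ids == [f"s{i}" for i in range(9)]

    def test_all_removed_errors(self):
        cts = self._make([[0] * 10])
        with pytest.raises(ValueError):
            pp.filter_species(cts)

    def test_presence_counted_on_observed_sessions_only(self):
        counts = np.array([[1, 0, 0, 0, 0, 0, 0, 0, 0, 0]])
        mask = np.zeros((1, 10), dtype=bool)
        mask[0, :5] = True  # 1 of 5 observed sessions -> 20% presence
        cts = pp.CommunityTimeSeries(counts=counts, mask=mask, species_ids=["s0"])
        out = pp.filter_species(cts, min_presence=0.10)
        assert out.species_ids == ["s0"]


class TestLagDesign:
    def test_index_bookkeeping(self):
        x = np.array([10.0, 20, 30, 40, 50, 60, 70, 80])
        ld = pp.build_lag_design(x, max_lag=6, start=7)
        assert np.allclose(ld.value_matrix[0], [80, 70, 60, 50, 40, 30, 20])
        assert np.allclose(ld.lag_matrix[0], np.arange(7))

    def test_zero_lag_is_identity(self):
        x = np.arange(10.0)
        ld = pp.build_lag_design(x, max_lag=0, start=0)
        assert np.allclose(ld.value_matrix[:, 0], x)

    def test_constant_series(self):
        ld = pp.build_lag_design(np.full(20, 7.0), max_lag=6)
        assert np.allclose(ld.value_matrix, 7.0)

    def test_insufficient_leadin_names_requirement(self):
        with pytest.raises(ValueError, match="6 months"):
            pp.build_lag_design(np.arange(10.0), max_lag=6, start=3)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 6), st.integers(1, 20), st.integers(0, 424242))
    def test_value_matrix_invariant(self, L, T, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=L + T)
        ld = pp.build_lag_design(x, max_lag=L, start=L)
        for t in range(T):
            for l in range(L + 1):
                assert ld.value_matrix[t, l] == x[L + t - l]


class TestRoundTrip:
    def test_counts_roundtrip_exact(self, tmp_path, rng):
        counts = rng.poisson(3.0, size=(5, 30))
        mask = rng.random((5, 30)) > 0.1
        cts = pp.CommunityTimeSeries(
            counts=counts,
            mask=mask,
            species_ids=[f"sp{i}" for i in range(5)],
            dates=pd.date_range("2000-01-01", periods=30, freq="MS"),
        )
        path = tmp_path / "counts.csv"
        pp.write_counts(cts, path)
        back = pp.read_counts(path)
        assert back.species_ids == cts.species_ids
        assert np.array_equal(back.mask, cts.mask)
        assert np.array_equal(back.counts[back.mask], cts.counts[cts.mask])

    def test_time_grid_must_be_regular(self):
        with pytest.raises(ValueError):
            pp.CommunityTimeSeries(
                counts=np.ones((1, 3), dtype=int),
                mask=np.ones((1, 3), dtype=bool),
                species_ids=["a"],
                time_index=np.array([0, 2, 3]),
            )
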