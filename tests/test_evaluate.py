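"""Evaluation statistics against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from corticurve.errors import DegenerateTestError, ValidationError
from corticurve.evaluate import (
    compare_methods_permutation,
    compare_methods_t,
    duration_bias,
    fisher_average,
    obs_truncated,
    rank_accuracy,
    spearman,
    stability,
    z_test_per_schedule,
)
from corticurve.simulate import default_schedule_sets
from .conftest import make_series


def spearman_oracle(x, y):
    """Brute force: mid-ranks by sorting, then Pearson correlation."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size)
        i = 0
        sv = v[order]
        while i < v.size:
            j = i
            while j + 1 < v.size and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.linspace(0, 5, 50)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(10.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_undefined(self):
        with pytest.raises(DegenerateTestError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(5, 40)
            x = rng.integers(0, 8, n).astype(float)  # heavy ties
            y = rng.integers(0, 8, n).astype(float) + rng.normal(0, 0.1, n)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)


class TestFisherAverage:
    def test_identical_values_fixed_point(self):
        assert fisher_average([0.7, 0.7, 0.7]) == pytest.approx(0.7)

    def test_symmetric_values_cancel(self):
        assert fisher_average([0.5, -0.5]) == pytest.approx(0.0)

    def test_hand_computed_average(self):
        expected = np.tanh((np.arctanh(0.9) + np.arctanh(0.8)) / 2)
        assert fisher_average([0.9, 0.8]) == pytest.approx(expected, rel=1e-12)
        assert fisher_average([0.9, 0.8]) == pytest.approx(0.857, abs=1e-3)

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValidationError):
            fisher_average([1.0, 0.5])


class TestPairedT:
    def test_identical_vectors_null(self):
        res = compare_methods_t([0.9, 0.8, 0.85], [0.9, 0.8, 0.85])
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_constant_positive_difference_is_extreme(self):
        res = compare_methods_t([0.9, 0.8], [0.7, 0.6])
        assert res["p"] < 0.05 and res["direction"] == 1.0

    def test_large_consistent_difference_significant(self):
        rng = np.random.default_rng(1)
        b = rng.uniform(0.5, 0.7, 12)
        res = compare_methods_t(b + 0.2 + rng.normal(0, 0.01, 12), b)
        assert res["p"] < 0.05 and res["df"] == 11

    def test_representative_set_df(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0.8, 0.95, 12)
        assert compare_methods_t(a, a + rng.normal(0, 0.02, 12))["df"] == 11


class TestPermutation:
    def test_all_zero_differences(self):
        assert compare_methods_permutation([0.5] * 10, [0.5] * 10)["p"] == 1.0

    def test_ten_positive_differences_exact_p(self):
        a = np.linspace(0.80, 0.89, 10)
        res = compare_methods_permutation(a + 0.05, a)
        assert res["p"] == pytest.approx(2 / 1024)
        assert res["n_permutations"] == 1024

    def test_alternating_differences_near_one(self):
        a = np.full(10, 0.8)
        d = np.tile([0.05, -0.05], 5)
        assert compare_methods_permutation(a + d, a)["p"] > 0.9

    def test_matches_monte_carlo_permutation(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.7, 0.9, 10)
        b = a + rng.normal(0.02, 0.03, 10)
        exact = compare_methods_permutation(a, b)["p"]
        d = a - b
        draws = rng.choice([-1.0, 1.0], size=(100_000, 10))
        mc = float(np.mean(np.abs((draws * d).mean(axis=1)) >= abs(d.mean()) - 1e-15))
        assert exact == pytest.approx(mc, abs=4 * np.sqrt(exact * (1 - exact) / 100_000))


class TestZTest:
    def test_equal_correlations_null(self):
        res = z_test_per_schedule(0.9, 0.9, 1000)
        assert res["z"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_hand_computed_z(self):
        res = z_test_per_schedule(0.95, 0.90, 10_000)
        expected = (np.arctanh(0.95) - np.arctanh(0.90)) / np.sqrt(2 / 9997)
        assert res["z"] == pytest.approx(expected, rel=1e-12)
        assert res["z"] == pytest.approx(25.4, abs=0.1)

    def test_antisymmetric_in_arguments(self):
        a = z_test_per_schedule(0.95, 0.90, 500)["z"]
        b = z_test_per_schedule(0.90, 0.95, 500)["z"]
        assert a == pytest.approx(-b)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            z_test_per_schedule(0.9, 0.8, 3)


class TestRankAccuracy:
    @staticmethod
    def _tables(n=50, shift=0.0, permute=False, seed=0):
        rng = np.random.default_rng(seed)
        truth = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(n)],
            "AUCg": rng.normal(500, 100, n), "AUCi": rng.normal(150, 80, n),
            "reactivity": rng.normal(5, 2, n), "max_increase": np.abs(rng.normal(7, 2, n)),
        })
        est = truth.copy()
        for col in ("AUCg", "AUCi", "reactivity", "max_increase"):
            v = est[col].to_numpy()
            if permute:
                v = rng.permutation(v)
            est[col] = v + shift
        est["method"] = "OBS"
        est["schedule_id"] = "s"
        return est, truth

    def test_perfect_estimates(self):
        est, truth = self._tables()
        acc = rank_accuracy(est, truth)
        assert np.allclose(acc["r_s"], 1.0)
        assert np.allclose(acc["mae"], 0.0) and np.allclose(acc["bias"], 0.0)

    def test_constant_shift_keeps_rank_flips_bias(self):
        est, truth = self._tables(shift=2.0)
        acc = rank_accuracy(est, truth)
        assert np.allclose(acc["r_s"], 1.0)
        assert np.allclose(acc["bias"], -2.0)

    def test_permuted_estimates_uncorrelated(self):
        est, truth = self._tables(n=10_000, permute=True, seed=1)
        acc = rank_accuracy(est, truth)
        assert np.all(np.abs(acc["r_s"]) < 0.03)

    def test_unknown_participants_rejected(self):
        est, truth = self._tables()
        est.loc[0, "participant_id"] = "stranger"
        with pytest.raises(ValidationError):
            rank_accuracy(est, truth)


class TestStability:
    def test_pair_count(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(size=(40, 5)),
                             columns=[f"s{i}" for i in range(5)])
        res = stability(frame)
        assert len(res["pairwise"]) == 10

    def test_identical_columns_give_one(self):
        v = np.arange(30.0)
        frame = pd.DataFrame({"a": v, "b": v})
        assert stability(frame)["mean_r_s"] == pytest.approx(1.0)

    def test_needs_two_schedules(self):
        with pytest.raises(ValidationError):
            stability(pd.DataFrame({"a": np.arange(10.0)}))


class TestDurationTools:
    def test_duration_bias_of_schedule_independent_values(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=3000)
        durations = rng.choice([40.0, 60.0, 80.0], 3000)
        assert abs(duration_bias(values, durations)) < 0.05

    def test_single_duration_undefined(self):
        with pytest.raises(DegenerateTestError):
            duration_bias([1.0, 2.0, 3.0], [40.0, 40.0, 40.0])

    def test_obs_truncation_cutoff(self):
        sset = default_schedule_sets()["duration"]  # durations 40/60/80, shared to 40
        series = [
            make_series(np.arange(0, 81, 10.0), np.linspace(5, 9, 9),
                        participant_id="a"),
            make_series(np.arange(0, 41, 10.0), np.linspace(5, 7, 5),
                        participant_id="b"),
        ]
        allocation = {"a": "dur3", "b": "dur1"}
        table = obs_truncated(series, allocation, sset)
        assert set(table["method"]) == {"OBS_s"}
        # both series now span exactly [0, 40]
        assert table["AUCg"].iloc[0] == pytest.approx(
            np.trapezoid(np.linspace(5, 9, 9)[:5], np.arange(0, 41, 10.0))
        )

    def test_truncation_noop_for_single_schedule(self):
        from corticurve.simulate import SamplingSchedule, ScheduleSet
        from corticurve.evaluate import indicator_table_obs

        sched = SamplingSchedule("only", (0.0, 20.0, 40.0))
        sset = ScheduleSet("duration", (sched,))
        series = [make_series([0, 20, 40], [5, 8, 6], participant_id="a")]
        table = obs_truncated(series, {"a": "only"}, sset)
        obs = indicator_table_obs(series)
        assert table["AUCg"].iloc[0] == pytest.approx(obs["AUCg"].iloc[0])
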