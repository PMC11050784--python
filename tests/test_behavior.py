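"""SDT scoring, paired inference, Bayes factor and power analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from jolreact.behavior import (achieved_power, dprime, jzs_bf10, paired_test,
                               required_n, score_recognition)


def _trials(subject, condition, status, responses):
    return pd.DataFrame(dict(subject=subject, condition=condition,
                             item_status=status, response=list(responses)))


class TestScoring:
    def test_hits_are_responses_3_and_4(self):
        old = _trials("S01", "JOL", "old", [4, 4, 3, 3, 3, 2, 2, 1, 1, 1])
        new = _trials("S01", "new", "new", [1, 1, 4, 1])
        table = score_recognition(pd.concat([old, new]))
        row = table.iloc[0]
        assert row["hits"] == 5
        assert row["false_alarms"] == 1

    def test_extreme_rates_get_half_count_correction(self):
        old = _trials("S01", "JOL", "old", [1] * 10)
        new = _trials("S01", "new", "new", [4] * 8)
        row = score_recognition(pd.concat([old, new])).iloc[0]
        assert row["hit_rate"] == pytest.approx(1 / 20)   # 0 -> 1/(2N)
        assert row["fa_rate"] == pytest.approx(1 - 1 / 16)

    def test_new_items_shared_between_conditions(self):
        old_j = _trials("S01", "JOL", "old", [4] * 5 + [1] * 5)
        old_n = _trials("S01", "no-JOL", "old", [4] * 3 + [1] * 7)
        new = _trials("S01", "new", "new", [4, 1, 1, 1])
        table = score_recognition(pd.concat([old_j, old_n, new]))
        assert set(table["condition"]) == {"JOL", "no-JOL"}
        assert (table["false_alarms"] == 1).all()
        assert (table["n_new"] == 4).all()

    def test_tsv_round_trip(self, tmp_path):
        df = pd.concat([_trials("S01", "JOL", "old", [4, 2, 3]),
                        _trials("S01", "new", "new", [1, 4])])
        p = tmp_path / "b.tsv"
        df.to_csv(p, sep="\t", index=False)
        back = pd.read_csv(p, sep="\t")
        pd.testing.assert_frame_equal(back, df.reset_index(drop=True))

    def test_bad_values_rejected(self):
        with pytest.raises(ValueError, match="item_status"):
            score_recognition(_trials("S01", "JOL", "studied", [3]))
        with pytest.raises(ValueError, match="responses"):
            score_recognition(_trials("S01", "JOL", "old", [5]))


class TestDprime:
    # (hits, n_old, fas, n_new) -> (d', c) frozen from the closed form
    # z(H) - z(F) / -(z(H)+z(F))/2 evaluated with the inverse normal CDF
    HAND_TABLE = [
        (8, 10, 2, 10, 1.6832425, 0.0),
        (9, 10, 1, 10, 2.5631031, 0.0),
        (7, 10, 3, 10, 1.0488010, 0.0),
        (8, 10, 5, 10, 0.8416212, -0.4208106),
        (5, 10, 2, 10, 0.8416212, 0.4208106),
        (6, 10, 4, 10, 0.5066942, 0.0),
        (9, 10, 5, 10, 1.2815516, -0.6407758),
        (19, 20, 1, 20, 3.2897073, 0.0),
        (15, 20, 5, 20, 1.3489795, 0.0),
        (30, 40, 10, 40, 1.3489795, 0.0),
        (35, 40, 2, 40, 2.7952030, 0.2472521),
        (12, 20, 8, 20, 0.5066942, 0.0),
    ]

    @pytest.mark.parametrize("h,no,f,nn,d,c", HAND_TABLE)
    def test_hand_computed_table(self, h, no, f, nn, d, c):
        res = dprime(h, no, f, nn)
        assert res.d_prime == pytest.approx(d, abs=1e-6)
        assert res.criterion_c == pytest.approx(c, abs=1e-6)

    def test_uncorrected_symmetric_pair(self):
        # H = 0.8, F = 0.2 -> d' = 2 z(0.8) = 1.683
        res = dprime(8, 10, 2, 10)
        assert res.d_prime == pytest.approx(2 * stats.norm.ppf(0.8), abs=1e-9)

    def test_no_discrimination_flags_cprime(self):
        res = dprime(8, 10, 8, 10)
        assert res.d_prime == 0.0
        assert np.isnan(res.criterion_cprime)

    @settings(deadline=None, max_examples=50)
    @given(h=st.integers(0, 20), f=st.integers(0, 20))
    def test_swapping_hits_and_fas_negates_dprime(self, h, f):
        a = dprime(h, 20, f, 20)
        b = dprime(f, 20, h, 20)
        assert a.d_prime == pytest.approx(-b.d_prime, abs=1e-12)

    def test_cprime_is_c_over_d(self):
        res = dprime(16, 20, 4, 20)
        assert res.criterion_cprime == pytest.approx(
            res.criterion_c / res.d_prime)


class TestPairedTest:
    def test_matches_scipy_on_random_data(self, rng):
        x, y = rng.standard_normal((2, 27))
        res = paired_test(x, y)
        ref = stats.ttest_rel(x, y)
        assert res.t_value == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.df == 26
        assert res.cohen_d == pytest.approx(res.t_value / np.sqrt(27))
        lo, hi = stats.t.interval(0.95, 26, loc=(x - y).mean(),
                                  scale=stats.sem(x - y))
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_zero_mean_difference_gives_t_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        res = paired_test(x, y)
        assert res.t_value == pytest.approx(0.0)

    def test_type_one_error_near_nominal_under_null(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(200):
            x, y = rng.standard_normal((2, 27))
            if paired_test(x, y).p_value < 0.05:
                rejections += 1
        assert 0.01 <= rejections / 200 <= 0.10


class TestBayesFactor:
    def test_agrees_with_brute_force_grid(self):
        # independent oracle: trapezoid rule on a fine wide grid
        for t, n in [(0.5, 5), (2.0, 27), (5.0, 27), (8.0, 100)]:
            grid = np.linspace(-60, 60, 400001)
            num = np.trapezoid(
                stats.nct.pdf(t, n - 1, grid * np.sqrt(n))
                * stats.cauchy.pdf(grid, 0, np.sqrt(2) / 2), grid)
            oracle = num / stats.t.pdf(t, n - 1)
            assert jzs_bf10(t, n) == pytest.approx(oracle, rel=1e-3)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        for t, n in [(1.0, 10), (3.5, 27), (8.031, 27)]:
            ref = float(pg.bayesfactor_ttest(t, n, paired=True))
            assert jzs_bf10(t, n) == pytest.approx(ref, rel=1e-3)

    def test_null_favoring_at_t_zero(self):
        assert jzs_bf10(0.0, 27) < 1.0
        assert jzs_bf10(0.0, 5) < 1.0

    def test_monotone_in_t(self):
        values = [jzs_bf10(t, 27) for t in np.linspace(0, 10, 21)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_one_sided_doubles_for_large_positive_t(self):
        two = jzs_bf10(8.0, 27, tails="two")
        one = jzs_bf10(8.0, 27, tails="one")
        assert one == pytest.approx(2 * two, rel=1e-4)


class TestPower:
    def test_medium_effect_requires_27_pairs(self):
        q = required_n(0.5, alpha=0.05, target_power=0.80, tails="one")
        assert q.result_n == 27
        assert q.achieved_power >= 0.80

    def test_large_effect_beta_below_point_001(self):
        assert 1 - achieved_power(27, 1.228, 0.05, "one") < 0.001

    @pytest.mark.parametrize("d,power", [(0.3, 0.8), (0.5, 0.9), (0.8, 0.95)])
    def test_required_n_inverts_achieved_power(self, d, power):
        q = required_n(d, 0.05, power, "one")
        assert achieved_power(q.result_n, d, 0.05, "one") >= power
        if q.result_n > 2:
            assert achieved_power(q.result_n - 1, d, 0.05, "one") < power

    def test_doubling_effect_never_increases_n(self):
        for d in (0.2, 0.4, 0.8):
            assert required_n(2 * d).result_n <= required_n(d).result_n
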