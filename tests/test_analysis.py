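"""Outcome measures: Bernoulli summaries, rates, pairwise deltas and
hypothesis tests (with exact-enumeration and simulation oracles)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from epimem.analysis import (
    PerformanceSummary,
    bernoulli_sd,
    compare_conditions,
    pairwise_deltas,
    performance_summary,
    rederive_choices,
    results_table,
    trial_average_rate,
)
from epimem.task import TrialResult


class TestBernoulliSummary:
    @pytest.mark.parametrize("p,n,sd", [
        (83.21, 143, 3.12),
        (64.28, 56, 6.40),
        (50.0, 100, 5.00),
    ])
    def test_sd_closed_form_to_two_decimals(self, p, n, sd):
        # printed values appear truncated rather than rounded
        # (SD(83.21, 143) = 3.1257), so compare at printed precision
        assert abs(bernoulli_sd(p, n) - sd) < 0.01

    def test_summary_from_trials(self):
        trials = [TrialResult(i, "assessment", 0, 1, 20, 10, "new",
                              hit=i < 7, rewarded_item=None, scored=True)
                  for i in range(10)]
        s = performance_summary(trials)
        assert s.n == 10 and s.hits == 7
        assert s.p == pytest.approx(70.0)
        assert s.sd == pytest.approx(100 * math.sqrt(0.7 * 0.3 / 10))

    def test_excluded_trials_not_counted(self):
        trials = [TrialResult(1, "assessment", 0, 1, 20, 10, "new", True,
                              None, scored=True),
                  TrialResult(2, "assessment", 0, 1, 20, 10, "new", True,
                              None, scored=False, excluded=True)]
        assert performance_summary(trials).n == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            performance_summary([])


class TestRates:
    def test_rate_arithmetic(self):
        t = np.linspace(100.0, 349.0, 10)
        gid = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0])
        rate = trial_average_rate(t, gid, np.arange(30), (100.0, 350.0))
        assert rate == pytest.approx(10 / (30 * 0.25))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            trial_average_rate(np.array([]), np.array([]), np.arange(3),
                               (10.0, 10.0))

    def test_no_spikes_is_zero(self):
        assert trial_average_rate(np.array([]), np.array([], int),
                                  np.arange(3), (0.0, 100.0)) == 0.0


class TestCompare:
    def test_identical_groups_p_one(self):
        _, p = compare_conditions((10, 10), (10, 10), "fisher")
        assert p == pytest.approx(1.0)
        x = np.arange(20.0)
        for test in ("mannwhitney", "ttest"):
            _, p = compare_conditions(x, x, test)
            assert p > 0.95

    def test_fisher_on_reconstructed_counts(self):
        """Hit/miss counts rebuilt from the printed means and n of the
        two arrangements (83.21% of 143 vs 93.33% of 99) differ
        significantly; the exact two-sided p is 0.0311."""
        _, p = compare_conditions((119, 24), (92, 7), "fisher")
        assert p == pytest.approx(0.031072, rel=1e-4)
        assert p < 0.05

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals summing hypergeometric point masses
        not exceeding the observed one, for all tables with small
        margins."""
        for a, b, c, d in itertools.product(range(0, 7, 2), repeat=4):
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            n = a + b + c + d
            dist = hypergeom(n, a + b, a + c)
            p_obs = dist.pmf(a)
            p_exact = sum(dist.pmf(k) for k in range(a + c + 1)
                          if dist.pmf(k) <= p_obs * (1 + 1e-9))
            _, p_fisher = compare_conditions((a, b), (c, d), "fisher")
            assert p_fisher == pytest.approx(min(p_exact, 1.0), rel=1e-6)

    def test_mannwhitney_type_one_error_rate(self):
        """Under the null (same distribution) the two-sided U test
        rejects at ~alpha = 0.05."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = rng.normal(size=25)
            b = rng.normal(size=25)
            _, p = compare_conditions(a, b, "mannwhitney")
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.02 < rate < 0.08

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions(np.array([]), np.arange(3.0), "ttest")
        with pytest.raises(ValueError):
            compare_conditions((0, 0), (1, 1), "fisher")


class TestPairwiseDeltas:
    def _mk(self, f_old, f_new, ww, bias, rec):
        trials = [TrialResult(1, "assessment", 0, 1, f_old, f_new, "new",
                              True, None, scored=True)]
        meta = [{"trial_index": 1,
                 "within_w": {0: ww[0], 1: ww[1]},
                 "bias": {0: bias[0], 1: bias[1]},
                 "recency": {0: rec[0], 1: rec[1]}}]
        return trials, meta

    def test_identical_statistics_give_zero_deltas(self):
        trials, meta = self._mk(12.0, 12.0, (1.0, 1.0), (-5.0, -5.0),
                                (3, 3))
        df = pairwise_deltas(trials, meta)
        assert (df[["d_rate", "d_weight", "d_bias", "d_trial"]]
                .iloc[0] == 0).all()

    def test_signed_differences_old_minus_new(self):
        trials, meta = self._mk(20.0, 10.0, (0.8, 1.2), (-4.0, -9.0),
                                (30, 40))
        row = pairwise_deltas(trials, meta).iloc[0]
        assert row.d_rate == 10.0
        assert row.d_weight == pytest.approx(-0.4)
        assert row.d_bias == pytest.approx(5.0)
        assert row.d_trial == -10

    def test_missing_snapshot_raises(self):
        trials, _ = self._mk(1, 1, (0, 0), (0, 0), (0, 0))
        with pytest.raises(ValueError):
            pairwise_deltas(trials, [])


def test_choice_rederivation_consistency():
    """Recomputing choices from recorded rates reproduces hit flags."""
    trials = [
        TrialResult(1, "assessment", 0, 1, 20.0, 10.0, "new", True, 1, True),
        TrialResult(2, "assessment", 2, 3, 20.0, 19.0, None, False, None,
                    True),
    ]
    df = results_table(trials)
    assert list(rederive_choices(df)) == [t.hit for t in trials]
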