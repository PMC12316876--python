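"""Outcome measures: firing rates, performance, pairwise differences,
hypothesis tests.

Performance is summarised as a hit rate with a Bernoulli standard
deviation, SD(%) = 100 * sqrt(p (1-p) / n) for hit probability p over n
trials. Pairwise differences (Delta f, Delta w, Delta b, Delta trial)
are computed between the old and new item of each Assessment pair, on
matched trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import TrialResult


@dataclass
class PerformanceSummary:
    n: int
    hits: int

    @property
    def p(self) -> float:
        """Hit rate in percent."""
        return 100.0 * self.hits / self.n

    @property
    def sd(self) -> float:
        """Bernoulli standard deviation of the hit rate, in percent."""
        frac = self.hits / self.n
        return 100.0 * math.sqrt(frac * (1.0 - frac) / self.n)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"PerformanceSummary(n={self.n}, hits={self.hits}, "
                f"p={self.p:.2f}%, sd={self.sd:.2f}%)")


def bernoulli_sd(p_percent: float, n: int) -> float:
    """SD (%) of a hit rate given in percent, from the Bernoulli model."""
    if n < 1:
        raise ValueError("n must be at least 1")
    p = p_percent / 100.0
    return 100.0 * math.sqrt(p * (1.0 - p) / n)


def trial_average_rate(
    spike_t: np.ndarray,
    spike_gid: np.ndarray,
    assembly: np.ndarray,
    window: tuple[float, float],
) -> float:
    """Mean single-cell firing rate (Hz) of ``assembly`` inside
    ``window`` = [t0, t1) in ms."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    assembly = np.asarray(assembly)
    if assembly.size == 0:
        raise ValueError("empty assembly")
    sel = (spike_t >= t0) & (spike_t < t1)
    count = np.isin(spike_gid[sel], assembly).sum()
    return 1000.0 * count / (assembly.size * (t1 - t0))


def performance_summary(trials: Sequence[TrialResult]) -> PerformanceSummary:
    """Hit rate over the scored (Assessment, non-excluded) trials."""
    scored = [t for t in trials if t.scored]
    if not scored:
        raise ValueError("no scored trials")
    return PerformanceSummary(n=len(scored),
                              hits=sum(t.hit for t in scored))


@dataclass
class PairwiseDeltas:
    """Old-minus-new differences for one Assessment pair."""

    trial_index: int
    d_rate: float      # Delta f_old-new, Hz
    d_weight: float    # Delta w_old-new, nS (effective within-network)
    d_bias: float      # Delta b_old-new, pA
    d_trial: float     # Delta trial_old-new (recency index difference)


def pairwise_deltas(
    trials: Sequence[TrialResult],
    trial_meta: Sequence[dict],
) -> pd.DataFrame:
    """Per-pair old-minus-new differences from scored Assessment trials.

    ``trial_meta`` carries, per trial, the effective within-network
    weights (static weight times instantaneous STP factor, AMPA+NMDA
    summed), mean bias currents and most-recent-activation indices of
    the two items, sampled at the decision time.
    """
    if len(trial_meta) < len(trials):
        raise ValueError("missing decision-time snapshots for some trials")
    rows = []
    # positional pairing: trial indices restart per session, so the two
    # sequences are matched element-wise and cross-checked
    for tr, m in zip(trials, trial_meta):
        if m["trial_index"] != tr.trial_index:
            raise ValueError("trial/snapshot sequences out of register")
        if not tr.scored or tr.old_item is None:
            continue
        rows.append(PairwiseDeltas(
            trial_index=tr.trial_index,
            d_rate=tr.f_old - tr.f_new,
            d_weight=m["within_w"][tr.old_item] - m["within_w"][tr.new_item],
            d_bias=m["bias"][tr.old_item] - m["bias"][tr.new_item],
            d_trial=m["recency"][tr.old_item] - m["recency"][tr.new_item],
        ))
    return pd.DataFrame([vars(r) for r in rows])


def compare_conditions(
    a,
    b,
    test: str = "fisher",
) -> tuple[float, float]:
    """Two-condition hypothesis test; returns (statistic, p-value).

    * ``fisher``: a, b are (hits, misses) tuples or PerformanceSummary;
      two-sided exact test on the 2x2 table.
    * ``mannwhitney``: a, b are samples; two-sided U test with normal
      approximation and tie correction.
    * ``ttest``: a, b are samples; Welch two-sample t test, two-sided.
    """
    if test == "fisher":
        def as_counts(x):
            if isinstance(x, PerformanceSummary):
                return (x.hits, x.n - x.hits)
            return tuple(x)
        table = np.array([as_counts(a), as_counts(b)])
        if table.sum(axis=1).min() == 0:
            raise ValueError("empty group")
        res = stats.fisher_exact(table, alternative="two-sided")
        return float(res[0]), float(res[1])
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if test == "ttest":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def results_table(trials: Iterable[TrialResult]) -> pd.DataFrame:
    """Per-trial results as a tidy DataFrame."""
    return pd.DataFrame([vars(t) for t in trials])


def rederive_choices(df: pd.DataFrame, threshold: float = 0.85) -> pd.Series:
    """Recompute hit flags from recorded rates (consistency check)."""
    return (df["f_new"] < threshold * df["f_old"]) & df["old_item"].notna()
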