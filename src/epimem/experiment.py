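"""Experiment driver: builder -> schedule -> engine -> analysis.

``run_experiment`` executes the requested task variant over a number of
seeded sessions against one preloaded network, pools the Assessment
trials and returns the aggregate performance together with per-trial
records, pairwise-difference tables and snapshots. All randomness is
derived from the experiment seed; the same configuration and seed
reproduce the same results bundle.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .analysis import PerformanceSummary, pairwise_deltas, performance_summary, results_table
from .engine import SessionResult, run_session
from .network import NetworkModel, ablate, build_network
from .params import PROFILES, ExperimentConfig
from .task import generate_schedule


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    variant: str
    seed: int
    summary: PerformanceSummary
    trials: pd.DataFrame
    deltas: pd.DataFrame
    sessions: list[SessionResult] = field(default_factory=list)
    config_hash: str = ""

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.trials.assign(config_hash=self.config_hash).to_csv(
            os.path.join(outdir, f"trials_{self.variant}.csv"), index=False)
        if len(self.deltas):
            self.deltas.assign(config_hash=self.config_hash).to_csv(
                os.path.join(outdir, f"deltas_{self.variant}.csv"),
                index=False)
        with open(os.path.join(outdir, f"summary_{self.variant}.json"),
                  "w") as fh:
            json.dump({
                "variant": self.variant, "seed": self.seed,
                "n": self.summary.n, "hits": self.summary.hits,
                "hit_rate_percent": self.summary.p,
                "sd_percent": self.summary.sd,
                "config_hash": self.config_hash,
            }, fh, indent=1)


def n_items_for(config: ExperimentConfig) -> int:
    return PROFILES[config.profile].n_items


def build_for_experiment(config: ExperimentConfig,
                         seed: int) -> NetworkModel:
    cfg = config.apply_profile()
    prof = PROFILES[config.profile]
    n_ctx = 3 if config.variant == "extra_context" else prof.n_contexts
    return build_network(cfg, seed=seed, n_items=prof.n_items,
                         n_contexts=n_ctx)


def run_experiment(
    config: ExperimentConfig,
    seed: int,
    n_sessions: Optional[int] = None,
    min_trials: Optional[int] = None,
    model: Optional[NetworkModel] = None,
    ablate_disynaptic: bool = False,
    keep_sessions: bool = False,
) -> ExperimentResult:
    """Run the configured variant over seeded sessions and pool trials.

    Each session uses a fresh plastic state (associative weights reset
    to the independent zero-weight state) on the same preloaded
    network; session seeds are derived from ``seed``. ``min_trials``
    keeps adding sessions until that many scored Assessment pairs have
    accumulated. ``ablate_disynaptic`` severs the learned negative
    between-network weights at the start of every Assessment block.
    """
    cfg = config.apply_profile()
    prof = PROFILES[config.profile]
    n_ctx = 3 if config.variant == "extra_context" else prof.n_contexts
    if model is None:
        model = build_network(cfg, seed=seed, n_items=prof.n_items,
                              n_contexts=n_ctx)
        n_items = prof.n_items
    else:
        n_items = sum(p.network == 0 for p in model.patterns)
    rng = np.random.default_rng([seed, 0xABCD])
    all_trials = []
    all_meta = []
    sessions = []
    n_sessions = n_sessions or cfg.n_sessions
    scored = 0
    k = 0
    while True:
        sched_seed = int(rng.integers(2**31))
        sess_seed = int(rng.integers(2**31))
        sched = generate_schedule(cfg.variant, sched_seed,
                                  n_items=n_items, stim=cfg.stimulus)
        res = run_session(
            model, sched, cfg, seed=sess_seed,
            ablate_disynaptic_at_assessment=ablate_disynaptic)
        all_trials.extend(res.trials)
        all_meta.extend(res.trial_meta)
        scored += sum(t.scored for t in res.trials)
        if keep_sessions:
            sessions.append(res)
        k += 1
        if min_trials is not None:
            if scored >= min_trials:
                break
        elif k >= n_sessions:
            break

    summary = performance_summary(all_trials)
    deltas = pairwise_deltas(all_trials, all_meta)
    return ExperimentResult(
        config=cfg, variant=cfg.variant, seed=seed, summary=summary,
        trials=results_table(all_trials), deltas=deltas,
        sessions=sessions, config_hash=cfg.config_hash(),
    )


__all__ = [
    "ExperimentResult", "run_experiment", "build_for_experiment",
    "ablate", "n_items_for",
]
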