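#!/usr/bin/env python
"""Grid calibration of the reduced-scale profile.

The reduced profile (4 HCs x 8 MCs per network, 8 items) has smaller
assemblies and fan-ins than the full-scale model, so the cue, basket and
associative gains must be re-tuned to restore the full-scale operating
regime: cue-driven assembly activation without spontaneous attractor
transitions, and a reference (Arrangement 1) hit rate in the
behavioural range. This script evaluates candidate gain multipliers
over seeded sessions and reports hit rates and rate-ratio medians; the
chosen multipliers are recorded as ``REDUCED_PROFILE`` defaults.

Usage:
    python scripts/calibrate_reduced.py --seed 1 --sessions 6 \
        --grid "ctx_stim_scale=1.5,2.0;assoc_scale_neg=16,32"
"""

from __future__ import annotations

import argparse
import dataclasses
import itertools
import json
import time

import numpy as np

from epimem.engine import run_session
from epimem.network import build_network
from epimem.params import PROFILES, REDUCED_PROFILE, ExperimentConfig
from epimem.task import generate_schedule


def evaluate(profile_kwargs: dict, seed: int, n_sessions: int,
             variants=("exp1_arr1", "exp1_arr2")) -> dict:
    PROFILES["reduced"] = dataclasses.replace(REDUCED_PROFILE,
                                              **profile_kwargs)
    cfg = ExperimentConfig(profile="reduced").apply_profile()
    prof = PROFILES["reduced"]
    model = build_network(cfg, seed=seed, n_items=prof.n_items,
                          n_contexts=2)
    out = {}
    for variant in variants:
        hits = tot = 0
        ratios = []
        for s in range(n_sessions):
            sched = generate_schedule(variant, seed=seed * 1000 + s,
                                      n_items=prof.n_items)
            res = run_session(model, sched, cfg, seed=seed * 2000 + s)
            for r in res.trials:
                if r.scored:
                    tot += 1
                    hits += r.hit
                    ratios.append(r.f_new / max(r.f_old, 1e-9))
        out[variant] = {
            "hits": hits, "n": tot,
            "hit_rate": 100.0 * hits / max(tot, 1),
            "median_ratio": float(np.median(ratios)) if ratios else None,
        }
    return out


def parse_grid(spec: str) -> list[dict]:
    axes = []
    for axis in spec.split(";"):
        key, _, vals = axis.partition("=")
        axes.append([(key.strip(), float(v)) for v in vals.split(",")])
    return [dict(combo) for combo in itertools.product(*axes)]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--sessions", type=int, default=6)
    ap.add_argument("--grid", default="assoc_scale_pos=4,8;assoc_scale_neg=16,32")
    ap.add_argument("--out", default=None)
    args = ap.parse_args()

    results = []
    for kwargs in parse_grid(args.grid):
        t0 = time.time()
        res = evaluate(kwargs, args.seed, args.sessions)
        res["profile"] = kwargs
        res["wall_s"] = round(time.time() - t0, 1)
        results.append(res)
        print(json.dumps(res))
    if args.out:
        with open(args.out, "w") as fh:
            json.dump(results, fh, indent=1)


if __name__ == "__main__":
    main()
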