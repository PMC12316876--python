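"""Task protocol: schedule construction, arrangement predicates, ledger
bookkeeping and the decision/reward rule."""

import numpy as np
import pytest

from epimem.task import (
    VARIANTS,
    ItemStatusLedger,
    ScheduleError,
    TrialSpec,
    decide_and_reward,
    generate_schedule,
    validate_schedule,
)


@pytest.mark.parametrize("variant", VARIANTS)
@pytest.mark.parametrize("n_items", [8, 16])
def test_schedules_validate_across_seeds(variant, n_items):
    """Every generated schedule passes the independent validator (which
    replays the ledger and re-checks all predicates)."""
    for seed in range(25):
        sched = generate_schedule(variant, seed, n_items=n_items)
        validate_schedule(sched)  # raises on violation


def test_schedule_reproducibility():
    a = generate_schedule("exp1_arr1", 7, n_items=16)
    b = generate_schedule("exp1_arr1", 7, n_items=16)
    assert [(t.items, t.t_start, t.block) for t in a.trials] == \
        [(t.items, t.t_start, t.block) for t in b.trials]
    c = generate_schedule("exp1_arr1", 8, n_items=16)
    assert [t.items for t in a.trials] != [t.items for t in c.trials]


def test_arrangement1_recency_predicate():
    """In Arrangement 1 every assessed new item was activated more
    recently (before Assessment) than its old partner."""
    for seed in range(20):
        sched = generate_schedule("exp1_arr1", seed, n_items=16)
        recency = {}
        assess = []
        for tr in sched.trials:
            if tr.block == "assessment":
                assess.append((recency[tr.new_item], recency[tr.old_item]))
            for it in tr.items:
                recency[it] = tr.trial_index
        assert all(rn > ro for rn, ro in assess)


def test_arrangement2_reverses_recency():
    """In Arrangement 2 the old item's final pre-Assessment stimulation
    follows the new item's most recent activation."""
    for seed in range(20):
        sched = generate_schedule("exp1_arr2", seed, n_items=16)
        recency = {}
        assess = []
        for tr in sched.trials:
            if tr.block == "assessment":
                assess.append((recency[tr.new_item], recency[tr.old_item]))
            for it in tr.items:
                recency[it] = tr.trial_index
        assert all(ro > rn for rn, ro in assess)


def test_assessment_pairs_never_repeat_encoding_pairs():
    for seed in range(20):
        sched = generate_schedule("exp1_arr1", seed, n_items=16)
        seen = set()
        for tr in sched.trials:
            if tr.block == "assessment":
                assert frozenset(tr.items) not in seen
            seen.add(frozenset(tr.items))


def test_extra_context_exclusion_tagging():
    """Pairs whose old item became the more recent through the extra
    context-C block are tagged and excluded from scoring."""
    any_excluded = False
    for seed in range(30):
        sched = generate_schedule("extra_context", seed, n_items=16)
        for tr in sched.assessment_trials:
            assert tr.scored != tr.excluded
            any_excluded |= tr.excluded
    assert any_excluded


def test_unbalanced_adds_new_item_repetitions():
    """The unbalanced variant stimulates future new-in-context-A items
    more often in context-B than the reference task does."""
    ref = generate_schedule("exp1_arr1", 3, n_items=16)
    unb = generate_schedule("unbalanced", 3, n_items=16)

    def b_counts(sched):
        counts = {}
        new_items = {t.new_item for t in sched.assessment_trials}
        for tr in sched.trials:
            if tr.block == "encoding_B":
                for it in tr.items:
                    if it in new_items:
                        counts[it] = counts.get(it, 0) + 1
        return counts

    assert sum(b_counts(unb).values()) > sum(b_counts(ref).values())


def test_ledger_status_is_monotone():
    led = ItemStatusLedger()
    assert not led.is_old(3, 100)
    led.record(3, 100, trial_index=5)
    assert led.is_old(3, 100)
    assert not led.is_old(3, 101)
    led.record(3, 100, trial_index=9)
    assert led.is_old(3, 100)
    assert led.recency(3) == 9


class TestDecideAndReward:
    def trial(self, old=0, new=1, block="assessment", scored=True):
        return TrialSpec(10, block, 100, old, new, 0.0, old_item=old,
                         new_item=new, scored=scored)

    def test_clear_margin_is_hit_and_rewarded(self):
        led = ItemStatusLedger()
        led.record(0, 100, 1)
        res = decide_and_reward(self.trial(), {0: 20.0, 1: 10.0}, led,
                                "exp1_arr1")
        assert res.choice == "new" and res.hit
        assert res.rewarded_item == 1

    def test_insufficient_margin_is_error(self):
        led = ItemStatusLedger()
        led.record(0, 100, 1)
        res = decide_and_reward(self.trial(), {0: 20.0, 1: 19.0}, led,
                                "exp1_arr1")
        assert res.choice is None and not res.hit
        assert res.rewarded_item is None

    def test_degenerate_silent_trial_is_error(self):
        led = ItemStatusLedger()
        res = decide_and_reward(self.trial(), {0: 0.0, 1: 0.0}, led,
                                "exp1_arr1")
        assert not res.hit and res.rewarded_item is None

    def test_wrong_selection_is_miss(self):
        led = ItemStatusLedger()
        led.record(0, 100, 1)
        res = decide_and_reward(self.trial(), {0: 10.0, 1: 20.0}, led,
                                "exp1_arr1")
        assert not res.hit
        assert res.rewarded_item is None  # the old item earns nothing

    def test_reverse_scheme_rewards_old_item(self):
        led = ItemStatusLedger()
        led.record(0, 100, 1)
        res = decide_and_reward(self.trial(), {0: 20.0, 1: 10.0}, led,
                                "reverse_reward")
        assert res.hit
        assert res.rewarded_item == 0  # reward attaches to the old item

    def test_reverse_scheme_reward_is_repeatable(self):
        """Both-old pairs under the reversed contingency reward the
        singled-out item again (no once-only restriction)."""
        led = ItemStatusLedger()
        led.record(0, 100, 1)
        led.record(1, 100, 2)
        tr = TrialSpec(10, "encoding_A", 100, 0, 1, 0.0)
        res = decide_and_reward(tr, {0: 20.0, 1: 10.0}, led,
                                "reverse_reward")
        assert res.rewarded_item == 1  # selected (lower-rate) old item

    def test_reverse_scheme_failed_discrimination_unrewarded(self):
        led = ItemStatusLedger()
        led.record(0, 100, 1)
        res = decide_and_reward(self.trial(), {0: 10.0, 1: 20.0}, led,
                                "reverse_reward")
        assert not res.hit
        assert res.rewarded_item is None

    def test_reward_only_once_under_standard_scheme(self):
        """An item already old in the current context is never rewarded
        again under the standard rule."""
        led = ItemStatusLedger()
        led.record(0, 100, 1)
        led.record(1, 100, 2)  # the 'new' item has actually been shown
        tr = TrialSpec(10, "encoding_B", 100, 0, 1, 0.0)
        res = decide_and_reward(tr, {0: 20.0, 1: 10.0}, led, "exp1_arr1")
        assert res.rewarded_item is None


def test_unknown_variant_rejected():
    with pytest.raises(ScheduleError):
        generate_schedule("nope", 0)


def test_odd_item_count_rejected():
    with pytest.raises(ScheduleError):
        generate_schedule("exp1_arr1", 0, n_items=7)
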