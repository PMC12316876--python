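"""Item-in-context task protocol: schedules, bookkeeping, decisions.

A session consists of Item-Context Encoding blocks followed by a Memory
Assessment block. Within every trial the two items of a pair are cued
serially (250 ms each, 200 ms apart) while the current context pattern
is cued continuously. An item becomes *old-in-context* the moment it has
been presented in that context; Assessment pairs one never-shown-in-
target-context item (new) with a randomly chosen old item, each item
assessed exactly once, and no Assessment pair repeats an Encoding pair.

Arrangements fix the recency relation of Assessment pairs:

* Arrangement 1 (control): the new item's most recent pre-Assessment
  activation is *later* than the old item's (recency conflicts with
  episodic memory);
* Arrangement 2: reversed — the old item's final pre-Assessment
  stimulation follows the new item's most recent activation (recency and
  episodic memory act synergistically).

Variants: ``exp1_arr1`` (A->B->Assessment in A), ``exp2_arr1``
(A->B->A->Assessment in B), their Arrangement-2 counterparts,
``unbalanced`` (extra repetitions of future new-in-context-A items in
context-B), ``extra_context`` (a context-C block precedes Assessment;
pairs whose old item became more recent in C are excluded from the
Arrangement-1 analysis), and ``reverse_reward`` (reward attaches to
old-in-context selections, repeatable per activation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .params import StimulusParams

VARIANTS = (
    "exp1_arr1", "exp2_arr1", "exp1_arr2", "exp2_arr2",
    "unbalanced", "extra_context", "reverse_reward",
)
_VARIANT_IDX = {v: i for i, v in enumerate(VARIANTS)}

# trial phase layout (ms, relative to trial start)
ITEM1_ON = 0.0
DECISION_PHASE = 800.0     # time reserved after the second item
BLOCK_GAP = 500.0          # silent gap at context transitions


class ScheduleError(RuntimeError):
    pass


@dataclass
class TrialSpec:
    """One pair presentation."""

    trial_index: int            # 1-based, global within the session
    block: str                  # encoding_A / encoding_B / encoding_C / assessment
    context: int                # context pattern id
    item_first: int
    item_second: int
    t_start: float              # ms
    old_item: Optional[int] = None   # designated old-in-context item, if any
    new_item: Optional[int] = None
    scored: bool = False        # counts toward performance statistics
    excluded: bool = False      # excluded from the arrangement analysis

    @property
    def items(self) -> tuple[int, int]:
        return (self.item_first, self.item_second)


@dataclass
class Event:
    t: float
    kind: str        # context_on / context_off / item_stim / assessment_marker
    pattern: int
    block: str
    trial_index: int


@dataclass
class ItemStatus:
    presentations: int = 0
    last_trial: int = 0      # trial index of the most recent activation


@dataclass
class ItemStatusLedger:
    """Old/new-in-context bookkeeping.

    ``status`` is monotone: an item flips new -> old for a context upon
    its first presentation there and never back. ``last_trial`` tracks
    the most recent activation in *any* context (the recency index used
    by the arrangement predicates and the Delta-trial analysis).
    """

    per_context: dict[tuple[int, int], ItemStatus] = field(default_factory=dict)
    last_activation: dict[int, int] = field(default_factory=dict)

    def is_old(self, item: int, context: int) -> bool:
        st = self.per_context.get((item, context))
        return st is not None and st.presentations > 0

    def record(self, item: int, context: int, trial_index: int) -> None:
        st = self.per_context.setdefault((item, context), ItemStatus())
        st.presentations += 1
        st.last_trial = trial_index
        self.last_activation[item] = trial_index

    def recency(self, item: int) -> int:
        return self.last_activation.get(item, 0)


@dataclass
class TaskSchedule:
    variant: str
    seed: int
    n_items: int
    contexts: dict[str, int]            # label -> pattern id
    trials: list[TrialSpec]
    stim: StimulusParams
    trial_duration: float

    @property
    def assessment_trials(self) -> list[TrialSpec]:
        return [t for t in self.trials if t.block == "assessment"]

    def events(self) -> list[Event]:
        """Flat ordered event list (context switches + item stimuli)."""
        out: list[Event] = []
        current_ctx = None
        for tr in self.trials:
            if tr.context != current_ctx:
                if current_ctx is not None:
                    out.append(Event(tr.t_start - BLOCK_GAP, "context_off",
                                     current_ctx, tr.block, tr.trial_index))
                out.append(Event(tr.t_start - BLOCK_GAP if current_ctx is not None
                                 else tr.t_start - BLOCK_GAP, "context_on",
                                 tr.context, tr.block, tr.trial_index))
                current_ctx = tr.context
            if tr.block == "assessment":
                out.append(Event(tr.t_start, "assessment_marker", -1,
                                 tr.block, tr.trial_index))
            t2 = tr.t_start + self.stim.t_stim + self.stim.T_stim
            out.append(Event(tr.t_start, "item_stim", tr.item_first,
                             tr.block, tr.trial_index))
            out.append(Event(t2, "item_stim", tr.item_second,
                             tr.block, tr.trial_index))
        if current_ctx is not None and self.trials:
            last = self.trials[-1]
            out.append(Event(last.t_start + self.trial_duration, "context_off",
                             current_ctx, last.block, last.trial_index))
        return out

    def item_windows(self, trial: TrialSpec) -> dict[int, tuple[float, float]]:
        """Stimulation window [t0, t1) of each item of a trial."""
        t_a = trial.t_start
        t_b = trial.t_start + self.stim.t_stim + self.stim.T_stim
        return {
            trial.item_first: (t_a, t_a + self.stim.t_stim),
            trial.item_second: (t_b, t_b + self.stim.t_stim),
        }

    def decision_time(self, trial: TrialSpec) -> float:
        return (trial.t_start + 2 * self.stim.t_stim + self.stim.T_stim)

    @property
    def duration(self) -> float:
        if not self.trials:
            return 0.0
        return self.trials[-1].t_start + self.trial_duration + BLOCK_GAP

    def to_json(self, path: str) -> None:
        payload = {
            "variant": self.variant, "seed": self.seed,
            "n_items": self.n_items, "contexts": self.contexts,
            "trial_duration": self.trial_duration,
            "trials": [asdict(t) for t in self.trials],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _pairs_of(items: list[int], rng: np.random.Generator) -> list[tuple[int, int]]:
    perm = [items[i] for i in rng.permutation(len(items))]
    return [(perm[i], perm[i + 1]) for i in range(0, len(perm) - 1, 2)]


def _intro_block(group: list[int], rng: np.random.Generator
                 ) -> list[tuple[int, int]]:
    """Introduce a group of items into the current context as new-old
    pairs: the first trial pairs the first two (both new); every later
    trial pairs one not-yet-shown item with a random already-shown item
    of the same group, so each introduction is a rewardable new-in-
    context presentation."""
    order = [group[i] for i in rng.permutation(len(group))]
    trials = [(order[0], order[1])]
    for k in range(2, len(order)):
        partner = order[rng.integers(k)]
        trials.append((order[k], partner))
    return trials


def _group_block(group: list[int], rng: np.random.Generator,
                 extra_rounds: int = 1) -> list[tuple[int, int]]:
    """Introduce a group, then re-pair it ``extra_rounds`` times (all
    items old-in-context by then), consolidating each item's contextual
    binding while preserving the group's position in the recency order."""
    trials = _intro_block(group, rng)
    for _ in range(extra_rounds):
        trials += _pairs_of(group, rng)
    return trials


def generate_schedule(
    variant: str,
    seed: int,
    n_items: int = 16,
    stim: Optional[StimulusParams] = None,
    max_retries: int = 200,
) -> TaskSchedule:
    """Build the timed trial schedule of one session.

    Exactly reproducible from ``(variant, seed)``; the drawn Assessment
    matching is resampled (bounded retries) until it satisfies the
    arrangement predicate and repeats no Encoding pair, then validated.
    """
    if variant not in VARIANTS:
        raise ScheduleError(f"unknown variant {variant!r}")
    if n_items % 2 or n_items < 4:
        raise ScheduleError("n_items must be even and at least 4")
    stim = stim or StimulusParams()
    rng = np.random.default_rng([seed, _VARIANT_IDX[variant], 0x5EED])

    ctx_a, ctx_b, ctx_c = n_items, n_items + 1, n_items + 2
    contexts = {"A": ctx_a, "B": ctx_b}
    items = list(range(n_items))
    perm = [items[i] for i in rng.permutation(n_items)]
    h1, h2 = perm[: n_items // 2], perm[n_items // 2:]  # h1: shown in A first

    arrangement = "arr2" if variant.endswith("arr2") else "arr1"
    exp2 = variant.startswith("exp2")

    blocks: list[tuple[str, int, list[tuple[int, int]]]] = []
    if not exp2:
        # reverse_reward keeps the reference trial structure: the reward
        # imbalance arises because only already-old partners earn the
        # (repeatable) reward, so an item's reward count follows the
        # random pairing draws (including zero for unlucky items)
        blocks.append(("encoding_A", ctx_a, _group_block(h1, rng)))
        if variant == "unbalanced":
            # future new-in-context-A items introduced normally (after the
            # old group, Arrangement 1), then repeated extra rounds
            b_pairs = (_group_block(h1, rng)
                       + _group_block(h2, rng, extra_rounds=2))
        elif arrangement == "arr2":
            # new-in-A items first; the old-in-A group's context-B
            # stimulations all follow them
            b_pairs = _group_block(h2, rng) + _group_block(h1, rng)
        else:
            # Arrangement 1: old-in-A group strictly precedes the new group
            b_pairs = _group_block(h1, rng) + _group_block(h2, rng)
        blocks.append(("encoding_B", ctx_b, b_pairs))
        if variant == "extra_context":
            contexts["C"] = ctx_c
            c_items = [items[i] for i in rng.permutation(n_items)[: n_items // 2]]
            blocks.append(("encoding_C", ctx_c, _group_block(c_items, rng)))
        assess_ctx = ctx_a
        new_items, old_items = list(h2), list(h1)
    else:
        blocks.append(("encoding_A", ctx_a, _group_block(h1, rng)))
        blocks.append(("encoding_B", ctx_b, _group_block(h1, rng)))
        blocks.append(("encoding_A", ctx_a, _group_block(h2, rng)))
        if arrangement == "arr2":
            # old-in-B items re-activated after the second context-A block
            blocks.append(("encoding_B", ctx_b, _pairs_of(h1, rng)))
        assess_ctx = ctx_b
        new_items, old_items = list(h2), list(h1)

    encoding_pairs = {frozenset(p) for _, _, ps in blocks for p in ps}

    # Assessment: random perfect matching new x old, no encoding repeats
    matching = None
    for _ in range(max_retries):
        cand = list(zip(new_items,
                        [old_items[i] for i in rng.permutation(len(old_items))]))
        if all(frozenset(p) not in encoding_pairs for p in cand):
            matching = cand
            break
    if matching is None:
        raise ScheduleError("could not draw a non-repeating Assessment matching")
    matching = [matching[i] for i in rng.permutation(len(matching))]

    trials: list[TrialSpec] = []
    trial_duration = 2 * stim.t_stim + stim.T_stim + DECISION_PHASE
    t = BLOCK_GAP
    idx = 0
    prev_ctx = None
    ledger = ItemStatusLedger()
    for block, ctx, pairs in blocks:
        if prev_ctx is not None and ctx != prev_ctx:
            t += BLOCK_GAP
        prev_ctx = ctx
        for a, b in pairs:
            idx += 1
            old, new = _designate(ledger, a, b, ctx)
            trials.append(TrialSpec(idx, block, ctx, a, b, t,
                                    old_item=old, new_item=new))
            ledger.record(a, ctx, idx)
            ledger.record(b, ctx, idx)
            t += trial_duration

    # pre-Assessment recencies decide the arrangement predicate
    pre_recency = {i: ledger.recency(i) for i in items}
    if prev_ctx != assess_ctx:
        t += BLOCK_GAP
    for new, old in matching:
        idx += 1
        first, second = (new, old) if rng.random() < 0.5 else (old, new)
        tr = TrialSpec(idx, "assessment", assess_ctx, first, second, t,
                       old_item=old, new_item=new, scored=True)
        ok = _arrangement_ok(arrangement, pre_recency[new], pre_recency[old])
        if variant == "extra_context":
            tr.excluded = not ok
            tr.scored = ok
        elif not ok:
            raise ScheduleError(
                f"assessment pair ({new},{old}) violates {arrangement}")
        trials.append(tr)
        ledger.record(first, assess_ctx, idx)
        ledger.record(second, assess_ctx, idx)
        t += trial_duration

    sched = TaskSchedule(variant, seed, n_items, contexts, trials, stim,
                         trial_duration)
    validate_schedule(sched)
    return sched


def _designate(ledger: ItemStatusLedger, a: int, b: int, ctx: int
               ) -> tuple[Optional[int], Optional[int]]:
    a_old, b_old = ledger.is_old(a, ctx), ledger.is_old(b, ctx)
    if a_old and not b_old:
        return a, b
    if b_old and not a_old:
        return b, a
    return None, None


def _arrangement_ok(arrangement: str, rec_new: int, rec_old: int) -> bool:
    if arrangement == "arr1":
        return rec_new > rec_old
    return rec_old > rec_new


def validate_schedule(sched: TaskSchedule) -> None:
    """Independent walk over the trial list re-deriving the ledger and
    checking every protocol invariant; raises ScheduleError on failure."""
    ledger = ItemStatusLedger()
    seen_pairs: set[frozenset] = set()
    assessed: set[int] = set()
    pre_recency: dict[int, int] = {}
    in_assessment = False
    prev_t = -np.inf
    for tr in sched.trials:
        if tr.t_start < prev_t:
            raise ScheduleError("trials out of temporal order")
        prev_t = tr.t_start
        if tr.item_first == tr.item_second:
            raise ScheduleError("pair with identical items")
        if tr.block == "assessment":
            if not in_assessment:
                in_assessment = True
                pre_recency = {i: ledger.recency(i)
                               for i in range(sched.n_items)}
            if frozenset(tr.items) in seen_pairs:
                raise ScheduleError("assessment pair repeats an earlier pair")
            if tr.old_item is None or tr.new_item is None:
                raise ScheduleError("assessment pair lacks old/new designation")
            if ledger.is_old(tr.new_item, tr.context):
                raise ScheduleError("designated new item is old-in-context")
            if not ledger.is_old(tr.old_item, tr.context):
                raise ScheduleError("designated old item is new-in-context")
            for it in tr.items:
                if it in assessed:
                    raise ScheduleError("item assessed more than once")
                assessed.add(it)
            arrangement = "arr2" if sched.variant.endswith("arr2") else "arr1"
            ok = _arrangement_ok(arrangement, pre_recency[tr.new_item],
                                 pre_recency[tr.old_item])
            if sched.variant == "extra_context":
                if tr.scored == tr.excluded:
                    raise ScheduleError("inconsistent exclusion tagging")
                if tr.scored != ok:
                    raise ScheduleError("mis-tagged extra-context pair")
            elif not ok:
                raise ScheduleError("arrangement predicate violated")
        elif in_assessment:
            raise ScheduleError("encoding trial after assessment started")
        seen_pairs.add(frozenset(tr.items))
        ledger.record(tr.item_first, tr.context, tr.trial_index)
        ledger.record(tr.item_second, tr.context, tr.trial_index)


# ---------------------------------------------------------------------------
# decisions and reward
# ---------------------------------------------------------------------------

@dataclass
class TrialResult:
    trial_index: int
    block: str
    old_item: Optional[int]
    new_item: Optional[int]
    f_old: float                 # Hz (selected-as-old side for undesignated)
    f_new: float
    choice: Optional[str]        # "new" | None (no selection)
    hit: bool
    rewarded_item: Optional[int]
    scored: bool
    excluded: bool = False


def decide_and_reward(
    trial: TrialSpec,
    rates: dict[int, float],
    ledger: ItemStatusLedger,
    variant: str,
    threshold: float = 0.85,
) -> TrialResult:
    """Apply the rate-based novelty readout and the reward rule.

    The item whose trial-average rate is more than (1 - threshold) below
    its partner's is selected as "new"; a hit requires that selection to
    match the designated new item. Undesignated (both-new or both-old)
    encoding pairs select the lower-rate item outright. Standard
    variants reward a correctly selected new-in-context item once
    (it then turns old-in-context); ``reverse_reward`` rewards
    old-in-context selections, repeatable on every activation.

    Degenerate trials (both rates zero, or no rate clears the margin on
    a designated pair) are scored as errors and earn no reward.
    """
    i1, i2 = trial.items
    f1, f2 = rates[i1], rates[i2]
    designated = trial.old_item is not None

    selected_new: Optional[int] = None
    if f1 == 0.0 and f2 == 0.0:
        selected_new = None  # degenerate trial
    elif f1 < threshold * f2:
        selected_new = i1
    elif f2 < threshold * f1:
        selected_new = i2
    elif not designated:
        selected_new = i1 if f1 <= f2 else i2

    if designated:
        f_old = rates[trial.old_item]
        f_new = rates[trial.new_item]
        hit = selected_new == trial.new_item
    else:
        # no ground truth; report rates by selection side
        f_new = rates[selected_new] if selected_new is not None else f1
        other = i2 if selected_new == i1 else i1
        f_old = rates[other]
        hit = selected_new is not None

    rewarded_item: Optional[int] = None
    if variant == "reverse_reward":
        # the reversed contingency rewards responses to old-in-context
        # items, repeatably on every activation where the old item is
        # singled out; reward totals therefore become imbalanced across
        # items through the random pairing and discrimination outcomes
        if designated:
            if hit:
                rewarded_item = trial.old_item
        elif selected_new is not None and ledger.is_old(
                selected_new, trial.context):
            # both items old: the response singles out one of them
            rewarded_item = selected_new
    else:
        if (selected_new is not None
                and not ledger.is_old(selected_new, trial.context)):
            rewarded_item = selected_new

    return TrialResult(
        trial_index=trial.trial_index, block=trial.block,
        old_item=trial.old_item, new_item=trial.new_item,
        f_old=f_old, f_new=f_new,
        choice="new" if selected_new is not None else None,
        hit=bool(hit and designated), rewarded_item=rewarded_item,
        scored=trial.scored, excluded=trial.excluded,
    )
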