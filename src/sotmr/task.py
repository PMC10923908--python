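"""Transitive-inference task protocol.

Each of three 6-item hierarchies (A > B > ... > F) is trained through its
five adjacent premise pairs; inference is later probed with the non-adjacent
pairs B-D and C-E (1st degree of separation), B-E (2nd degree), and the
anchor pair A-F which is solvable without inference.  Learning proceeds in
blocks of 30 trials (10 per hierarchy, each premise pair twice with
top/bottom positions counterbalanced), under the constraint that consecutive
pairs within a hierarchy never share an item, so the hierarchy order is
never revealed.  Feedback for a hierarchy switches off once middle-pair
accuracy (B-C, C-D, D-E) exceeds 66% in two of the last three blocks, after
a minimum of three blocks; training hard-stops at ten blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONDITIONS = ("Up", "Down", "Control")
CATEGORIES = ("faces", "scenes", "objects")
PAIR_CLASSES = ("premise", "inference_deg1", "inference_deg2", "anchor")
PHASES = ("learning", "immediate", "late")


@dataclass(frozen=True)
class Hierarchy:
    """One 6-item ordered hierarchy with its experimental and novel sounds."""

    condition: str
    category: str
    items: tuple[str, ...]
    experimental_sounds: tuple[str, ...] = ()
    novel_sounds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if len(self.items) != 6 or len(set(self.items)) != 6:
            raise ValueError("a hierarchy needs exactly 6 unique items")
        exp = self.experimental_sounds or tuple(f"{self.category}_exp_{i}" for i in self.items)
        nov = self.novel_sounds or tuple(f"{self.category}_nov_{k}" for k in range(6))
        if set(exp) & set(nov):
            raise ValueError("experimental and novel sound sets must be disjoint")
        object.__setattr__(self, "experimental_sounds", exp)
        object.__setattr__(self, "novel_sounds", nov)

    def rank(self, item: str) -> int:
        try:
            return self.items.index(item)
        except ValueError:
            raise KeyError(f"item {item!r} not in hierarchy") from None


@dataclass(frozen=True)
class PairTrial:
    """One two-alternative forced-choice trial on a hierarchy pair."""

    pair: tuple[str, str]
    correct: str
    pair_class: str
    phase: str
    hierarchy: str              # category label of the owning hierarchy
    position_order: tuple[str, str] = ()   # (top item, bottom item)
    feedback: bool = False
    confidence: int | None = None          # -2 (guessing) .. +2 (certain), late test only

    def __post_init__(self) -> None:
        if self.correct not in self.pair:
            raise ValueError("correct item must be a member of the pair")
        if self.pair_class not in PAIR_CLASSES:
            raise ValueError(f"pair_class must be one of {PAIR_CLASSES}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if self.feedback and self.phase != "learning":
            raise ValueError("feedback is given only in the learning phase")
        if self.confidence is not None:
            if self.phase != "late":
                raise ValueError("confidence ratings exist only in the late test")
            if not -2 <= self.confidence <= 2:
                raise ValueError("confidence must lie in -2..+2")
        if self.position_order and set(self.position_order) != set(self.pair):
            raise ValueError("position_order must be a permutation of the pair")


def build_premise_pairs(h: Hierarchy) -> list[tuple[str, str]]:
    """The 5 adjacent pairs in hierarchy order; the first element is correct."""
    return [(h.items[i], h.items[i + 1]) for i in range(5)]


def degree_of_separation(pair: tuple[str, str], h: Hierarchy) -> int:
    """Number of items between the two pair members (0 = adjacent/premise)."""
    i, j = h.rank(pair[0]), h.rank(pair[1])
    if i == j:
        raise ValueError("pair members must differ")
    return abs(i - j) - 1


def _classify(pair: tuple[str, str], h: Hierarchy) -> str:
    deg = degree_of_separation(pair, h)
    ranks = sorted(h.rank(x) for x in pair)
    if ranks == [0, 5]:
        return "anchor"
    return {0: "premise", 1: "inference_deg1", 2: "inference_deg2"}[deg]


def build_late_test_pairs(h: Hierarchy) -> list[PairTrial]:
    """The 9 late-test pair templates: 5 premise + B-D, C-E (deg1) + B-E (deg2) + A-F anchor."""
    A, B, C, D, E, F = h.items
    pairs = build_premise_pairs(h) + [(B, D), (C, E), (B, E), (A, F)]
    return [PairTrial(pair=p, correct=p[0], pair_class=_classify(p, h),
                      phase="late", hierarchy=h.category) for p in pairs]


def _orientations(pairs: list[tuple[str, str]]) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Each pair with both top/bottom display orders: [(pair, (top, bottom)), ...]."""
    out = []
    for p in pairs:
        out.append((p, (p[0], p[1])))
        out.append((p, (p[1], p[0])))
    return out


def _shuffle_no_shared_item(trials: list, rng: np.random.Generator,
                            max_attempts: int = 200) -> list:
    """Order trials so consecutive pairs share no item.

    Random reshuffles first; if none succeeds within ``max_attempts``, a
    randomised backtracking search settles it (and proves infeasibility by
    exhaustion otherwise, which cannot happen for 5-pair premise sets).
    """
    items_of = lambda t: set(t[0])
    n = len(trials)
    for _ in range(max_attempts):
        order = [trials[k] for k in rng.permutation(n)]
        if all(not (items_of(a) & items_of(b)) for a, b in zip(order, order[1:])):
            return order

    chosen: list[int] = []
    used = [False] * n

    def extend() -> bool:
        if len(chosen) == n:
            return True
        prev = items_of(trials[chosen[-1]]) if chosen else set()
        for k in rng.permutation(n):
            if not used[k] and not (items_of(trials[k]) & prev):
                used[k] = True
                chosen.append(k)
                if extend():
                    return True
                chosen.pop()
                used[k] = False
        return False

    if extend():
        return [trials[k] for k in chosen]
    raise RuntimeError("the no-shared-item constraint is unsatisfiable for this trial set")


def schedule_learning_block(hierarchies: list[Hierarchy], rng: np.random.Generator | int = 0,
                            category_order: list[str] | None = None,
                            feedback: bool = True) -> list[PairTrial]:
    """One 30-trial learning block: 10 trials per hierarchy, contiguous sub-blocks.

    Each of the 5 premise pairs appears exactly twice per hierarchy, with
    top/bottom positions counterbalanced, and consecutive pairs within a
    sub-block never share an item.  ``category_order`` is the
    counterbalancing input; default is the given hierarchy order.
    """
    if len(hierarchies) != 3:
        raise ValueError("a learning block needs exactly 3 hierarchies")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    by_cat = {h.category: h for h in hierarchies}
    order = category_order or [h.category for h in hierarchies]
    if sorted(order) != sorted(by_cat):
        raise ValueError("category_order must name each hierarchy exactly once")
    block: list[PairTrial] = []
    for cat in order:
        h = by_cat[cat]
        oriented = _shuffle_no_shared_item(_orientations(build_premise_pairs(h)), rng)
        for pair, pos in oriented:
            block.append(PairTrial(pair=pair, correct=pair[0], pair_class="premise",
                                   phase="learning", hierarchy=cat,
                                   position_order=pos, feedback=feedback))
    return block


def schedule_test_block(hierarchies: list[Hierarchy], rng: np.random.Generator | int = 0,
                        phase: str = "immediate") -> list[PairTrial]:
    """One test block: pairs of all hierarchies randomly interleaved, with the
    no-shared-item constraint applied per hierarchy stream.

    Immediate test: the 5 premise pairs per hierarchy, each twice (10 trials
    per hierarchy).  Late test: the 9 late-test pairs per hierarchy, 5
    premise + 4 new, each shown once with a random orientation plus one
    repeat of a random pair to keep 10 trials per hierarchy.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    streams = []
    for h in hierarchies:
        if phase == "immediate":
            oriented = _shuffle_no_shared_item(_orientations(build_premise_pairs(h)), rng)
            trials = [PairTrial(pair=p, correct=p[0], pair_class="premise", phase=phase,
                                hierarchy=h.category, position_order=pos)
                      for p, pos in oriented]
        elif phase == "late":
            base = build_late_test_pairs(h)
            base = base + [base[rng.integers(len(base))]]
            pick = [(t.pair, (t.pair, t.pair[::-1])[rng.integers(2)], t.pair_class) for t in base]
            pick = _shuffle_no_shared_item([(p, pos, cls) for p, pos, cls in pick], rng)
            trials = [PairTrial(pair=p, correct=p[0], pair_class=cls, phase="late",
                                hierarchy=h.category, position_order=pos)
                      for p, pos, cls in pick]
        else:
            raise ValueError("phase must be 'immediate' or 'late'")
        streams.append(trials)
    # random interleave keeping each stream's internal order
    tokens = np.concatenate([[k] * len(s) for k, s in enumerate(streams)])
    tokens = tokens[rng.permutation(tokens.size)]
    cursors = [0] * len(streams)
    out = []
    for k in tokens:
        out.append(streams[k][cursors[k]])
        cursors[k] += 1
    return out


@dataclass
class ExitState:
    """Per-hierarchy middle-pair accuracy history and feedback switches."""

    categories: tuple[str, ...]
    history: dict[str, list[float]] = field(default_factory=dict)
    feedback_on: dict[str, bool] = field(default_factory=dict)
    blocks_completed: int = 0
    min_blocks: int = 3
    max_blocks: int = 10
    criterion: float = 66.0
    strict: bool = True                   # "over 66%" read literally as > 66.0
    window_mode: str = "all_blocks"       # or "from_block_3": only blocks >= 3 enter the window

    def __post_init__(self) -> None:
        for cat in self.categories:
            self.history.setdefault(cat, [])
            self.feedback_on.setdefault(cat, True)

    @property
    def done(self) -> bool:
        return (self.blocks_completed >= self.max_blocks
                or not any(self.feedback_on.values()))


def update_exit_criterion(state: ExitState, block_accuracies: dict[str, float]) -> ExitState:
    """Record one block's middle-pair accuracies (%) and update feedback switches.

    Evaluation starts once at least ``min_blocks`` blocks are complete; a
    hierarchy's feedback turns off (never back on) when accuracy beats the
    criterion in at least 2 of the last 3 recorded blocks.
    """
    if set(block_accuracies) != set(state.categories):
        raise ValueError("block_accuracies must cover every hierarchy exactly once")
    for acc in block_accuracies.values():
        if not 0.0 <= acc <= 100.0:
            raise ValueError("accuracies must lie in [0, 100]")
    for cat, hist in state.history.items():
        if len(hist) != state.blocks_completed:
            raise ValueError("inconsistent ExitState: history length != blocks_completed")
    if state.blocks_completed >= state.max_blocks:
        raise ValueError(f"training already stopped at {state.max_blocks} blocks")

    new_hist = {cat: state.history[cat] + [block_accuracies[cat]] for cat in state.categories}
    new_fb = dict(state.feedback_on)
    completed = state.blocks_completed + 1
    if completed >= state.min_blocks:
        for cat in state.categories:
            if not new_fb[cat]:
                continue
            hist = new_hist[cat] if state.window_mode == "all_blocks" else new_hist[cat][2:]
            window = hist[-3:]
            hits = sum(1 for a in window if (a > state.criterion if state.strict
                                             else a >= state.criterion))
            if len(window) >= 2 and hits >= 2:
                new_fb[cat] = False
    return replace(state, history=new_hist, feedback_on=new_fb, blocks_completed=completed)


@dataclass(frozen=True)
class SoundImageTrial:
    sound: str
    target: str
    images: tuple[str, str, str]   # screen order, target somewhere among them
    block: int


def build_sound_image_test(hierarchies: list[Hierarchy], rng: np.random.Generator | int = 0,
                           n_blocks: int = 2, reps_per_block: int = 3) -> list[SoundImageTrial]:
    """Sound-image association test: target + 2 distractors, >= 1 same-category lure.

    Every experimental sound appears ``reps_per_block`` times in each of
    ``n_blocks`` blocks; image screen positions are randomised per trial.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    for h in hierarchies:
        if len(h.items) < 3:
            raise ValueError(f"category {h.category} has fewer than 3 items")
    category_of = {item: h.category for h in hierarchies for item in h.items}
    all_items = [item for h in hierarchies for item in h.items]
    sound_of = {item: s for h in hierarchies for item, s in zip(h.items, h.experimental_sounds)}

    trials = []
    for block in range(n_blocks):
        plan = [item for item in all_items for _ in range(reps_per_block)]
        plan = [plan[k] for k in rng.permutation(len(plan))]
        for target in plan:
            same_cat = [x for x in all_items if x != target and category_of[x] == category_of[target]]
            others = [x for x in all_items if x != target]
            lure = same_cat[rng.integers(len(same_cat))]
            remaining = [x for x in others if x != lure]
            filler = remaining[rng.integers(len(remaining))]
            images = [target, lure, filler]
            images = tuple(images[k] for k in rng.permutation(3))
            trials.append(SoundImageTrial(sound=sound_of[target], target=target,
                                          images=images, block=block))
    return trials


ROLLUP = {"inference_deg1": "inference", "inference_deg2": "inference",
          "deg1": "inference", "deg2": "inference", "premise": "premise"}


def score_behaviour(responses: pd.DataFrame,
                    valid_pairs: dict[str, set[tuple[str, str]]] | None = None) -> pd.DataFrame:
    """Accuracy per subject x condition x session x pair_class, with counts.

    ``responses`` needs columns subject, condition, session, pair_class,
    correct (0/1); an optional ``pair`` column is validated against
    ``valid_pairs`` (per hierarchy category) when provided.  Empty cells are
    simply absent from the output — never reported as 0.  Roll-up rows
    aggregate the two inference degrees into pair_class "inference".
    """
    required = {"subject", "condition", "session", "pair_class", "correct"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"responses table lacks columns: {sorted(missing)}")
    if valid_pairs is not None:
        if "pair" not in responses.columns or "hierarchy" not in responses.columns:
            raise ValueError("pair validation needs 'pair' and 'hierarchy' columns")
        for _, row in responses.iterrows():
            pair = tuple(sorted(row["pair"]))
            known = {tuple(sorted(p)) for p in valid_pairs.get(row["hierarchy"], set())}
            if pair not in known:
                raise ValueError(f"response references unknown pair {row['pair']} "
                                 f"in hierarchy {row['hierarchy']}")

    keys = ["subject", "condition", "session", "pair_class"]
    grouped = responses.groupby(keys)["correct"].agg(n="count", accuracy="mean").reset_index()
    roll = responses.assign(pair_class=responses["pair_class"].map(lambda c: ROLLUP.get(c, c)))
    roll = roll[roll["pair_class"] == "inference"]
    if len(roll):
        extra = roll.groupby(keys)["correct"].agg(n="count", accuracy="mean").reset_index()
        grouped = pd.concat([grouped, extra], ignore_index=True)
    grouped["accuracy"] *= 100.0
    return grouped.sort_values(keys).reset_index(drop=True)
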