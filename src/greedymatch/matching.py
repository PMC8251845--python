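"""Greedy 1:1 propensity-score matching without replacement.

Two greedy algorithms, both visiting treated subjects in a uniformly random
order driven by a seed:

* caliper-random matching: the control is drawn uniformly at random from all
  still-unmatched controls whose score lies within the caliper;
* nearest-neighbor (NN) caliper matching: the still-unmatched control with
  the smallest absolute score difference is taken, accepted only if that
  distance is within the caliper; exact distance ties are broken uniformly
  at random among every control at the minimal distance.

Both are "greedy": a matched control is never revisited, so the result
depends on the random visiting order (and, for caliper-random, on the random
within-caliper draw).  That order-dependence is precisely the quantity this
package studies, so the random choices are specified exactly and are
reproducible from the seed.

The production implementations keep the unmatched controls in a Fenwick
(binary indexed) tree over the score-sorted order, giving O(log m) eligible
counts, k-th-alive selection and deletion per treated subject.  Transparent
O(n*m) reference implementations with the identical random-number consumption
pattern are provided for validation; the two are bit-identical by
construction and asserted so in the test suite.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from numpy.random import default_rng

from .dgp import Cohort
from .propensity import PropensityFit, caliper_width

__all__ = [
    "MatchConfig",
    "MatchedSet",
    "greedy_caliper_match",
    "nn_caliper_match",
    "greedy_caliper_match_reference",
    "nn_caliper_match_reference",
]


@dataclass(frozen=True)
class MatchConfig:
    """Configuration of one matching repetition.

    ``caliper_width``, when given, overrides the multiplier-derived width
    (useful for hand-built examples); otherwise the width is
    ``caliper_multiplier x SD`` of the scores on ``scale``.
    """

    algorithm: str = "caliper_random"   # or "nn_caliper"
    caliper_multiplier: float = 0.2
    seed: int = 0
    scale: str = "probability"          # or "logit"
    caliper_width: float | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ("caliper_random", "nn_caliper"):
            raise ValueError(f"unknown matching algorithm {self.algorithm!r}")
        if self.caliper_width is None and not (self.caliper_multiplier > 0):
            raise ValueError("caliper multiplier must be positive")
        if self.caliper_width is not None and not (self.caliper_width > 0):
            raise ValueError("explicit caliper width must be positive")


@dataclass
class MatchedSet:
    """The outcome of one matching repetition.

    ``pairs`` is a (k, 2) integer array of (treated-id, control-id) subject
    indices; ids never repeat (matching is without replacement).
    """

    pairs: np.ndarray
    seed: int
    n_treated_unmatched: int
    algorithm: str
    caliper: float

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])

    def to_frame(self, fit: PropensityFit | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "pair_id": np.arange(self.n_pairs),
            "treated_id": self.pairs[:, 0],
            "control_id": self.pairs[:, 1],
        })
        if fit is not None:
            df["ps_treated"] = fit.ps[self.pairs[:, 0]]
            df["ps_control"] = fit.ps[self.pairs[:, 1]]
        return df


def _first_true(lo: int, hi: int, pred) -> int:
    """First index in [lo, hi) where a monotone predicate turns true (hi if never)."""
    while lo < hi:
        mid = (lo + hi) // 2
        if pred(mid):
            hi = mid
        else:
            lo = mid + 1
    return lo


class _Fenwick:
    """Binary indexed tree over m slots, each initially holding count 1.

    Supports prefix counts, removal of a slot and selection of the k-th
    (0-based) remaining slot, all in O(log m).
    """

    __slots__ = ("n", "tree", "top")

    def __init__(self, n: int) -> None:
        self.n = n
        # closed form for the all-ones initial state
        self.tree = [0] + [(i & -i) for i in range(1, n + 1)]
        self.top = 1 << (n.bit_length() - 1) if n else 0

    def prefix(self, i: int) -> int:
        """Number of remaining slots among positions [0, i)."""
        tree = self.tree
        s = 0
        while i > 0:
            s += tree[i]
            i -= i & -i
        return s

    def remove(self, pos: int) -> None:
        """Remove slot ``pos`` (0-based); must currently be present."""
        i = pos + 1
        tree = self.tree
        n = self.n
        while i <= n:
            tree[i] -= 1
            i += i & -i

    def kth(self, k: int) -> int:
        """0-based position of the k-th (0-based) remaining slot."""
        tree = self.tree
        n = self.n
        pos = 0
        rem = k + 1
        bit = self.top
        while bit:
            nxt = pos + bit
            if nxt <= n and tree[nxt] < rem:
                rem -= tree[nxt]
                pos = nxt
            bit >>= 1
        return pos  # 0-based: pos is the index before the answer's 1-based slot


def _setup(fit: PropensityFit, cohort: Cohort, config: MatchConfig):
    """Shared preamble: score arrays, caliper width, sorted control order."""
    scores = fit.scores(config.scale)
    if config.caliper_width is not None:
        width = float(config.caliper_width)
    else:
        width = caliper_width(fit, config.caliper_multiplier, scale=config.scale)
    treated_ids = np.flatnonzero(cohort.t == 1)
    control_ids = np.flatnonzero(cohort.t == 0)
    if treated_ids.size == 0 or control_ids.size == 0:
        raise ValueError("matching needs at least one treated and one control subject")
    # controls in (score, id) order so "k-th eligible" is well defined
    order = np.lexsort((control_ids, scores[control_ids]))
    sorted_controls = control_ids[order]
    cs = scores[sorted_controls].tolist()      # python list: fast bisect
    return scores, width, treated_ids, sorted_controls, cs


def greedy_caliper_match(
    fit: PropensityFit, cohort: Cohort, config: MatchConfig
) -> MatchedSet:
    """Caliper matching with random within-caliper control selection.

    Treated subjects are visited in a random permutation; for each, one of
    the still-unmatched controls with |score difference| <= caliper is chosen
    uniformly at random, or the treated subject is left unmatched if there is
    none.
    """
    scores, width, treated_ids, sorted_controls, cs = _setup(fit, cohort, config)
    rng = default_rng(config.seed)
    perm = rng.permutation(treated_ids.size)

    m = len(cs)
    bit = _Fenwick(m)
    pairs: list[tuple[int, int]] = []
    unmatched = 0
    for idx in perm:
        tid = treated_ids[idx]
        s = scores[tid]
        lo = bisect_left(cs, s - width)
        hi = bisect_right(cs, s + width)
        before = bit.prefix(lo)
        count = bit.prefix(hi) - before
        if count == 0:
            unmatched += 1
            continue
        k = int(rng.integers(count)) if count > 1 else 0
        pos = bit.kth(before + k)
        bit.remove(pos)
        pairs.append((int(tid), int(sorted_controls[pos])))

    return MatchedSet(
        pairs=np.array(pairs, dtype=np.int64).reshape(-1, 2),
        seed=config.seed,
        n_treated_unmatched=unmatched,
        algorithm="caliper_random",
        caliper=width,
    )


def nn_caliper_match(
    fit: PropensityFit, cohort: Cohort, config: MatchConfig
) -> MatchedSet:
    """Nearest-neighbor matching within a caliper.

    Treated subjects are visited in a random permutation; each is paired with
    the still-unmatched control minimising the absolute score difference,
    provided that minimum is within the caliper.  When several controls sit
    at exactly the minimal distance, one is chosen uniformly at random.
    """
    scores, width, treated_ids, sorted_controls, cs = _setup(fit, cohort, config)
    rng = default_rng(config.seed)
    perm = rng.permutation(treated_ids.size)

    m = len(cs)
    bit = _Fenwick(m)
    alive = m
    pairs: list[tuple[int, int]] = []
    unmatched = 0
    for idx in perm:
        tid = treated_ids[idx]
        if alive == 0:
            unmatched += 1
            continue
        s = scores[tid]
        pos0 = bisect_left(cs, s)
        rank = bit.prefix(pos0)      # remaining controls with score < s
        d_left = np.inf              # nearest remaining below s is strictly below,
        d_right = np.inf             # so d_left > 0 always; equal scores sit right
        if rank > 0:
            d_left = s - cs[bit.kth(rank - 1)]
        if rank < alive:
            d_right = cs[bit.kth(rank)] - s
        d = min(d_left, d_right)
        if d > width:
            unmatched += 1
            continue
        # Tie set: every remaining control whose computed |score - s| equals d.
        # Distances are monotone in sorted position on each side of s, so each
        # side's tie set is a contiguous position range found by bisection on
        # the computed distance (value-based bisection would miss distinct
        # scores that round to the same distance).
        cnt_left = n_before_left = 0
        if d_left == d:
            lo_left = _first_true(0, pos0, lambda p: s - cs[p] <= d)
            hi_left = _first_true(lo_left, pos0, lambda p: s - cs[p] < d)
            n_before_left = bit.prefix(lo_left)
            cnt_left = bit.prefix(hi_left) - n_before_left
        cnt_right = n_before_right = 0
        if d_right == d:
            lo_right = _first_true(pos0, m, lambda p: cs[p] - s >= d)
            hi_right = _first_true(lo_right, m, lambda p: cs[p] - s > d)
            n_before_right = bit.prefix(lo_right)
            cnt_right = bit.prefix(hi_right) - n_before_right
        total = cnt_left + cnt_right
        k = int(rng.integers(total)) if total > 1 else 0
        if k < cnt_left:
            pos = bit.kth(n_before_left + k)
        else:
            pos = bit.kth(n_before_right + (k - cnt_left))
        bit.remove(pos)
        alive -= 1
        pairs.append((int(tid), int(sorted_controls[pos])))

    return MatchedSet(
        pairs=np.array(pairs, dtype=np.int64).reshape(-1, 2),
        seed=config.seed,
        n_treated_unmatched=unmatched,
        algorithm="nn_caliper",
        caliper=width,
    )


# ---------------------------------------------------------------------------
# Reference implementations: plain masked linear scans over the same sorted
# control order, consuming random numbers in exactly the same pattern as the
# fast paths, hence bit-identical output.  Used as oracles in the tests.
# ---------------------------------------------------------------------------

def greedy_caliper_match_reference(
    fit: PropensityFit, cohort: Cohort, config: MatchConfig
) -> MatchedSet:
    scores, width, treated_ids, sorted_controls, cs_list = _setup(fit, cohort, config)
    cs = np.asarray(cs_list)
    rng = default_rng(config.seed)
    perm = rng.permutation(treated_ids.size)

    alive = np.ones(cs.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    unmatched = 0
    for idx in perm:
        tid = treated_ids[idx]
        s = scores[tid]
        # same boundary arithmetic as the fast path: window [s - w, s + w]
        eligible = np.flatnonzero(alive & (cs >= s - width) & (cs <= s + width))
        if eligible.size == 0:
            unmatched += 1
            continue
        k = int(rng.integers(eligible.size)) if eligible.size > 1 else 0
        pos = eligible[k]
        alive[pos] = False
        pairs.append((int(tid), int(sorted_controls[pos])))
    return MatchedSet(
        pairs=np.array(pairs, dtype=np.int64).reshape(-1, 2),
        seed=config.seed,
        n_treated_unmatched=unmatched,
        algorithm="caliper_random",
        caliper=width,
    )


def nn_caliper_match_reference(
    fit: PropensityFit, cohort: Cohort, config: MatchConfig
) -> MatchedSet:
    scores, width, treated_ids, sorted_controls, cs_list = _setup(fit, cohort, config)
    cs = np.asarray(cs_list)
    rng = default_rng(config.seed)
    perm = rng.permutation(treated_ids.size)

    alive = np.ones(cs.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    unmatched = 0
    for idx in perm:
        tid = treated_ids[idx]
        live = np.flatnonzero(alive)
        if live.size == 0:
            unmatched += 1
            continue
        s = scores[tid]
        dist = np.abs(cs[live] - s)
        d = dist.min()
        if d > width:
            unmatched += 1
            continue
        ties = live[dist == d]
        k = int(rng.integers(ties.size)) if ties.size > 1 else 0
        pos = ties[k]
        alive[pos] = False
        pairs.append((int(tid), int(sorted_controls[pos])))
    return MatchedSet(
        pairs=np.array(pairs, dtype=np.int64).reshape(-1, 2),
        seed=config.seed,
        n_treated_unmatched=unmatched,
        algorithm="nn_caliper",
        caliper=width,
    )


MATCHERS: dict[str, Callable[[PropensityFit, Cohort, MatchConfig], MatchedSet]] = {
    "caliper_random": greedy_caliper_match,
    "nn_caliper": nn_caliper_match,
}
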