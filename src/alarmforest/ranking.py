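"""Local method rankings and global rank aggregation.

Per dataset, methods are ranked by descending validation AUC (four
probability schemes) or challenge score (ten class methods); ties are
broken by a seeded random permutation.  The local rank lists are then
fused into one global ordering sigma* minimizing the weighted total
distance theta(sigma) = sum_i w_i d(sigma, L_i), where d is the Spearman
footrule — the sum over items of absolute position differences (a
squared-displacement variant is available).  The minimization is an
exhaustive search over all k! orderings, made tractable by
branch-and-bound with an assignment-problem bound; it is guarded against
k > 10.

Because the tie-breaking is random, the whole two-step procedure is
repeated (1000 repetitions by default) and summarized as an item x
position frequency table of global ranks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .aggregation import ProbMethod
from .cv import EvaluationTable
from .methods import enumerate_methods

MAX_EXHAUSTIVE_ITEMS = 10


@dataclass(frozen=True)
class RankList:
    """An ordered list of item names (best first); a full permutation."""

    items: tuple
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError("a rank list may not repeat items")

    def position(self, item) -> int:
        """1-based position of an item."""
        return self.items.index(item) + 1


@dataclass
class GlobalRank:
    """The aggregated ordering and its objective value."""

    ranking: tuple
    objective: float
    co_optima: tuple


def rank_items(values: pd.Series, rng: np.random.Generator,
               source: str = "") -> RankList:
    """Descending-value ranking with randomized tie-breaking."""
    values = values.astype(float)
    tiebreak = rng.permutation(len(values))
    order = np.lexsort((tiebreak, -values.to_numpy()))
    return RankList(items=tuple(values.index[order]), source=source)


def method_values(evaluation: EvaluationTable, measure: str) -> pd.Series:
    """Per-item validation values from one dataset's evaluation table.

    ``measure="score"`` returns the ten class methods' mean validation
    scores.  ``measure="AUC"`` returns the four probability schemes' mean
    validation AUCs; AUC depends only on the probability vector, so the
    methods sharing a scheme carry identical values and are collapsed.
    """
    table = evaluation.long
    sel = table[(table["sample"] == "validation") & (table["metric"] == measure)]
    if sel.empty:
        raise ValueError(f"no validation rows for measure {measure!r}")
    per_method = sel.groupby("method")["value"].mean()
    if measure == "score":
        return per_method
    if measure == "AUC":
        scheme = {m.name: m.prob_method.value for m in enumerate_methods()}
        return per_method.groupby(per_method.index.map(scheme)).mean()
    raise ValueError(f"unknown measure {measure!r}")


def local_ranks(evaluations: Sequence[EvaluationTable], measure: str,
                rng: np.random.Generator) -> list[RankList]:
    """One tie-broken rank list per dataset."""
    out = []
    for ev in evaluations:
        values = method_values(ev, measure)
        name = str(ev.long["dataset"].iloc[0])
        out.append(rank_items(values, rng, source=name))
    return out


def footrule_distance(a: RankList, b: RankList) -> float:
    """Spearman footrule: sum over items of |pos_a - pos_b|."""
    if set(a.items) != set(b.items):
        raise ValueError("rank lists cover different item universes")
    pos_b = {item: i for i, item in enumerate(b.items)}
    return float(sum(abs(i - pos_b[item]) for i, item in enumerate(a.items)))


def _position_costs(lists: Sequence[RankList], weights, distance: str) -> tuple[list, np.ndarray]:
    """items (sorted) and cost[i, p] = sum_l w_l f(|p - pos_l(item_i)|)."""
    universe = set(lists[0].items)
    for lst in lists[1:]:
        if set(lst.items) != universe:
            raise ValueError("rank lists cover different item universes")
    items = sorted(universe)
    k = len(items)
    if weights is None:
        weights = np.ones(len(lists))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(lists),) or (weights < 0).any():
        raise ValueError("need one non-negative weight per list")
    cost = np.zeros((k, k))
    positions = np.arange(k)
    for w, lst in zip(weights, lists):
        for i, item in enumerate(items):
            diff = np.abs(positions - (lst.position(item) - 1)).astype(float)
            cost[i] += w * (diff ** 2 if distance == "squared" else diff)
    return items, cost


def aggregate_exhaustive(lists: Sequence[RankList], weights=None,
                         distance: str = "footrule") -> GlobalRank:
    """Exhaustively minimize the total weighted distance over permutations.

    The objective decomposes over (item, position) pairs, so a linear
    assignment solve gives the optimal value up front; a depth-first
    enumeration with a running lower bound then recovers *all* co-optimal
    orderings.  sigma* is the lexicographically smallest co-optimum.
    Refuses k > 10 (10! orderings is the practical ceiling for exhaustive
    search).
    """
    if distance not in ("footrule", "squared"):
        raise ValueError(f"unknown distance {distance!r}")
    if not lists:
        raise ValueError("need at least one rank list")
    items, cost = _position_costs(lists, weights, distance)
    k = len(items)
    if k > MAX_EXHAUSTIVE_ITEMS:
        raise ValueError(
            f"exhaustive aggregation over {k} items is intractable (limit "
            f"{MAX_EXHAUSTIVE_ITEMS}); use a stochastic search instead")

    row, col = linear_sum_assignment(cost)
    optimum = float(cost[row, col].sum())

    eps = 1e-9
    co_optima: list[tuple] = []
    order: list[int] = []
    used = np.zeros(k, dtype=bool)

    def dfs(partial_cost: float) -> None:
        depth = len(order)
        if depth == k:
            if partial_cost <= optimum + eps:
                co_optima.append(tuple(items[i] for i in order))
            return
        open_pos = np.arange(depth + 1, k)
        for i in range(k):
            if used[i]:
                continue
            c = partial_cost + cost[i, depth]
            used[i] = True
            order.append(i)
            free = ~used
            # lower bound: each unplaced item at its cheapest open position
            bound = c + (float(cost[free][:, open_pos].min(axis=1).sum())
                         if free.any() else 0.0)
            if bound <= optimum + eps:
                dfs(c)
            order.pop()
            used[i] = False

    dfs(0.0)
    ranking = min(co_optima)
    return GlobalRank(ranking=ranking, objective=optimum,
                      co_optima=tuple(sorted(co_optima)))


def rank_distribution(values_by_dataset: Mapping[str, pd.Series],
                      repetitions: int = 1000, seed: int = 0,
                      weights=None, distance: str = "footrule") -> pd.DataFrame:
    """Item x position frequency table of global ranks over repetitions.

    Each repetition redraws the random tie-breaking in the local rankings,
    re-aggregates, and records where each item lands in sigma*.  Entries
    are percentages; every row and every column sums to 100.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    datasets = list(values_by_dataset)
    items = sorted(values_by_dataset[datasets[0]].index)
    k = len(items)
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(0.0, index=items,
                          columns=[f"N{p}" for p in range(1, k + 1)])
    for _ in range(repetitions):
        lists = [rank_items(values_by_dataset[d], rng, source=d) for d in datasets]
        result = aggregate_exhaustive(lists, weights=weights, distance=distance)
        for pos, item in enumerate(result.ranking, start=1):
            counts.loc[item, f"N{pos}"] += 1
    return counts / repetitions * 100.0


def evaluation_rank_distribution(evaluations: Sequence[EvaluationTable],
                                 measure: str, repetitions: int = 1000,
                                 seed: int = 0, weights=None,
                                 distance: str = "footrule") -> pd.DataFrame:
    """Convenience wrapper: rank distribution straight from evaluations."""
    values = {str(ev.long["dataset"].iloc[0]): method_values(ev, measure)
              for ev in evaluations}
    return rank_distribution(values, repetitions=repetitions, seed=seed,
                             weights=weights, distance=distance)
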