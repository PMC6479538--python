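import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import alarmforest as af
from alarmforest.ranking import (GlobalRank, RankList, aggregate_exhaustive,
                                 footrule_distance, method_values,
                                 rank_distribution, rank_items)

ITEMS = ("A", "B", "C", "D")


def brute_force_aggregate(lists, weights=None, distance="footrule"):
    """Full enumeration over all permutations (independent oracle)."""
    items = sorted(lists[0].items)
    if weights is None:
        weights = [1.0] * len(lists)
    best_value, best = np.inf, None
    for perm in itertools.permutations(items):
        sigma = RankList(items=perm)
        if distance == "footrule":
            value = sum(w * footrule_distance(sigma, L) for w, L in zip(weights, lists))
        else:
            value = sum(
                w * sum((sigma.position(i) - L.position(i)) ** 2 for i in items)
                for w, L in zip(weights, lists))
        if value < best_value - 1e-12 or (
                abs(value - best_value) <= 1e-12 and perm < best):
            best_value, best = value, perm
    return best, best_value


def test_rank_items_deterministic_without_ties():
    values = pd.Series([0.9, 0.8, 0.7, 0.6], index=ITEMS)
    rng = np.random.default_rng(0)
    assert rank_items(values, rng).items == ITEMS


def test_tied_pair_is_ordered_randomly_half_the_time():
    values = pd.Series([0.9, 0.9, 0.1], index=("A", "B", "C"))
    rng = np.random.default_rng(5)
    first = [rank_items(values, rng).items[0] for _ in range(600)]
    frac_a = np.mean([f == "A" for f in first])
    assert 0.42 < frac_a < 0.58
    assert all(rank_items(values, rng).items[2] == "C" for _ in range(10))


def test_all_tied_values_cover_all_orders():
    values = pd.Series([0.5, 0.5, 0.5], index=("A", "B", "C"))
    rng = np.random.default_rng(9)
    seen = {rank_items(values, rng).items for _ in range(300)}
    assert len(seen) == 6


def test_footrule_identity_reverse_and_symmetry():
    a = RankList(items=ITEMS)
    assert footrule_distance(a, a) == 0.0
    rev = RankList(items=ITEMS[::-1])
    assert footrule_distance(a, rev) == 8.0  # 3+1+1+3
    assert footrule_distance(a, rev) == footrule_distance(rev, a)
    with pytest.raises(ValueError):
        footrule_distance(a, RankList(items=("A", "B", "C", "E")))


@settings(deadline=None, derandomize=True, max_examples=80)
@given(st.permutations(ITEMS), st.permutations(ITEMS), st.permutations(ITEMS))
def test_footrule_is_a_metric(pa, pb, pc):
    a, b, c = (RankList(items=tuple(p)) for p in (pa, pb, pc))
    assert footrule_distance(a, b) >= 0
    assert (footrule_distance(a, b) == 0) == (a.items == b.items)
    assert footrule_distance(a, b) == footrule_distance(b, a)
    assert footrule_distance(a, c) <= footrule_distance(a, b) + footrule_distance(b, c)


def test_identical_lists_aggregate_to_themselves():
    lst = RankList(items=("C", "A", "B"))
    result = aggregate_exhaustive([lst, lst, lst])
    assert result.ranking == lst.items
    assert result.objective == 0.0
    assert result.co_optima == (lst.items,)


def test_two_against_one_majority():
    abc = RankList(items=("A", "B", "C"))
    bac = RankList(items=("B", "A", "C"))
    result = aggregate_exhaustive([abc, abc, bac])
    assert result.ranking == ("A", "B", "C")
    assert result.objective == 2.0


def test_guard_refuses_more_than_ten_items():
    big = RankList(items=tuple("ABCDEFGHIJK"))
    with pytest.raises(ValueError, match="intractable"):
        aggregate_exhaustive([big])


@pytest.mark.parametrize("distance", ["footrule", "squared"])
def test_aggregation_matches_full_enumeration(distance):
    rng = np.random.default_rng(17)
    for _ in range(25):
        k = int(rng.integers(2, 7))
        m = int(rng.integers(1, 5))
        items = tuple(f"i{j}" for j in range(k))
        lists = [RankList(items=tuple(rng.permutation(items))) for _ in range(m)]
        weights = rng.integers(1, 4, size=m).astype(float)
        result = aggregate_exhaustive(lists, weights=weights, distance=distance)
        oracle_best, oracle_value = brute_force_aggregate(lists, weights, distance)
        assert result.objective == pytest.approx(oracle_value)
        assert result.ranking == oracle_best
        # every reported co-optimum actually achieves the optimum
        for sigma in result.co_optima:
            value = sum(w * footrule_distance(RankList(items=sigma), L)
                        for w, L in zip(weights, lists)) if distance == "footrule" \
                else None
            if value is not None:
                assert value == pytest.approx(oracle_value)


def test_relabeling_equivariance():
    rng = np.random.default_rng(23)
    items = ("A", "B", "C", "D")
    lists = [RankList(items=tuple(rng.permutation(items))) for _ in range(3)]
    mapping = {"A": "W", "B": "X", "C": "Y", "D": "Z"}  # order-preserving
    relabeled = [RankList(items=tuple(mapping[i] for i in lst.items))
                 for lst in lists]
    r1 = aggregate_exhaustive(lists)
    r2 = aggregate_exhaustive(relabeled)
    assert tuple(mapping[i] for i in r1.ranking) == r2.ranking


def test_rank_distribution_rows_and_columns_sum_to_hundred():
    rng_values = {
        "d1": pd.Series([0.9, 0.9, 0.5, 0.2], index=ITEMS),
        "d2": pd.Series([0.8, 0.8, 0.8, 0.1], index=ITEMS),
    }
    dist = rank_distribution(rng_values, repetitions=40, seed=2)
    np.testing.assert_allclose(dist.sum(axis=1), 100.0)
    np.testing.assert_allclose(dist.sum(axis=0), 100.0)


def test_tie_free_values_give_degenerate_distribution():
    values = {d: pd.Series([0.9, 0.7, 0.5, 0.3], index=ITEMS) for d in ("x", "y", "z")}
    dist = rank_distribution(values, repetitions=25, seed=0)
    np.testing.assert_allclose(np.diag(dist.loc[list(ITEMS)]), 100.0)


def test_single_repetition_is_an_indicator_table():
    values = {"only": pd.Series([0.3, 0.9, 0.1], index=("A", "B", "C"))}
    dist = rank_distribution(values, repetitions=1, seed=0)
    assert set(np.unique(dist.to_numpy())) == {0.0, 100.0}
    assert dist.loc["B", "N1"] == 100.0


def test_method_values_collapses_auc_to_four_schemes(tmp_path):
    ds = af.generate_dataset(af.SyntheticSpec(
        n_pos=16, n_neg=20, p=3, delta=1.0, seed=31, name="mv"))
    table = af.cross_validate(ds, af.ForestConfig(n_trees=15), seed=2)
    auc_values = method_values(table, "AUC")
    assert sorted(auc_values.index) == sorted(
        ["Avg Prob", "Voting Prob INB", "Voting Prob Train", "Voting Prob 0.5"])
    score_values = method_values(table, "score")
    assert len(score_values) == 10
    with pytest.raises(ValueError):
        method_values(table, "accuracy")
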