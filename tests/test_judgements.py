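"""Depth-order reconstruction, merit, discordance and tau."""

import random
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relief_districts import (
    DepthOrder,
    DepthOrderModel,
    JudgementSet,
    PairJudgement,
    depth_order,
    discordant_pairs,
    kendall_tau,
    merit,
    n_pairs,
)
from conftest import all_weak_orders, brute_merit, brute_tau_b


def js_of(pairs, observer="o", session="s"):
    return JudgementSet(observer, session, [PairJudgement(*p) for p in pairs])


def truthful_complete(ranks, observer="o", session="s"):
    """Complete truthful session for a strict ranking (rank 0 = nearest)."""
    v = len(ranks)
    return js_of(
        [(a, b, a if ranks[a] < ranks[b] else b) for a, b in combinations(range(v), 2)],
        observer, session,
    )


# ----------------------------------------------------------------------
def test_n_pairs_stimulus_scale():
    assert n_pairs(57) == 1596


@pytest.mark.parametrize("v,expected", [(2, 1), (10, 45), (57, 1596)])
def test_n_pairs_closed_form(v, expected):
    assert n_pairs(v) == expected


def test_n_pairs_domain_error():
    with pytest.raises(ValueError):
        n_pairs(1)


def test_depth_order_transitive_tournament():
    js = js_of([(0, 1, 0), (0, 2, 0), (1, 2, 1)])
    order = depth_order(js, 3)
    np.testing.assert_array_equal(order.win_counts, [2, 1, 0])
    np.testing.assert_array_equal(order.ranks, [0, 1, 2])
    assert order.levels == 3


def test_depth_order_cycle_is_total_tie():
    js = js_of([(0, 1, 0), (1, 2, 1), (0, 2, 2)])
    order = depth_order(js, 3)
    np.testing.assert_array_equal(order.win_counts, [1, 1, 1])
    np.testing.assert_array_equal(order.ranks, [0, 0, 0])
    assert order.levels == 1


def test_depth_order_random_tournament_counts_descend():
    rng = random.Random(7)
    js = js_of([(a, b, rng.choice((a, b))) for a, b in combinations(range(4), 2)])
    order = depth_order(js, 4)
    by_rank = sorted(range(4), key=lambda v: order.ranks[v])
    counts = [order.win_counts[v] for v in by_rank]
    assert counts == sorted(counts, reverse=True)


def test_depth_order_duplicate_pair_rejected():
    js = js_of([(0, 1, 0), (1, 0, 1)])
    with pytest.raises(ValueError, match="duplicate"):
        depth_order(js, 2)


def test_depth_order_shuffle_invariant():
    rng = random.Random(11)
    pairs = [(a, b, rng.choice((a, b))) for a, b in combinations(range(6), 2)]
    ref = depth_order(js_of(pairs), 6)
    for _ in range(5):
        rng.shuffle(pairs)
        again = depth_order(js_of(pairs), 6)
        np.testing.assert_array_equal(again.ranks, ref.ranks)


# ----------------------------------------------------------------------
def test_merit_consistent_set_is_one():
    js = js_of([(0, 1, 0), (0, 2, 0), (1, 2, 1)])
    assert merit(js, depth_order(js, 3)) == 1.0


def test_merit_against_reversed_external_order_is_minus_one():
    ranks = [0, 1, 2, 3]
    js = truthful_complete(ranks)
    reversed_order = DepthOrder(ranks=ranks[::-1], win_counts=np.zeros(4))
    assert merit(js, reversed_order) == -1.0


def test_merit_one_inverted_judgement_matches_oracle():
    ranks = list(range(5))
    js = truthful_complete(ranks)
    # invert the judgement on the extreme pair (0,4)
    flipped = [
        PairJudgement(j.a, j.b, j.a + j.b - j.chosen)
        if {j.a, j.b} == {0, 4} else j
        for j in js.judgements
    ]
    js = JudgementSet("o", "s", flipped)
    order = depth_order(js, 5)
    assert merit(js, order) == pytest.approx(brute_merit(js.judgements, order.ranks))
    # the flip ties (0,1) and (3,4) in the counts: those 2 pairs leave C and D
    # but stay in N, and the flipped pair itself is discordant
    assert merit(js, order) == pytest.approx((7 - 1) / 10)


def test_merit_empty_set_rejected():
    with pytest.raises(ValueError):
        merit(JudgementSet("o", "s", []), DepthOrder(ranks=[0], win_counts=[0]))


def test_count_order_is_merit_optimal_on_mostly_consistent_data():
    """On near-transitive data the win-count order attains the global optimum.

    Exhaustive check over all weak orders of 5 vertices, for truthful
    tournaments with a single planted inversion.  (On heavily cyclic random
    tournaments the count order is only a heuristic for the NP-hard
    maximum-concordance ordering, so no claim is made there.)
    """
    from itertools import permutations

    for flip_pair in ({0, 4}, {1, 3}, {0, 2}):
        base = truthful_complete(list(range(5)))
        flipped = [
            PairJudgement(j.a, j.b, j.a + j.b - j.chosen)
            if {j.a, j.b} == flip_pair else j
            for j in base.judgements
        ]
        js = JudgementSet("o", "s", flipped)
        counts = depth_order(js, 5).win_counts
        best_completion = max(
            brute_merit(js.judgements, _ranks_of(perm))
            for perm in permutations(range(5))
            if all(counts[perm[i]] >= counts[perm[i + 1]] for i in range(4))
        )
        best_alt = max(
            brute_merit(js.judgements, list(r)) for r in all_weak_orders(5)
        )
        assert best_completion == pytest.approx(best_alt)


def _ranks_of(perm):
    ranks = [0] * len(perm)
    for i, v in enumerate(perm):
        ranks[v] = i
    return ranks


def test_merit_one_iff_no_discord_and_no_judged_tie():
    js = js_of([(0, 1, 0), (0, 2, 0), (1, 2, 1)])
    order = depth_order(js, 3)
    assert merit(js, order) == 1.0
    assert len(discordant_pairs(js, order)) == 0
    # a cyclic set produces consensus ties: merit < 1 though nothing is discordant
    cyc = js_of([(0, 1, 0), (1, 2, 1), (0, 2, 2)])
    cyc_order = depth_order(cyc, 3)
    assert len(discordant_pairs(cyc, cyc_order)) == 0
    assert merit(cyc, cyc_order) < 1.0


# ----------------------------------------------------------------------
def test_discordant_fully_consistent_empty():
    js = js_of([(0, 1, 0), (0, 2, 0), (1, 2, 1)])
    assert len(discordant_pairs(js, depth_order(js, 3))) == 0


def test_discordant_planted_inversion_recovered():
    v = 10
    ranks = list(range(v))
    js = truthful_complete(ranks)
    # invert the judgement on (0, 9); win counts stay strictly descending
    flipped = [
        PairJudgement(j.a, j.b, j.a + j.b - j.chosen)
        if {j.a, j.b} == {0, 9} else j
        for j in js.judgements
    ]
    js = JudgementSet("o", "s", flipped)
    order = depth_order(js, v)
    # the flip ties (0,1) and (8,9) in the counts; those pairs become
    # consensus-tied and are never discordant, leaving exactly the flip
    assert discordant_pairs(js, order).pairs == {(0, 9)}


def test_discordant_total_tie_is_empty():
    cyc = js_of([(0, 1, 0), (1, 2, 1), (0, 2, 2)])
    assert len(discordant_pairs(cyc, depth_order(cyc, 3))) == 0


# ----------------------------------------------------------------------
def test_kendall_tau_identity_and_reversal():
    a = DepthOrder(ranks=np.arange(6), win_counts=np.zeros(6))
    b = DepthOrder(ranks=np.arange(6)[::-1], win_counts=np.zeros(6))
    assert kendall_tau(a, a) == pytest.approx(1.0)
    assert kendall_tau(a, b) == pytest.approx(-1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    r1=st.lists(st.integers(0, 3), min_size=8, max_size=8),
    r2=st.lists(st.integers(0, 3), min_size=8, max_size=8),
)
def test_kendall_tau_matches_brute_force_with_ties(r1, r2):
    expected = brute_tau_b(r1, r2)
    if np.isnan(expected):
        return  # constant ranking: tau undefined
    assert kendall_tau(np.array(r1), np.array(r2)) == pytest.approx(expected)


def test_kendall_tau_size_mismatch():
    with pytest.raises(ValueError):
        kendall_tau(np.arange(3), np.arange(4))


# ----------------------------------------------------------------------
def test_model_results_and_csv_round_trip(tmp_path):
    from relief_districts.judgements import read_judgements_csv, write_judgements_csv

    js = truthful_complete(list(range(4)), observer="a", session="s1")
    res = DepthOrderModel(js, 4).fit()
    assert res.merit == 1.0
    assert res.n_discordant == 0
    assert res.levels == 4
    assert "number of merit" in res.summary()

    path = tmp_path / "j.csv"
    write_judgements_csv([js], path)
    back = read_judgements_csv(path)
    assert len(back) == 1
    assert back[0].judgements == js.judgements
    res2 = DepthOrderModel.from_dataframe(
        __import__("pandas").read_csv(path), 4
    ).fit()
    np.testing.assert_array_equal(res2.ranks, res.ranks)
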