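"""Exact/at-least combination counting and Apriori candidate generation."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyrx import combos
from polyrx.combos import (
    ExactComboTable,
    atleast_count,
    atleast_count_naive,
    class_exposures,
    combo_key,
    exact_combo_counts,
    generate_candidates,
)

from conftest import make_exposures


def test_exact_counts_direct_grouping():
    exposures = make_exposures(
        [("p", 0, "A"), ("p", 0, "B"), ("p", 1, "A"), ("q", 0, "A"), ("q", 0, "B")]
    )
    exact = exact_combo_counts(exposures)
    assert exact.counts == {("A", "B"): 2, ("A",): 1}
    assert exact.total_exposed_windows == 3


def test_exact_counts_empty():
    exact = exact_combo_counts(make_exposures([]))
    assert exact.counts == {}
    assert exact.total_exposed_windows == 0


def test_single_window_contributes_one_exact_key():
    exact = exact_combo_counts(
        make_exposures([("p", 0, "A"), ("p", 0, "B"), ("p", 0, "C")])
    )
    assert exact.counts == {("A", "B", "C"): 1}


def test_atleast_enumeration_of_one_window():
    # a single {A,B,C} window supports every non-empty subset once
    exact = exact_combo_counts(
        make_exposures([("p", 0, "A"), ("p", 0, "B"), ("p", 0, "C")])
    )
    for r in (1, 2, 3):
        for q in combinations("ABC", r):
            assert atleast_count(q, exact) == 1


def test_atleast_superset_sum():
    exact = ExactComboTable({("A", "B"): 2, ("A",): 1}, 3)
    assert atleast_count(("A",), exact) == 3
    assert atleast_count(("A", "B"), exact) == 2
    assert atleast_count(("Z",), exact) == 0
    assert atleast_count(("A", "Z"), exact) == 0


def test_conservation_invariant_checked():
    with pytest.raises(ValueError, match="exact counts sum"):
        ExactComboTable({("A",): 1}, 2)


@given(
    st.lists(
        st.tuples(
            st.integers(0, 5),            # patient
            st.integers(0, 4),            # window
            st.sampled_from("ABCDEFGH"),  # drug
        ),
        min_size=1,
        max_size=60,
    )
)
@settings(max_examples=100, deadline=None)
def test_index_equals_naive_superset_sum(rows):
    exposures = make_exposures(
        [(f"p{p}", w, d) for p, w, d in rows]
    ).drop_duplicates()
    exact = exact_combo_counts(exposures)
    items = exact.observed_items()
    for r in (1, 2, 3):
        for q in combinations(items, r):
            assert atleast_count(q, exact) == atleast_count_naive(q, exact)


def test_window_contributes_to_all_nonempty_subsets(small_ingredient_claims):
    # each k-drug window supports exactly 2^k - 1 at-least keys
    from polyrx import windowing

    exposures, _ = windowing.build_exposure_table(small_ingredient_claims)
    exact = exact_combo_counts(exposures)
    total_subset_contributions = sum(
        (2 ** len(k) - 1) * c for k, c in exact.counts.items()
    )
    all_keys = {
        q
        for k in exact.counts
        for r in range(1, len(k) + 1)
        for q in combinations(k, r)
    }
    assert sum(atleast_count_naive(q, exact) for q in all_keys) == (
        total_subset_contributions
    )


def test_candidate_pairs_from_qualifying_singles():
    prev = {("A",): 10, ("B",): 10, ("C",): 10, ("D",): 2}
    cands = generate_candidates(2, prev, support_threshold=5)
    assert cands == {("A", "B"), ("A", "C"), ("B", "C")}


def test_candidate_prune_requires_all_subsets():
    # BC below threshold -> ABC must not be emitted
    prev = {("A", "B"): 10, ("A", "C"): 10, ("B", "C"): 3}
    assert generate_candidates(3, prev, support_threshold=5) == set()
    prev[("B", "C")] = 5
    assert generate_candidates(3, prev, support_threshold=5) == {("A", "B", "C")}


def test_candidate_threshold_zero_is_full_enumeration():
    prev = {("A",): 1, ("B",): 0, ("C",): 3}
    cands = generate_candidates(2, prev, support_threshold=0)
    assert cands == {("A", "B"), ("A", "C"), ("B", "C")}


def test_candidate_size_bounds():
    with pytest.raises(ValueError, match="2..5"):
        generate_candidates(6, {}, 1)
    with pytest.raises(ValueError, match="2..5"):
        generate_candidates(1, {}, 1)
    # configurable ceiling: N=6 allowed when max_n raised
    prev = {q: 5 for q in combinations("ABCDEF", 5)}
    assert generate_candidates(6, prev, 1, max_n=6) == {combo_key("ABCDEF")}


@pytest.mark.parametrize("threshold", [1, 5, 20])
def test_candidate_completeness_against_brute_force(
    small_ingredient_claims, threshold
):
    """No N-combo reaching the support threshold escapes the Apriori gate."""
    from polyrx import windowing

    exposures, _ = windowing.build_exposure_table(small_ingredient_claims)
    exact = exact_combo_counts(exposures)
    singles = [(d,) for d in exact.observed_items()]
    at_least = {k: atleast_count(k, exact) for k in singles}
    prev = dict(at_least)
    for n in range(2, 6):
        cands = generate_candidates(n, prev, support_threshold=threshold)
        counts = {k: atleast_count(k, exact) for k in cands}
        # brute force: every n-subset of an exact key with count >= threshold
        brute = {}
        for key, _ in exact.counts.items():
            for q in combinations(key, n):
                if q not in brute:
                    brute[q] = atleast_count_naive(q, exact)
        qualifying = {q for q, c in brute.items() if c >= threshold}
        assert qualifying <= cands
        prev = counts


def test_class_exposures_dedup_and_tally(demo_map):
    # lisinopril and losartan share class C09; metformin is A10
    exposures = make_exposures(
        [
            ("p", 0, "lisinopril"),
            ("p", 0, "losartan"),
            ("p", 0, "metformin"),
        ]
    )
    out, n_dropped = class_exposures(exposures, demo_map)
    assert n_dropped == 0
    assert set(map(tuple, out.values)) == {("p", 0, "A10"), ("p", 0, "C09")}


def test_class_exposures_unclassified_dropped(demo_map):
    from polyrx.vocab import DrugMapping, IngredientInfo

    info = dict(demo_map.ingredient_info)
    info["mystery"] = IngredientInfo("RX1", "C1", "DB1", "", "")
    m = DrugMapping(
        code_to_ingredients={**demo_map.code_to_ingredients, "mystery": {"mystery"}},
        ingredient_info=info,
    )
    exposures = make_exposures([("p", 0, "metformin"), ("p", 0, "mystery")])
    out, n_dropped = class_exposures(exposures, m)
    assert n_dropped == 1
    assert set(out["ingredient"]) == {"A10"}


def test_class_atleast_coarsening_never_loses_windows(
    small_ingredient_claims, demo_map
):
    """At class level, a query of distinct classes covers at least the
    windows of any ingredient query mapping onto those classes."""
    from polyrx import windowing
    from polyrx.vocab import primary_class

    exposures, _ = windowing.build_exposure_table(small_ingredient_claims)
    exact_ing = exact_combo_counts(exposures)
    cls, _ = class_exposures(exposures, demo_map)
    exact_cls = exact_combo_counts(cls)
    for pair in [("metformin", "lisinopril"), ("sertraline", "omeprazole")]:
        classes = combo_key(primary_class(d, demo_map) for d in pair)
        assert len(classes) == 2
        assert atleast_count(classes, exact_cls) >= atleast_count(pair, exact_ing)
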