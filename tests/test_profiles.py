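"""Co-drug profiles, exposure distributions, outcome RR, sensitivities."""

import numpy as np
import pandas as pd
import pytest

from polyrx import combos, profiles, synthetic, vocab, windowing
from polyrx.profiles import (
    codrug_profile,
    cohort_size_sensitivity,
    exposure_count_distribution,
    first_events,
    outcome_relative_risk,
    window_duration_sensitivity,
)
from polyrx.synthetic import CohortSimConfig, ConditionSpec

from conftest import make_exposures


def pair_stats(rows):
    return pd.DataFrame(
        rows, columns=["combo", "atleast_exposure_count", "observe_per_expect_1s"]
    )


def test_codrug_profile_normalization():
    pairs = pair_stats(
        [
            {"combo": ("d", "t"), "atleast_exposure_count": 250,
             "observe_per_expect_1s": 2.0},
            {"combo": ("e", "t"), "atleast_exposure_count": 100,
             "observe_per_expect_1s": 0.5},
            {"combo": ("x", "y"), "atleast_exposure_count": 999,
             "observe_per_expect_1s": 9.9},
        ]
    )
    out = codrug_profile("t", pairs, 1000)
    assert list(out["codrug"]) == ["d", "e"]  # unrelated pair excluded
    assert out["p_coexposure_given_exposure"].tolist() == [0.25, 0.10]
    assert out["observed_per_expected"].tolist() == [2.0, 0.5]
    assert list(out.columns) == [
        "codrug", "p_coexposure_given_exposure", "observed_per_expected",
    ]


def test_codrug_profile_requires_target_in_singles():
    singles = pd.DataFrame(
        {"combo": [("t",)], "atleast_exposure_count": [400]}
    )
    pairs = pair_stats(
        [{"combo": ("d", "t"), "atleast_exposure_count": 400,
          "observe_per_expect_1s": 1.0}]
    )
    out = codrug_profile("t", pairs, singles)
    # P = 1 iff the partner co-occurs in every target window
    assert out["p_coexposure_given_exposure"].tolist() == [1.0]
    with pytest.raises(KeyError, match="absent"):
        codrug_profile("zzz", pairs, singles)


def test_exposure_count_distribution_toy():
    exposures = make_exposures(
        [("p", 0, "A"), ("p", 1, "A"), ("p", 1, "B"),
         ("p", 2, "A"), ("p", 2, "B"), ("p", 2, "C")]
    )
    dist = exposure_count_distribution(exposures)
    assert dist.histogram == {1: 1, 2: 1, 3: 1}
    assert dist.median == 2.0
    assert dist.n_windows == 3


def test_exposure_count_distribution_planted_condition():
    config = CohortSimConfig(
        n_patients=25, seed=4,
        enrollment_months_distribution={12: 1.0},
        conditions=(ConditionSpec("c", 1.0, frozenset("ABCDE"), 1.0),),
    )
    cohort = synthetic.simulate_cohort(config)
    ing = cohort.claims.rename(columns={"drug_code": "ingredient"})
    exposures, _ = windowing.build_exposure_table(ing)
    dist = exposure_count_distribution(exposures)
    assert set(dist.histogram) == {5}
    assert dist.median == 5.0 and dist.p95 == 5.0


def test_exposure_count_distribution_empty_flagged():
    dist = exposure_count_distribution(make_exposures([]))
    assert dist.histogram == {} and dist.median is None and dist.p95 is None


def test_first_event_per_patient_only():
    events = pd.DataFrame(
        {"patient_id": ["p", "p", "q"], "event_age_days": [50, 20, 70]}
    )
    out = first_events(events)
    assert out.set_index("patient_id")["event_age_days"].to_dict() == {
        "p": 20, "q": 70,
    }


def _rr_setup(event_at, stats_rows):
    ing = pd.DataFrame(
        {
            "patient_id": ["p"] * 2,
            "ingredient": ["A", "B"],
            "fill_age_days": [100, 100],
            "days_supply": [30, 30],
        }
    )
    events = pd.DataFrame({"patient_id": ["p"], "event_age_days": [event_at]})
    stats = pd.DataFrame(
        stats_rows,
        columns=["combo", "atleast_exposure_count", "fraction_all_windows"],
    )
    return ing, events, stats


def test_outcome_rr_ratio_definition():
    # supply covers days 100-129; event at 140 -> lookback 110-139 overlaps
    ing, events, stats = _rr_setup(
        140, [{"combo": ("A", "B"), "atleast_exposure_count": 10,
               "fraction_all_windows": 0.01}]
    )
    out = outcome_relative_risk(stats, ing, events, min_occurrences=1)
    assert out["pre_event_fraction"].tolist() == [1.0]
    assert out["relative_risk"].iloc[0] == pytest.approx(100.0)


def test_outcome_rr_zero_when_never_pre_event():
    # event at 300: lookback 270-299 far past the supply -> RR 0
    ing, events, stats = _rr_setup(
        300, [{"combo": ("A", "B"), "atleast_exposure_count": 10,
               "fraction_all_windows": 0.01}]
    )
    out = outcome_relative_risk(stats, ing, events, min_occurrences=1)
    assert out["relative_risk"].tolist() == [0.0]


def test_outcome_rr_min_occurrence_filter_and_no_events():
    ing, events, stats = _rr_setup(
        140, [{"combo": ("A", "B"), "atleast_exposure_count": 10,
               "fraction_all_windows": 0.01}]
    )
    assert outcome_relative_risk(stats, ing, events, min_occurrences=11).empty
    assert outcome_relative_risk(stats, ing, events.iloc[0:0], min_occurrences=1).empty


def test_outcome_rr_independent_events_near_one(small_ingredient_claims, small_cohort):
    """Events scheduled independently of prescriptions give RR near 1 —
    the null centers between the cohort's exposed-window fraction and 1,
    because lookbacks sample all enrolled time while the denominator
    incidence is per exposed window."""
    exposures, _ = windowing.build_exposure_table(small_ingredient_claims)
    exact = combos.exact_combo_counts(exposures)
    w = windowing.count_exposed_windows(exposures)
    singles = [(d,) for d in exact.observed_items()]
    at_least = combos.atleast_counts(singles, exact)
    from polyrx.stats import compute_combo_stats

    stats1 = compute_combo_stats(singles, exact, w, at_least=at_least)
    top = stats1.head(3)

    rng = np.random.default_rng(17)
    elig = small_cohort.eligibility
    # uniform event day inside each patient's eligibility
    offs = rng.random(len(elig))
    events = pd.DataFrame(
        {
            "patient_id": elig["patient_id"],
            "event_age_days": (
                elig["start_age_days"]
                + (offs * (elig["end_age_days"] - elig["start_age_days"]))
                .astype(int)
            ),
        }
    )
    out = outcome_relative_risk(
        top, small_ingredient_claims, events, min_occurrences=1
    )
    # day-level lookback vs window incidence: agreement within sampling noise
    assert ((out["relative_risk"] > 0.5) & (out["relative_risk"] < 2.0)).all()


def test_window_sensitivity_monotone_and_degenerate(small_ingredient_claims):
    table = window_duration_sensitivity(small_ingredient_claims, [10, 30, 90])
    means = table["mean_drugs_per_window"].tolist()
    assert means == sorted(means)
    single = window_duration_sensitivity(small_ingredient_claims, [30])
    assert len(single) == 1 and single["window_days"].iloc[0] == 30


def test_window_sensitivity_single_claim_alignment():
    # a boundary-aligned 30-day claim occupies one 30-day window
    ing = pd.DataFrame(
        {"patient_id": ["p"], "ingredient": ["A"],
         "fill_age_days": [90], "days_supply": [30]}
    )
    table = window_duration_sensitivity(ing, [10, 30, 40])
    by_d = table.set_index("window_days")["n_exposed_windows"]
    assert by_d[30] == 1
    assert (by_d >= 1).all()
    assert by_d[10] == 3


def test_cohort_sensitivity_identity_and_determinism(small_ingredient_claims):
    n = small_ingredient_claims["patient_id"].nunique()
    a = cohort_size_sensitivity(small_ingredient_claims, [n, n // 3], seed=5)
    b = cohort_size_sensitivity(small_ingredient_claims, [n, n // 3], seed=5)
    pd.testing.assert_frame_equal(a, b)
    full = a.iloc[0]
    assert full["topk_overlap"] == 1.0
    assert full["topk_rank_correlation"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="exceeds"):
        cohort_size_sensitivity(small_ingredient_claims, [n + 1], seed=5)


def test_cohort_sensitivity_once_observed_fraction_trend(small_ingredient_claims):
    """Smaller cohorts overestimate the once-observed combination fraction
    (direction asserted over replicates, not any printed value)."""
    n = small_ingredient_claims["patient_id"].nunique()
    small_vals, large_vals = [], []
    for seed in range(5):
        t = cohort_size_sensitivity(
            small_ingredient_claims, [n // 6, n], seed=seed
        )
        small_vals.append(t.iloc[0]["fraction_once_observed"])
        large_vals.append(t.iloc[1]["fraction_once_observed"])
    assert np.mean(small_vals) >= np.mean(large_vals)
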