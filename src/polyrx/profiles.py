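"""Usage-note analyses and technical-validation procedures.

* co-drug profiles — conditional co-exposure probabilities for one target
  drug or class, from the pair-level record table;
* per-window distinct-drug distributions (histogram, median, 95th
  percentile over exposed windows);
* relative risk of combination exposure in the 30 days before an outcome
  event (first event per patient) versus overall incidence;
* sensitivity of mean concomitant-exposure counts to the window duration;
* sensitivity of combination rankings and once-observed fractions to
  cohort size, by patient-level subsampling.

All procedures are pure functions of (claims/exposures, parameters,
seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import combos, windowing
from .combos import ExactComboTable, atleast_count, combo_key, window_drug_sets


def codrug_profile(
    target: str,
    pair_stats: pd.DataFrame,
    single_stats: pd.DataFrame | int,
) -> pd.DataFrame:
    """Common co-exposures with one target drug (or class).

    For every partner ``d`` appearing with the target in the pair-level
    (N=2) statistics table, reports ``P(co-exposure | exposure)`` =
    at_least({target, d}) / at_least({target}) and the pair's
    observed/expected ratio. Partners never co-observed with the target
    have no pair record and are absent (not zero rows).

    Parameters
    ----------
    target
        Drug ingredient or class of interest; must be present in the
        single-drug table.
    pair_stats
        N=2 statistics table (columns ``combo``, ``atleast_exposure_count``,
        ``observe_per_expect_1s``).
    single_stats
        The N=1 statistics table (the target's at-least count, the
        normalization denominator, is looked up there), or that count
        directly as an integer.
    """
    mask = pair_stats["combo"].map(lambda k: target in k)
    pairs = pair_stats.loc[mask]
    if isinstance(single_stats, pd.DataFrame):
        hit = single_stats.loc[single_stats["combo"] == (target,)]
        if hit.empty:
            raise KeyError(f"target {target!r} absent from the single-drug table")
        target_atleast = int(hit["atleast_exposure_count"].iloc[0])
    else:
        target_atleast = int(single_stats)
    if target_atleast <= 0:
        raise ValueError(f"target {target!r} has no exposed windows")
    partners = pairs["combo"].map(lambda k: next(d for d in k if d != target))
    out = pd.DataFrame(
        {
            "codrug": partners.to_numpy(),
            "p_coexposure_given_exposure": (
                pairs["atleast_exposure_count"] / target_atleast
            ).to_numpy(),
            "observed_per_expected": pairs["observe_per_expect_1s"].to_numpy(),
        }
    )
    return out.sort_values(
        "p_coexposure_given_exposure", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class ExposureCountDistribution:
    """Distribution of distinct drugs (or classes) per exposed window."""

    histogram: dict[int, int]
    median: float | None
    p95: float | None
    n_windows: int


def exposure_count_distribution(exposures: pd.DataFrame) -> ExposureCountDistribution:
    """Histogram plus median and 95th percentile of per-exposed-window
    distinct-drug counts. Windows with no drugs are not part of the
    distribution; an empty exposure table yields flagged (None) quantiles."""
    if exposures.empty:
        return ExposureCountDistribution({}, None, None, 0)
    sizes = exposures.groupby(["patient_id", "window_index"], sort=False)[
        "ingredient"
    ].nunique()
    hist = sizes.value_counts().sort_index()
    return ExposureCountDistribution(
        histogram={int(k): int(v) for k, v in hist.items()},
        median=float(np.median(sizes)),
        p95=float(np.quantile(sizes, 0.95)),
        n_windows=int(len(sizes)),
    )


def first_events(events: pd.DataFrame) -> pd.DataFrame:
    """Only the first outcome event per patient is used."""
    return (
        events.sort_values(["patient_id", "event_age_days"], kind="mergesort")
        .drop_duplicates("patient_id", keep="first")
        .reset_index(drop=True)
    )


def outcome_relative_risk(
    combo_stats: pd.DataFrame,
    ingredient_claims: pd.DataFrame,
    events: pd.DataFrame,
    min_occurrences: int = 5000,
    lookback_days: int = 30,
) -> pd.DataFrame:
    """Relative risk of combination exposure in the pre-event lookback.

    For each combination in ``combo_stats`` with at-least count >=
    ``min_occurrences``, compares the fraction of pre-event lookback
    periods (the ``lookback_days`` days ending the day before each
    patient's first event) exposed to the combination against the
    combination's ``fraction_all_windows``. A day-level lookback is used
    rather than the event's discrete calendar window, so the lookback is
    never truncated at a window boundary.

    Returns a table (combo, pre_event_exposed, n_events, pre_event_fraction,
    overall_fraction, relative_risk) sorted by descending relative risk.
    """
    events = first_events(events)
    qualifying = combo_stats.loc[
        combo_stats["atleast_exposure_count"] >= min_occurrences
    ]
    if events.empty or qualifying.empty:
        return pd.DataFrame(
            columns=[
                "combo", "pre_event_exposed", "n_events",
                "pre_event_fraction", "overall_fraction", "relative_risk",
            ]
        )

    # ingredients exposed during each patient's lookback, by day overlap
    merged = ingredient_claims.merge(events, on="patient_id", how="inner")
    lb_start = merged["event_age_days"] - lookback_days
    lb_end = merged["event_age_days"] - 1
    covers = (merged["fill_age_days"] <= lb_end) & (
        merged["fill_age_days"] + merged["days_supply"] - 1 >= lb_start
    )
    exposed = merged.loc[covers, ["patient_id", "ingredient"]].drop_duplicates()
    by_patient = exposed.groupby("patient_id")["ingredient"].agg(set)

    n_events = len(events)
    rows = []
    for rec in qualifying.itertuples():
        key = set(rec.combo)
        n_pre = int(
            sum(1 for s in by_patient if key.issubset(s))
        )
        pre_frac = n_pre / n_events
        overall = rec.fraction_all_windows
        rr = pre_frac / overall if overall > 0 else float("nan")
        rows.append(
            {
                "combo": rec.combo,
                "pre_event_exposed": n_pre,
                "n_events": n_events,
                "pre_event_fraction": pre_frac,
                "overall_fraction": overall,
                "relative_risk": rr,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["relative_risk", "combo"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


DEFAULT_SENSITIVITY_DURATIONS = (10, 20, 30, 40, 50, 60, 90)


def window_duration_sensitivity(
    ingredient_claims: pd.DataFrame,
    durations=DEFAULT_SENSITIVITY_DURATIONS,
    top_k: int = 100,
) -> pd.DataFrame:
    """Re-run windowing and counting at several window durations.

    Because every overlapping supply exposes the whole window, longer
    windows can only add concomitance: the mean distinct-drug count per
    exposed window is non-decreasing in the duration. Reports, per
    duration: exposed-window count, mean and median distinct drugs per
    exposed window, and the top-K exact combinations by count.
    """
    rows = []
    for d in durations:
        exposures, _ = windowing.build_exposure_table(
            ingredient_claims, windowing.WindowingConfig(window_days=int(d))
        )
        sets = window_drug_sets(exposures)
        sizes = sets.map(len)
        exact = combos.exact_combo_counts(exposures)
        ranked = sorted(exact.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        rows.append(
            {
                "window_days": int(d),
                "n_exposed_windows": int(len(sets)),
                "mean_drugs_per_window": float(sizes.mean()) if len(sizes) else float("nan"),
                "median_drugs_per_window": float(sizes.median()) if len(sizes) else float("nan"),
                "top_combos": [k for k, _ in ranked[:top_k]],
            }
        )
    return pd.DataFrame(rows)


def cohort_size_sensitivity(
    ingredient_claims: pd.DataFrame,
    sample_sizes,
    seed: int,
    window_days: int = 30,
    top_k: int = 100,
) -> pd.DataFrame:
    """Effect of cohort size on combination rankings and rare combos.

    Subsamples patients without replacement at each size (fixed seed),
    re-runs windowing and exact counting, and reports the fraction of
    exposed windows carrying a once-observed exact combination (smaller
    cohorts overestimate it) plus the agreement of the top-K at-least
    ranking (singles and pairs) with the full cohort: overlap fraction
    and Spearman rank correlation on the shared keys.
    """
    patients = np.sort(ingredient_claims["patient_id"].unique())
    rng = np.random.default_rng(seed)

    def _run(claims: pd.DataFrame):
        exposures, _ = windowing.build_exposure_table(
            claims, windowing.WindowingConfig(window_days=window_days)
        )
        exact = combos.exact_combo_counts(exposures)
        singles = [(d,) for d in exact.observed_items()]
        pairs = combos.generate_candidates(
            2, combos.atleast_counts(singles, exact), support_threshold=1
        )
        at_least = {
            k: atleast_count(k, exact) for k in [*singles, *pairs]
        }
        ranked = sorted(
            (k for k, c in at_least.items() if c > 0),
            key=lambda k: (-at_least[k], k),
        )
        return exact, at_least, ranked[:top_k]

    full_exact, full_atleast, full_top = _run(ingredient_claims)

    rows = []
    for size in sample_sizes:
        if size > len(patients):
            raise ValueError(
                f"sample size {size} exceeds cohort size {len(patients)}"
            )
        chosen = rng.choice(patients, size=int(size), replace=False)
        sub = ingredient_claims[ingredient_claims["patient_id"].isin(set(chosen))]
        exact, at_least, top = _run(sub)
        n_combos = len(exact.counts)
        n_windows = exact.total_exposed_windows
        once = (
            sum(1 for c in exact.counts.values() if c == 1) / n_windows
            if n_windows
            else float("nan")
        )
        shared = [k for k in full_top if k in at_least and at_least[k] > 0]
        overlap = len(set(full_top) & set(top)) / len(full_top) if full_top else float("nan")
        if len(shared) >= 2:
            rho = float(
                spearmanr(
                    [full_atleast[k] for k in shared],
                    [at_least[k] for k in shared],
                ).statistic
            )
        else:
            rho = float("nan")
        rows.append(
            {
                "n_patients": int(size),
                "n_exact_combos": n_combos,
                "fraction_once_observed": once,
                "topk_overlap": overlap,
                "topk_rank_correlation": rho,
            }
        )
    return pd.DataFrame(rows)
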