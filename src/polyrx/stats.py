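"""Per-combination derived statistics.

For a combination S over a universe of W exposed windows (windows with at
least one prescription):

* ``fraction_exact``   = exact(S) / at_least(S)
* ``fraction_all_windows`` = at_least(S) / W
* ``observe_per_expect_1s`` (N > 1) — observed at-least incidence over the
  incidence expected under independence of the member drugs:
  ``at_least(S) / (W * prod_d at_least({d})/W)``
* ``observe_per_expect_N1`` (N > 2) — the minimum over the N ways of
  splitting S into an (N-1)-subset plus one drug of the observed/expected
  ratio for that split; it measures overrepresentation beyond what the
  subsets already explain. For N = 2 the two definitions coincide, so the
  subset variant is reported only for N > 2.
* ``estimate_drug_combo_cost_per_day`` — sum of the member ingredients'
  median per-day costs (ingredient level only; undefined for classes).

Undefined ratios (a zero marginal) are NaN sentinels, never 0 or inf.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .combos import ComboKey, ExactComboTable, atleast_count, combo_key

STATS_COLUMNS = [
    "combo",
    "atleast_exposure_count",
    "exact_exposure_count",
    "estimate_drug_combo_cost_per_day",
    "fraction_exact",
    "fraction_all_windows",
    "observe_per_expect_1s",
    "observe_per_expect_N1",
]


def overrep_singles(
    key: ComboKey, at_least: dict[ComboKey, int], w: int
) -> float:
    """Observed/expected ratio from single-drug marginal frequencies.

    Returns NaN when any member drug has zero at-least count (the
    expectation is undefined, not zero).
    """
    key = combo_key(key)
    if w <= 0:
        raise ValueError(f"window universe must be positive, got {w}")
    observed = at_least[key]
    expected = float(w)
    for drug in key:
        marginal = at_least[(drug,)]
        if marginal <= 0:
            return float("nan")
        expected *= marginal / w
    return observed / expected


def overrep_subsets(
    key: ComboKey,
    at_least: dict[ComboKey, int],
    w: int,
    exact: ExactComboTable | None = None,
) -> float:
    """Observed/expected ratio from (N-1)+1 subset splits; the smallest of
    the N split ratios is reported.

    For S = {A,B,C} the splits compare at_least(ABC) against the
    incidences of (AB, C), (AC, B) and (BC, A). Missing subset counts are
    computed on demand from ``exact`` when provided. Requires |S| > 2;
    returns NaN on any zero subset marginal.
    """
    key = combo_key(key)
    if len(key) <= 2:
        raise ValueError("subset-based overrepresentation requires N > 2")
    observed = at_least[key]
    best = math.inf
    for drug in key:
        rest = tuple(d for d in key if d != drug)
        n_rest = _lookup(rest, at_least, exact)
        n_drug = _lookup((drug,), at_least, exact)
        if n_rest <= 0 or n_drug <= 0:
            return float("nan")
        ratio = observed / (n_rest * n_drug / w)
        best = min(best, ratio)
    return best


def _lookup(
    key: ComboKey, at_least: dict[ComboKey, int], exact: ExactComboTable | None
) -> int:
    if key in at_least:
        return at_least[key]
    if exact is None:
        raise KeyError(f"at-least count for {key} unavailable")
    count = atleast_count(key, exact)
    at_least[key] = count
    return count


def combo_cost(key: ComboKey, costs: dict[str, float]) -> float:
    """Estimated daily cost of a combination: sum of the per-ingredient
    median per-day costs. Any missing ingredient makes the whole combo's
    cost NaN (explicit missingness, never 0)."""
    total = 0.0
    for ing in combo_key(key):
        if ing not in costs:
            return float("nan")
        total += costs[ing]
    return total


def compute_combo_stats(
    keys,
    exact: ExactComboTable,
    w_exposed: int,
    costs: dict[str, float] | None = None,
    at_least: dict[ComboKey, int] | None = None,
) -> pd.DataFrame:
    """Full statistics table for a set of same-size combination keys.

    Parameters
    ----------
    keys
        Combination keys, all of one size N.
    exact
        Summarized exact counts (at-least counts derive from it).
    w_exposed
        Number of windows with any prescription (the denominator universe
        for fractions and expected incidences).
    costs
        Per-ingredient daily costs; omit for class-level tables (cost
        column left NaN).
    at_least
        Optional pre-computed at-least counts, extended in place.

    Returns a DataFrame in :data:`STATS_COLUMNS` order, sorted by
    descending at-least count then canonical key; ratio columns not
    applicable at the table's N are NaN.
    """
    keys = sorted({combo_key(k) for k in keys})
    if not keys:
        return pd.DataFrame(columns=STATS_COLUMNS)
    sizes = {len(k) for k in keys}
    if len(sizes) != 1:
        raise ValueError(f"mixed combination sizes in one table: {sorted(sizes)}")
    n = sizes.pop()
    if at_least is None:
        at_least = {}
    for k in keys:
        _lookup(k, at_least, exact)
    for k in keys:
        for drug in k:
            _lookup((drug,), at_least, exact)

    rows = []
    for k in keys:
        al = at_least[k]
        ex = exact.counts.get(k, 0)
        rows.append(
            {
                "combo": k,
                "atleast_exposure_count": al,
                "exact_exposure_count": ex,
                "estimate_drug_combo_cost_per_day": (
                    combo_cost(k, costs) if costs is not None else np.nan
                ),
                "fraction_exact": ex / al if al > 0 else np.nan,
                "fraction_all_windows": al / w_exposed if w_exposed > 0 else np.nan,
                "observe_per_expect_1s": (
                    overrep_singles(k, at_least, w_exposed) if n > 1 else np.nan
                ),
                "observe_per_expect_N1": (
                    overrep_subsets(k, at_least, w_exposed, exact)
                    if n > 2
                    else np.nan
                ),
            }
        )
    df = pd.DataFrame(rows, columns=STATS_COLUMNS)
    df = df.sort_values(
        ["atleast_exposure_count", "combo"],
        ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df
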