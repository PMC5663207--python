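"""Brute-force day-level reference pipeline.

Materializes one row per exposed day and groups by ``day // window_days``
— an intentionally naive, obviously-correct counterpart to the integer
interval arithmetic in :mod:`polyrx.windowing`. It serves as the
independent oracle both for validating the fast scanner and for the
Monte-Carlo enrichment oracle in :mod:`polyrx.synthetic`; it never stands
on the main code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .windowing import EXPOSURE_COLUMNS


def day_level_exposures(
    ingredient_claims: pd.DataFrame, window_days: int = 30
) -> pd.DataFrame:
    """Deduplicated (patient, window, ingredient) exposures computed by
    expanding every claim into its individual exposed days."""
    claims = ingredient_claims[ingredient_claims["days_supply"] > 0]
    if claims.empty:
        return pd.DataFrame(columns=EXPOSURE_COLUMNS).astype(
            {"window_index": np.int64}
        )
    fill = claims["fill_age_days"].to_numpy(dtype=np.int64)
    supply = claims["days_supply"].to_numpy(dtype=np.int64)
    idx = np.repeat(np.arange(len(claims)), supply)
    day_offsets = np.arange(supply.sum()) - np.repeat(
        np.cumsum(supply) - supply, supply
    )
    days = np.repeat(fill, supply) + day_offsets
    exposures = pd.DataFrame(
        {
            "patient_id": claims["patient_id"].to_numpy()[idx],
            "window_index": days // window_days,
            "ingredient": claims["ingredient"].to_numpy()[idx],
        }
    )
    return (
        exposures.drop_duplicates()
        .sort_values(EXPOSURE_COLUMNS, kind="mergesort")
        .reset_index(drop=True)
    )


def pair_enrichment_day_level(
    ingredient_claims: pd.DataFrame, pair: tuple[str, str], window_days: int = 30
) -> float:
    """Observed/expected co-occurrence ratio of an ingredient pair from
    the day-level pipeline: ``n_AB * W / (n_A * n_B)`` over distinct
    exposed (patient, window) pairs. NaN when a marginal is zero."""
    a, b = pair
    exposures = day_level_exposures(ingredient_claims, window_days)
    if exposures.empty:
        return float("nan")
    windows = exposures.assign(
        is_a=exposures["ingredient"] == a, is_b=exposures["ingredient"] == b
    ).groupby(["patient_id", "window_index"], sort=False)[["is_a", "is_b"]].any()
    w = len(windows)
    n_a = int(windows["is_a"].sum())
    n_b = int(windows["is_b"].sum())
    if n_a == 0 or n_b == 0:
        return float("nan")
    n_ab = int((windows["is_a"] & windows["is_b"]).sum())
    return n_ab * w / (n_a * n_b)
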