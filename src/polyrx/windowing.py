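"""Discrete exposure windows from prescription claims.

Prescription fills are converted into drug exposures in non-overlapping
windows of patient age. A window is ``window_days`` long and anchored at
age 0: day *d* belongs to window ``d // window_days``. A dispensed supply
covers the closed day interval ``[fill_age_days, fill_age_days +
days_supply - 1]``; the patient is exposed in every window that interval
touches. Fixed anchoring creates partial windows of observation at the
start and end of each enrollment period (mean duration ~window_days/2
under uniformly random enrollment offsets).

Claims with a non-positive days-of-supply are rejected and tallied, never
silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EXPOSURE_COLUMNS = ["patient_id", "window_index", "ingredient"]


@dataclass(frozen=True)
class WindowingConfig:
    """Windowing parameters. ``window_days`` defaults to 30, the most
    common prescription duration and hence the natural exposure timescale."""

    window_days: int = 30

    def __post_init__(self) -> None:
        if self.window_days < 1:
            raise ValueError(f"window_days must be >= 1, got {self.window_days}")


def prescription_windows(
    fill_age_days: int, days_supply: int, window_days: int = 30
) -> range:
    """Window indices covered by one prescription.

    Returns the contiguous inclusive range ``floor(fill/w) ..
    floor((fill + supply - 1)/w)``.

    >>> list(prescription_windows(100, 30, 30))
    [3, 4]
    >>> list(prescription_windows(29, 2, 30))
    [0, 1]
    """
    if days_supply < 1:
        raise ValueError(f"days_supply must be >= 1, got {days_supply}")
    if fill_age_days < 0:
        raise ValueError(f"fill_age_days must be >= 0, got {fill_age_days}")
    first = fill_age_days // window_days
    last = (fill_age_days + days_supply - 1) // window_days
    return range(first, last + 1)


def build_exposure_table(
    ingredient_claims: pd.DataFrame, config: WindowingConfig | None = None
) -> tuple[pd.DataFrame, int]:
    """Convert ingredient-level claims into deduplicated window exposures.

    Parameters
    ----------
    ingredient_claims
        Columns ``patient_id``, ``ingredient``, ``fill_age_days``,
        ``days_supply`` (output of :func:`polyrx.vocab.expand_to_ingredients`).
    config
        Windowing parameters; defaults to 30-day windows.

    Returns
    -------
    (exposures, n_rejected)
        ``exposures`` has one row per (patient_id, window_index, ingredient),
        duplicates collapsed, sorted canonically. ``n_rejected`` counts
        claims dropped for days_supply <= 0.
    """
    if config is None:
        config = WindowingConfig()
    w = config.window_days

    claims = ingredient_claims
    bad = claims["days_supply"] <= 0
    n_rejected = int(bad.sum())
    if n_rejected:
        claims = claims.loc[~bad]
    if claims.empty:
        empty = pd.DataFrame(columns=EXPOSURE_COLUMNS)
        return empty.astype({"window_index": np.int64}), n_rejected

    fill = claims["fill_age_days"].to_numpy(dtype=np.int64)
    supply = claims["days_supply"].to_numpy(dtype=np.int64)
    first = fill // w
    last = (fill + supply - 1) // w
    span = last - first + 1

    # one output row per (claim, window) via repeat + ramped offsets
    idx = np.repeat(np.arange(len(claims)), span)
    offsets = np.arange(span.sum()) - np.repeat(np.cumsum(span) - span, span)
    windows = np.repeat(first, span) + offsets

    exposures = pd.DataFrame(
        {
            "patient_id": claims["patient_id"].to_numpy()[idx],
            "window_index": windows,
            "ingredient": claims["ingredient"].to_numpy()[idx],
        }
    )
    exposures = (
        exposures.drop_duplicates()
        .sort_values(EXPOSURE_COLUMNS, kind="mergesort")
        .reset_index(drop=True)
    )
    return exposures, n_rejected


def window_universe(
    eligibility: pd.DataFrame,
    exposures: pd.DataFrame,
    config: WindowingConfig | None = None,
) -> tuple[int, int, int]:
    """Count observation windows across the cohort.

    Returns ``(W_all, W_exposed, n_partial)`` where W_all is the number of
    (patient, window) pairs whose window intersects the patient's
    eligibility period, W_exposed the number with at least one exposure,
    and n_partial the number only partly covered by eligibility.

    Raises
    ------
    ValueError
        If any exposure falls outside its patient's eligible windows
        (a generator-contract violation) or eligibility is ill-formed.
    """
    if config is None:
        config = WindowingConfig()
    w = config.window_days

    if (eligibility["start_age_days"] > eligibility["end_age_days"]).any():
        raise ValueError("eligibility period with start_age_days > end_age_days")

    start = eligibility["start_age_days"].to_numpy(dtype=np.int64)
    end = eligibility["end_age_days"].to_numpy(dtype=np.int64)
    first = start // w
    last = end // w
    w_all = int((last - first + 1).sum())
    # a boundary window is partial unless eligibility covers it fully
    start_partial = start % w != 0
    end_partial = end % w != w - 1
    single = first == last
    n_partial = int(
        (single & (start_partial | end_partial)).sum()
        + (~single & start_partial).sum()
        + (~single & end_partial).sum()
    )

    if exposures.empty:
        return w_all, 0, n_partial

    w_exposed = int(
        exposures.drop_duplicates(["patient_id", "window_index"]).shape[0]
    )

    bounds = pd.DataFrame(
        {
            "patient_id": eligibility["patient_id"].to_numpy(),
            "_first": first,
            "_last": last,
        }
    )
    check = exposures.drop_duplicates(["patient_id", "window_index"]).merge(
        bounds, on="patient_id", how="left"
    )
    outside = (
        check["_first"].isna()
        | (check["window_index"] < check["_first"])
        | (check["window_index"] > check["_last"])
    )
    if outside.any():
        n_bad = int(outside.sum())
        raise ValueError(
            f"{n_bad} exposed (patient, window) pairs fall outside eligibility"
        )
    if w_exposed > w_all:
        raise ValueError("more exposed windows than observed windows")
    return w_all, w_exposed, n_partial


def partial_window_durations(
    eligibility: pd.DataFrame, config: WindowingConfig | None = None
) -> np.ndarray:
    """Observed durations (in days) of all partial windows.

    A partial window is a boundary window only partly covered by the
    patient's eligibility; its duration is the number of eligible days it
    contains. With uniformly random enrollment offsets and 30-day windows
    the mean is ~15 days.
    """
    if config is None:
        config = WindowingConfig()
    w = config.window_days
    start = eligibility["start_age_days"].to_numpy(dtype=np.int64)
    end = eligibility["end_age_days"].to_numpy(dtype=np.int64)
    first = start // w
    last = end // w
    durations: list[np.ndarray] = []
    single = first == last
    # patients spanning several windows: head and tail checked separately
    multi_start = start[~single]
    multi_end = end[~single]
    head = (first[~single] + 1) * w - multi_start
    durations.append(head[head < w])
    tail = multi_end - last[~single] * w + 1
    durations.append(tail[tail < w])
    # single-window patients: partial iff they do not cover the full window
    span = end[single] - start[single] + 1
    durations.append(span[span < w])
    return np.concatenate(durations) if durations else np.array([], dtype=np.int64)


def count_exposed_windows(exposures: pd.DataFrame) -> int:
    """Number of distinct (patient, window) pairs with any exposure."""
    if exposures.empty:
        return 0
    return int(exposures.drop_duplicates(["patient_id", "window_index"]).shape[0])
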