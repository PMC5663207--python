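"""Exact and "at-least" multi-drug combination counting.

Each exposed (patient, window) pair carries a set of distinct drug
ingredients (or ATC level-2 classes). Two counts are defined per
combination S:

* **exact** — windows whose complete drug set equals S (no additional
  drugs). Every exposed window contributes to exactly one exact key, so
  exact counts sum to the number of exposed windows.
* **at-least** — windows whose drug set contains S, possibly with
  additional drugs: ``at_least(S) = sum of exact(E) over E ⊇ S``.

At-least counting runs against the summarized exact table through a
per-drug inverted index (far fewer keys than raw windows). At-least
counts are anti-monotone (S ⊆ S' implies at_least(S) >= at_least(S')),
which justifies Apriori-style candidate generation: an N-combo can reach
a support threshold only if every (N-1)-subset does.

Combo keys are canonically sorted tuples, so equal sets compare equal and
output files are stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .vocab import UNCLASSIFIED, DrugMapping, primary_class

ComboKey = tuple[str, ...]


def combo_key(items) -> ComboKey:
    """Canonical (sorted, duplicate-free) key for a drug set."""
    return tuple(sorted(set(items)))


def window_drug_sets(exposures: pd.DataFrame) -> pd.Series:
    """Per-(patient, window) canonical drug tuple, as a Series indexed by
    (patient_id, window_index)."""
    if exposures.empty:
        return pd.Series(dtype=object)
    ordered = exposures.sort_values(
        ["patient_id", "window_index", "ingredient"], kind="mergesort"
    )
    return ordered.groupby(["patient_id", "window_index"], sort=False)[
        "ingredient"
    ].agg(tuple)


@dataclass
class ExactComboTable:
    """Exact window counts per canonical combination.

    Invariant: counts sum to ``total_exposed_windows``.
    """

    counts: dict[ComboKey, int]
    total_exposed_windows: int
    _index: dict[str, set[ComboKey]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != self.total_exposed_windows:
            raise ValueError(
                f"exact counts sum to {total}, expected "
                f"{self.total_exposed_windows} exposed windows"
            )

    @property
    def inverted_index(self) -> dict[str, set[ComboKey]]:
        """drug -> set of exact keys containing it (built lazily)."""
        if self._index is None:
            index: dict[str, set[ComboKey]] = {}
            for key in self.counts:
                for drug in key:
                    index.setdefault(drug, set()).add(key)
            self._index = index
        return self._index

    def observed_items(self) -> list[str]:
        return sorted(self.inverted_index)


def exact_combo_counts(exposures: pd.DataFrame) -> ExactComboTable:
    """Summarize deduplicated exposures into exact combination counts.

    Each exposed window contributes 1 to exactly one key: the canonical
    tuple of its distinct drugs.
    """
    sets = window_drug_sets(exposures)
    counts = sets.value_counts().to_dict() if not sets.empty else {}
    return ExactComboTable(
        counts={k: int(v) for k, v in counts.items()},
        total_exposed_windows=int(len(sets)),
    )


def atleast_count(query, exact: ExactComboTable) -> int:
    """At-least window count for a combination: sum of exact counts over
    all superset keys, found by intersecting the per-drug inverted index.

    Drugs never observed yield 0.
    """
    key = combo_key(query)
    if not key:
        raise ValueError("query combination must be non-empty")
    index = exact.inverted_index
    posting_lists = []
    for drug in key:
        postings = index.get(drug)
        if not postings:
            return 0
        posting_lists.append(postings)
    supersets = set.intersection(*sorted(posting_lists, key=len))
    return sum(exact.counts[k] for k in supersets)


def atleast_count_naive(query, exact: ExactComboTable) -> int:
    """Reference superset-sum without the index (oracle for tests)."""
    key = set(combo_key(query))
    if not key:
        raise ValueError("query combination must be non-empty")
    return sum(c for k, c in exact.counts.items() if key.issubset(k))


def atleast_counts(
    queries, exact: ExactComboTable
) -> dict[ComboKey, int]:
    """At-least counts for many queries at once."""
    return {combo_key(q): atleast_count(q, exact) for q in queries}


def generate_candidates(
    n: int,
    previous: dict[ComboKey, int],
    support_threshold: int = 1000,
    max_n: int = 5,
) -> set[ComboKey]:
    """Apriori candidate N-combos from threshold-qualifying (N-1)-combos.

    Emits every N-combo all of whose (N-1)-subsets appear in ``previous``
    with an at-least count >= ``support_threshold``. Anti-monotonicity
    guarantees no N-combo whose own at-least count reaches the threshold
    is missed. With threshold 0 this degenerates to full enumeration over
    the observed items.

    Parameters
    ----------
    n
        Target combination size, 2..max_n.
    previous
        At-least counts at size n-1 covering at least every (n-1)-combo
        meeting the threshold.
    """
    if not 2 <= n <= max_n:
        raise ValueError(f"combination size must be in 2..{max_n}, got {n}")
    qualifying = {k for k, c in previous.items() if c >= support_threshold}
    if any(len(k) != n - 1 for k in qualifying):
        raise ValueError(f"previous level must contain {n - 1}-item keys")
    if n == 2:
        singles = sorted(k[0] for k in qualifying)
        return {combo_key(p) for p in combinations(singles, 2)}
    # join step: pairs sharing their first n-2 items, then full-subset prune
    by_prefix: dict[ComboKey, list[str]] = {}
    for k in sorted(qualifying):
        by_prefix.setdefault(k[:-1], []).append(k[-1])
    candidates: set[ComboKey] = set()
    for prefix, tails in by_prefix.items():
        for a, b in combinations(sorted(tails), 2):
            cand = prefix + (a, b)
            if all(
                combo_key(sub) in qualifying
                for sub in combinations(cand, n - 1)
            ):
                candidates.add(cand)
    return candidates


def class_exposures(
    exposures: pd.DataFrame, mapping: DrugMapping
) -> tuple[pd.DataFrame, int]:
    """Translate ingredient exposures to primary ATC level-2 classes.

    Classes are counted once per window even when several ingredients of
    the window share a class. Ingredients with no usable ATC code are
    dropped and tallied.

    Returns
    -------
    (class_exposures, n_unclassified_dropped)
        Same schema as the input with ``ingredient`` holding the class
        code, deduplicated per (patient, window, class).
    """
    if exposures.empty:
        return exposures.copy(), 0
    classes = exposures["ingredient"].map(
        lambda ing: primary_class(ing, mapping)
    )
    out = exposures.assign(ingredient=classes)
    unclassified = out["ingredient"] == UNCLASSIFIED
    n_dropped = int(unclassified.sum())
    out = (
        out.loc[~unclassified]
        .drop_duplicates()
        .sort_values(["patient_id", "window_index", "ingredient"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out, n_dropped
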