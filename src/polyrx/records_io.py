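"""Publication-format combination-count records.

Two families of five tab-delimited files each, one file per combination
size N = 1..5:

* ``db_drugs_Ns.tsv`` — ingredient-level rows: N ``drug_name_*`` columns
  followed by the statistics columns (at-least count, exact count, daily
  cost estimate, fraction_exact, fraction_all_windows, and the two
  observed/expected ratios where applicable).
* ``db_atc_classes_Ns.tsv`` — class-level rows: N ``atc_code_*`` /
  ``atc_name_*`` column pairs, same statistics but no cost column (a
  daily cost cannot be calculated at the class level).

Emission policy: all combinations are included for N <= 2; for N = 3..5
only combinations with at-least count >= 10,000 (default). Exposure
counts below 100 windows are rendered as the mask token ``"<100"`` to
protect patient privacy; by default the mask applies to both count
columns (the conservative reading — configurable). Reading the files back
parses the mask into an explicit censored representation (flag + upper
bound), never into a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import DrugMapping

_SUFFIXES = "ABCDE"
_COUNT_COLUMNS = ["atleast_exposure_count", "exact_exposure_count"]
_FLOAT_FORMAT = "{:.6g}"


@dataclass(frozen=True)
class RecordEmissionPolicy:
    """Inclusion and privacy-masking rules for emitted records."""

    include_all_up_to_n: int = 2
    min_atleast_for_large_n: int = 10_000
    privacy_mask_threshold: int = 100
    mask_token: str = "<100"
    mask_both_counts: bool = True  # mask at-least too, not only exact

    def __post_init__(self) -> None:
        if self.include_all_up_to_n < 0:
            raise ValueError("include_all_up_to_n must be >= 0")
        if self.min_atleast_for_large_n < 0:
            raise ValueError("min_atleast_for_large_n must be >= 0")
        if self.privacy_mask_threshold < 0:
            raise ValueError("privacy_mask_threshold must be >= 0")
        if not self.mask_token:
            raise ValueError("mask_token must be non-empty")


def drug_record_columns(n: int) -> list[str]:
    """Header for the N-ingredient file: N name columns then statistics.
    Overrepresentation ratios apply only for N>1 (singles variant) and
    N>2 (subsets variant)."""
    cols = [f"drug_name_{s}" for s in _SUFFIXES[:n]]
    cols += [
        "atleast_exposure_count",
        "exact_exposure_count",
        "estimate_drug_cost_per_day",
        "fraction_exact",
        "fraction_all_windows",
    ]
    if n > 1:
        cols.append("observe_per_expect_1s")
    if n > 2:
        cols.append("observe_per_expect_N1")
    return cols


def class_record_columns(n: int) -> list[str]:
    """Header for the N-class file: code+name column pairs, statistics,
    no cost column."""
    cols = []
    for s in _SUFFIXES[:n]:
        cols += [f"atc_code_{s}", f"atc_name_{s}"]
    cols += [
        "atleast_exposure_count",
        "exact_exposure_count",
        "fraction_exact",
        "fraction_all_windows",
    ]
    if n > 1:
        cols.append("observe_per_expect_1s")
    if n > 2:
        cols.append("observe_per_expect_N1")
    return cols


def _apply_policy(stats: pd.DataFrame, n: int, policy: RecordEmissionPolicy) -> pd.DataFrame:
    df = stats
    if n > policy.include_all_up_to_n:
        df = df[df["atleast_exposure_count"] >= policy.min_atleast_for_large_n]
    return df.sort_values(
        ["atleast_exposure_count", "combo"],
        ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def _mask(value: int, policy: RecordEmissionPolicy) -> str:
    if value < policy.privacy_mask_threshold:
        return policy.mask_token
    return str(int(value))


def _fmt(value: float) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return _FLOAT_FORMAT.format(value)


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_drug_records(
    stats_by_n: dict[int, pd.DataFrame],
    policy: RecordEmissionPolicy,
    out_dir: str | Path,
) -> dict[int, Path]:
    """Write ``db_drugs_Ns.tsv`` for each N present in ``stats_by_n``.

    Rows are sorted by descending at-least count (ties by canonical key);
    combinations below the inclusion threshold are omitted for
    N > ``include_all_up_to_n``; count cells below the privacy threshold
    are rendered as the mask token.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[int, Path] = {}
    for n, stats in sorted(stats_by_n.items()):
        header = drug_record_columns(n)
        rows = []
        for rec in _apply_policy(stats, n, policy).itertuples():
            row = list(rec.combo)
            if len(row) != n:
                raise ValueError(
                    f"combo {rec.combo} has size {len(row)}, expected {n} "
                    f"(column drug_name_{_SUFFIXES[n - 1]})"
                )
            if policy.mask_both_counts:
                row.append(_mask(rec.atleast_exposure_count, policy))
            else:
                row.append(str(int(rec.atleast_exposure_count)))
            row.append(_mask(rec.exact_exposure_count, policy))
            row.append(_fmt(rec.estimate_drug_combo_cost_per_day))
            row.append(_fmt(rec.fraction_exact))
            row.append(_fmt(rec.fraction_all_windows))
            if n > 1:
                row.append(_fmt(rec.observe_per_expect_1s))
            if n > 2:
                row.append(_fmt(rec.observe_per_expect_N1))
            rows.append(row)
        path = out_dir / f"db_drugs_{n}s.tsv"
        _write_tsv(path, header, rows)
        paths[n] = path
    return paths


def write_class_records(
    stats_by_n: dict[int, pd.DataFrame],
    policy: RecordEmissionPolicy,
    out_dir: str | Path,
    mapping: DrugMapping | None = None,
) -> dict[int, Path]:
    """Write ``db_atc_classes_Ns.tsv`` per N; combos hold ATC level-2
    codes, names resolved through ``mapping.class_names`` (blank when
    unknown)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    class_names = mapping.class_names if mapping is not None else {}
    paths: dict[int, Path] = {}
    for n, stats in sorted(stats_by_n.items()):
        header = class_record_columns(n)
        rows = []
        for rec in _apply_policy(stats, n, policy).itertuples():
            if len(rec.combo) != n:
                raise ValueError(
                    f"combo {rec.combo} has size {len(rec.combo)}, expected {n} "
                    f"(column atc_code_{_SUFFIXES[n - 1]})"
                )
            row: list[str] = []
            for code in rec.combo:
                row += [code, class_names.get(code, "")]
            if policy.mask_both_counts:
                row.append(_mask(rec.atleast_exposure_count, policy))
            else:
                row.append(str(int(rec.atleast_exposure_count)))
            row.append(_mask(rec.exact_exposure_count, policy))
            row.append(_fmt(rec.fraction_exact))
            row.append(_fmt(rec.fraction_all_windows))
            if n > 1:
                row.append(_fmt(rec.observe_per_expect_1s))
            if n > 2:
                row.append(_fmt(rec.observe_per_expect_N1))
            rows.append(row)
        path = out_dir / f"db_atc_classes_{n}s.tsv"
        _write_tsv(path, header, rows)
        paths[n] = path
    return paths


def read_records(path: str | Path, mask_token: str = "<100") -> pd.DataFrame:
    """Read one record file back into a stats-like table.

    Mask tokens parse into a censored-count representation: the numeric
    column holds NA and a companion ``<col>_censored`` flag is set, with
    ``<col>_censored_bound`` giving the exclusive upper bound implied by
    the token. A censored cell written back with the same policy
    reproduces the token byte-identically.

    Raises
    ------
    ValueError
        On unknown columns or a row whose width disagrees with the header
        (reported with its line number).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        raw_rows = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path.name}:{lineno}: row has {len(fields)} fields, "
                    f"header has {len(header)}"
                )
            raw_rows.append(fields)

    n = sum(c.startswith(("drug_name_", "atc_code_")) for c in header)
    expected = (
        drug_record_columns(n) if header[0].startswith("drug_name_")
        else class_record_columns(n)
    )
    unknown = [c for c in header if c not in expected]
    if unknown:
        raise ValueError(f"{path.name}: unknown columns {unknown}")

    df = pd.DataFrame(raw_rows, columns=header)
    if not mask_token.startswith("<") or not mask_token[1:].isdigit():
        raise ValueError(f"mask token {mask_token!r} is not of the form '<bound>'")
    bound = int(mask_token[1:])
    for col in _COUNT_COLUMNS:
        if col not in df.columns:
            continue
        censored = df[col] == mask_token
        df[f"{col}_censored"] = censored.to_numpy()
        df[f"{col}_censored_bound"] = np.where(censored, bound, np.nan)
        df[col] = pd.array(
            [pd.NA if c else int(v) for v, c in zip(df[col], censored)],
            dtype="Int64",
        )
    float_cols = [
        c
        for c in (
            "estimate_drug_cost_per_day",
            "fraction_exact",
            "fraction_all_windows",
            "observe_per_expect_1s",
            "observe_per_expect_N1",
        )
        if c in df.columns
    ]
    for col in float_cols:
        df[col] = pd.to_numeric(df[col].replace("", np.nan))
    return df


def write_readme(out_dir: str | Path, max_n: int = 5) -> Path:
    """Emit a README.txt describing the record files in the directory."""
    out_dir = Path(out_dir)
    lines = [
        "Multi-drug combination exposure records",
        "",
        "Files:",
    ]
    for n in range(1, max_n + 1):
        lines.append(
            f"  db_drugs_{n}s.tsv        exposure counts for combinations of "
            f"{n} drug ingredient(s)"
        )
    for n in range(1, max_n + 1):
        lines.append(
            f"  db_atc_classes_{n}s.tsv  exposure counts for combinations of "
            f"{n} ATC level-2 drug class(es)"
        )
    lines += [
        "  drug_mappings_ingredients.tsv  drug ingredient vocabulary mappings",
        "  drug_mappings_atc_classes.tsv  ATC level-2 class codes and names",
        "",
        "All files are UTF-8, tab-delimited, with a header row.",
        "Exposure counts below the privacy threshold are reported as '<100'.",
    ]
    path = out_dir / "README.txt"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
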