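"""End-to-end orchestration: claims -> ingredient expansion -> exposure
windows -> exact/at-least counting -> statistics -> publication records.

A run is a pure function of (claims, eligibility, mapping, RunConfig).
The manifest records row counts at every stage so the conservation
invariants (exposures in = sum of per-window set sizes; exact counts sum
to the number of exposed windows) are auditable after the fact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import combos, records_io, stats, vocab, windowing
from .combos import ComboKey, ExactComboTable
from .records_io import RecordEmissionPolicy
from .synthetic import CLAIMS_COLUMNS, ELIGIBILITY_COLUMNS
from .windowing import WindowingConfig


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one pipeline run."""

    window_days: int = 30
    support_threshold: int = 1000  # Apriori gate for candidate N-combos
    max_n: int = 5
    policy: RecordEmissionPolicy = field(default_factory=RecordEmissionPolicy)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.max_n <= 5:
            raise ValueError(f"max_n must be in 1..5, got {self.max_n}")
        if self.support_threshold < 0:
            raise ValueError("support_threshold must be >= 0")
        WindowingConfig(self.window_days)  # validates


@dataclass
class CountingResult:
    """Exact table plus per-size at-least counts for one item level."""

    exact: ExactComboTable
    at_least_by_n: dict[int, dict[ComboKey, int]]
    candidates_by_n: dict[int, int]


def count_combinations(
    exposures: pd.DataFrame, support_threshold: int, max_n: int
) -> CountingResult:
    """Summarize exposures into exact counts and threshold-gated at-least
    counts for combination sizes 1..max_n.

    Size 1 covers every observed item; sizes 2..max_n cover the Apriori
    candidates generated from the threshold-qualifying level below, so no
    combination whose at-least count reaches the threshold is missed.
    Candidates never observed together (count 0) are dropped.
    """
    exact = combos.exact_combo_counts(exposures)
    singles = [(d,) for d in exact.observed_items()]
    at_least_by_n: dict[int, dict[ComboKey, int]] = {
        1: combos.atleast_counts(singles, exact)
    }
    candidates_by_n: dict[int, int] = {1: len(singles)}
    for n in range(2, max_n + 1):
        cands = combos.generate_candidates(
            n, at_least_by_n[n - 1], support_threshold, max_n=max_n
        )
        candidates_by_n[n] = len(cands)
        counts = combos.atleast_counts(cands, exact)
        at_least_by_n[n] = {k: c for k, c in counts.items() if c > 0}
        if not at_least_by_n[n]:
            break
    return CountingResult(exact, at_least_by_n, candidates_by_n)


@dataclass
class PipelineResult:
    drug_stats: dict[int, pd.DataFrame]
    class_stats: dict[int, pd.DataFrame]
    costs: dict[str, float]
    manifest: dict
    out_dir: Path | None = None


def run_pipeline(
    claims: pd.DataFrame,
    eligibility: pd.DataFrame,
    mapping: vocab.DrugMapping,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute all stages and (optionally) write the record files.

    Stages: ingredient expansion, exposure windowing, window-universe
    accounting, exact/at-least counting and statistics at ingredient and
    ATC level-2 class level, then record emission under the run's policy.
    """
    if config is None:
        config = RunConfig()
    wconf = WindowingConfig(config.window_days)
    manifest: dict = {"config": _config_dict(config), "claims_in": int(len(claims))}

    ingredient_claims, n_unmapped = vocab.expand_to_ingredients(claims, mapping)
    manifest["claims_unmapped_dropped"] = n_unmapped
    manifest["ingredient_claims"] = int(len(ingredient_claims))

    exposures, n_rejected = windowing.build_exposure_table(ingredient_claims, wconf)
    manifest["claims_rejected_nonpositive_supply"] = n_rejected
    manifest["exposure_events"] = int(len(exposures))

    w_all, w_exposed, n_partial = windowing.window_universe(
        eligibility, exposures, wconf
    )
    manifest["windows_observed"] = w_all
    manifest["windows_exposed"] = w_exposed
    manifest["windows_partial"] = n_partial

    costs = vocab.estimate_cost_per_day(
        ingredient_claims[ingredient_claims["days_supply"] > 0]
    )

    drug_counting = count_combinations(
        exposures, config.support_threshold, config.max_n
    )
    if drug_counting.exact.total_exposed_windows != w_exposed:
        raise RuntimeError(
            "conservation violation: exact counts sum to "
            f"{drug_counting.exact.total_exposed_windows}, "
            f"but {w_exposed} windows are exposed"
        )
    drug_stats = {
        n: stats.compute_combo_stats(
            keys, drug_counting.exact, w_exposed, costs=costs,
            at_least=drug_counting.at_least_by_n[n],
        )
        for n, keys in (
            (n, list(d)) for n, d in drug_counting.at_least_by_n.items()
        )
        if keys
    }
    manifest["exact_drug_combos"] = len(drug_counting.exact.counts)
    manifest["drug_candidates_by_n"] = {
        str(n): c for n, c in drug_counting.candidates_by_n.items()
    }

    cls_exposures, n_unclassified = combos.class_exposures(exposures, mapping)
    manifest["class_exposure_events"] = int(len(cls_exposures))
    manifest["unclassified_exposures_dropped"] = n_unclassified
    w_exposed_cls = windowing.count_exposed_windows(cls_exposures)
    class_counting = count_combinations(
        cls_exposures, config.support_threshold, config.max_n
    )
    class_stats = {
        n: stats.compute_combo_stats(
            list(d), class_counting.exact, w_exposed_cls,
            at_least=class_counting.at_least_by_n[n],
        )
        for n, d in class_counting.at_least_by_n.items()
        if d
    }
    manifest["exact_class_combos"] = len(class_counting.exact.counts)
    manifest["class_candidates_by_n"] = {
        str(n): c for n, c in class_counting.candidates_by_n.items()
    }

    result = PipelineResult(drug_stats, class_stats, costs, manifest)
    if out_dir is not None:
        result.out_dir = write_outputs(result, mapping, config, out_dir)
    return result


def write_outputs(
    result: PipelineResult,
    mapping: vocab.DrugMapping,
    config: RunConfig,
    out_dir: str | Path,
) -> Path:
    """Emit record files, mapping tables, README and run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    drug_paths = records_io.write_drug_records(
        result.drug_stats, config.policy, out_dir
    )
    class_paths = records_io.write_class_records(
        result.class_stats, config.policy, out_dir, mapping=mapping
    )
    vocab.write_mapping_tables(mapping, out_dir, costs=result.costs)
    records_io.write_readme(out_dir, max_n=config.max_n)
    result.manifest["records_emitted"] = {
        "drugs": {str(n): _count_rows(p) for n, p in drug_paths.items()},
        "classes": {str(n): _count_rows(p) for n, p in class_paths.items()},
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir


def _count_rows(path: Path) -> int:
    with open(path, encoding="utf-8") as fh:
        return sum(1 for _ in fh) - 1


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


# ---------------------------------------------------------------------------
# Plain-text table I/O
# ---------------------------------------------------------------------------


def write_claims(claims: pd.DataFrame, path: str | Path) -> None:
    claims.to_csv(path, sep="\t", index=False, columns=CLAIMS_COLUMNS)


def read_claims(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "patient_id": str,
            "drug_code": str,
            "fill_age_days": "int64",
            "days_supply": "int64",
            "payment": float,
        },
    )
    missing = set(CLAIMS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"claims table missing columns: {sorted(missing)}")
    return df


def write_eligibility(eligibility: pd.DataFrame, path: str | Path) -> None:
    eligibility.to_csv(path, sep="\t", index=False, columns=ELIGIBILITY_COLUMNS)


def read_eligibility(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"patient_id": str, "start_age_days": "int64", "end_age_days": "int64"},
    )
    missing = set(ELIGIBILITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"eligibility table missing columns: {sorted(missing)}")
    return df


def write_exposures(exposures: pd.DataFrame, path: str | Path) -> None:
    exposures.to_csv(path, sep="\t", index=False, columns=windowing.EXPOSURE_COLUMNS)


def read_exposures(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"patient_id": str, "window_index": "int64", "ingredient": str},
    )
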