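"""Drug vocabulary: code -> ingredient expansion, ATC level-2 classes,
and per-ingredient daily-cost estimation.

Drug codes on claims (NDC-like identifiers) resolve to one or more active
ingredients; combination products count as exposure to each constituent.
Each ingredient carries vocabulary identifiers (RxNorm CUI, UMLS CUI,
DrugBank ID) and exactly one primary ATC code whose first three characters
(letter-digit-digit) give the level-2 "therapeutic main group" class.
Primary-class selection when an ingredient maps to several ATC codes is an
input contract: the mapping table must arrive pre-resolved.

The approximate cost of an ingredient per day of exposure is the median
payment-per-days-supply over all claims for that ingredient.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: sentinel class for ingredients with a missing or ill-formed ATC code
UNCLASSIFIED = "UNCLASSIFIED"

_ATC2_RE = re.compile(r"^[A-Z]\d\d")

INGREDIENT_FILE_COLUMNS = [
    "drug_name",
    "rxcui",
    "atc_code",
    "atc_name",
    "estimate_drug_cost_per_day",
    "UMLS_CUI",
    "DrugBankID",
]
CLASS_FILE_COLUMNS = ["atc_class", "atc_class_name"]


@dataclass(frozen=True)
class IngredientInfo:
    """Vocabulary identifiers for one drug ingredient."""

    rxcui: str
    umls_cui: str
    drugbank_id: str
    atc_code: str  # primary ATC code; "" if unmapped
    atc_class_name: str


@dataclass
class DrugMapping:
    """Drug code -> ingredient set, plus per-ingredient vocabulary info.

    Invariant: every ingredient referenced by ``code_to_ingredients`` has
    an ``ingredient_info`` entry (checked at construction).
    """

    code_to_ingredients: dict[str, frozenset[str]]
    ingredient_info: dict[str, IngredientInfo]
    class_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.code_to_ingredients = {
            c: frozenset(ings) for c, ings in self.code_to_ingredients.items()
        }
        for code, ings in self.code_to_ingredients.items():
            if not ings:
                raise ValueError(f"drug code {code!r} maps to an empty ingredient set")
            missing = ings - self.ingredient_info.keys()
            if missing:
                raise ValueError(
                    f"drug code {code!r} references ingredients without "
                    f"vocabulary entries: {sorted(missing)}"
                )

    @property
    def unclassified_ingredients(self) -> list[str]:
        """Ingredients carrying no usable ATC code (permitted, but flagged)."""
        return sorted(
            ing
            for ing, info in self.ingredient_info.items()
            if not _ATC2_RE.match(info.atc_code or "")
        )


def primary_class(ingredient: str, mapping: DrugMapping) -> str:
    """Level-2 class (first three characters) of the ingredient's primary
    ATC code, e.g. ``"A10BA02" -> "A10"``.

    Ingredients whose ATC field is missing or ill-formed return the
    :data:`UNCLASSIFIED` sentinel. One ingredient can map to multiple ATC
    codes in the source vocabularies; only the pre-resolved primary class
    is counted here.
    """
    try:
        info = mapping.ingredient_info[ingredient]
    except KeyError:
        raise KeyError(f"unknown ingredient {ingredient!r}") from None
    code = info.atc_code or ""
    if not _ATC2_RE.match(code):
        return UNCLASSIFIED
    return code[:3]


def expand_to_ingredients(
    claims: pd.DataFrame, mapping: DrugMapping
) -> tuple[pd.DataFrame, int]:
    """Replicate each claim once per constituent ingredient.

    A combination product (e.g. an acetaminophen+hydrocodone analog)
    counts as exposure to each ingredient; patient, fill age, days supply
    and payment are carried unchanged on every replicate. The full claim
    payment is attached to each constituent — a deliberate, documented
    upward bias for combination-product ingredients.

    Returns
    -------
    (ingredient_claims, n_dropped)
        ``ingredient_claims`` adds an ``ingredient`` column; claims whose
        drug code is absent from the mapping are dropped and tallied in
        ``n_dropped``.
    """
    known = claims["drug_code"].isin(mapping.code_to_ingredients.keys())
    n_dropped = int((~known).sum())
    kept = claims.loc[known].copy()
    if kept.empty:
        out = kept.assign(ingredient=pd.Series(dtype=object))
        return out.reset_index(drop=True), n_dropped
    ing_lists = kept["drug_code"].map(
        {c: sorted(s) for c, s in mapping.code_to_ingredients.items()}
    )
    out = kept.loc[kept.index.repeat(ing_lists.str.len())].copy()
    out["ingredient"] = [i for lst in ing_lists for i in lst]
    return out.reset_index(drop=True), n_dropped


def estimate_cost_per_day(ingredient_claims: pd.DataFrame) -> dict[str, float]:
    """Per-ingredient cost table: median of payment / days_supply.

    The median of an even number of claims is the midpoint of the two
    central values. Ingredients with no claims are simply absent.
    """
    if (ingredient_claims["days_supply"] <= 0).any():
        raise ValueError("days_supply must be positive for cost estimation")
    if ingredient_claims.empty:
        return {}
    per_day = ingredient_claims["payment"] / ingredient_claims["days_supply"]
    return per_day.groupby(ingredient_claims["ingredient"]).median().to_dict()


# ---------------------------------------------------------------------------
# Publication-layout mapping files (drug_mappings_ingredients.tsv /
# drug_mappings_atc_classes.tsv)
# ---------------------------------------------------------------------------


def write_mapping_tables(
    mapping: DrugMapping,
    out_dir: str | Path,
    costs: dict[str, float] | None = None,
) -> tuple[Path, Path]:
    """Write the two-file mapping record: one ingredient per row sorted by
    name, and one ATC level-2 class per row sorted by class code."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    costs = costs or {}
    rows = []
    for ing in sorted(mapping.ingredient_info):
        info = mapping.ingredient_info[ing]
        cost = costs.get(ing)
        rows.append(
            {
                "drug_name": ing,
                "rxcui": info.rxcui,
                "atc_code": info.atc_code,
                "atc_name": info.atc_class_name,
                "estimate_drug_cost_per_day": "" if cost is None else f"{cost:.4f}",
                "UMLS_CUI": info.umls_cui,
                "DrugBankID": info.drugbank_id,
            }
        )
    ing_path = out_dir / "drug_mappings_ingredients.tsv"
    pd.DataFrame(rows, columns=INGREDIENT_FILE_COLUMNS).to_csv(
        ing_path, sep="\t", index=False
    )

    classes = dict(mapping.class_names)
    for ing, info in mapping.ingredient_info.items():
        cls = primary_class(ing, mapping)
        if cls != UNCLASSIFIED:
            classes.setdefault(cls, info.atc_class_name)
    cls_path = out_dir / "drug_mappings_atc_classes.tsv"
    pd.DataFrame(
        sorted(classes.items()), columns=CLASS_FILE_COLUMNS
    ).to_csv(cls_path, sep="\t", index=False)
    return ing_path, cls_path


def read_mapping_tables(
    ingredients_path: str | Path, classes_path: str | Path | None = None
) -> DrugMapping:
    """Read mapping files in the publication layout back into a
    :class:`DrugMapping`. Every ingredient becomes a single-ingredient
    drug code named after itself; combination-product codes, which are
    claims-table artifacts, are not represented in this layout."""
    df = pd.read_csv(ingredients_path, sep="\t", dtype=str).fillna("")
    unknown = set(df.columns) - set(INGREDIENT_FILE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown mapping columns: {sorted(unknown)}")
    info = {
        r.drug_name: IngredientInfo(
            rxcui=r.rxcui,
            umls_cui=r.UMLS_CUI,
            drugbank_id=r.DrugBankID,
            atc_code=r.atc_code,
            atc_class_name=r.atc_name,
        )
        for r in df.itertuples()
    }
    class_names: dict[str, str] = {}
    if classes_path is not None:
        cdf = pd.read_csv(classes_path, sep="\t", dtype=str).fillna("")
        class_names = dict(zip(cdf["atc_class"], cdf["atc_class_name"]))
    return DrugMapping(
        code_to_ingredients={ing: frozenset({ing}) for ing in info},
        ingredient_info=info,
        class_names=class_names,
    )


# ---------------------------------------------------------------------------
# Bundled demo vocabulary (synthetic)
# ---------------------------------------------------------------------------

# Synthetic fixture vocabulary: real ingredient names and real ATC level-2
# classes, but fabricated vocabulary identifiers (RX9…/C59…/DB9…) so no
# incorrect real-world identifier is shipped.
_DEMO_INGREDIENTS: list[tuple[str, str]] = [
    ("acetaminophen", "N02BE01"),
    ("alprazolam", "N05BA12"),
    ("amlodipine", "C08CA01"),
    ("amoxicillin", "J01CA04"),
    ("atorvastatin", "C10AA05"),
    ("azithromycin", "J01FA10"),
    ("ciprofloxacin", "J01MA02"),
    ("glyburide", "A10BB01"),
    ("hydrochlorothiazide", "C03AA03"),
    ("hydrocodone", "R05DA03"),
    ("ibuprofen", "M01AE01"),
    ("lisinopril", "C09AA03"),
    ("losartan", "C09CA01"),
    ("metformin", "A10BA02"),
    ("metoprolol", "C07AB02"),
    ("omeprazole", "A02BC01"),
    ("oxycodone", "N02AA05"),
    ("sertraline", "N06AB06"),
    ("simvastatin", "C10AA01"),
    ("sitagliptin", "A10BH01"),
]

_DEMO_CLASS_NAMES: dict[str, str] = {
    "A02": "Drugs for acid related disorders",
    "A10": "Drugs used in diabetes",
    "C03": "Diuretics",
    "C07": "Beta blocking agents",
    "C08": "Calcium channel blockers",
    "C09": "Agents acting on the renin-angiotensin system",
    "C10": "Lipid modifying agents",
    "J01": "Antibacterials for systemic use",
    "M01": "Antiinflammatory and antirheumatic products",
    "N02": "Analgesics",
    "N05": "Psycholeptics",
    "N06": "Psychoanaleptics",
    "R05": "Cough and cold preparations",
}

DEMO_COMBINATION_PRODUCTS: dict[str, frozenset[str]] = {
    "hydrocodone-acetaminophen": frozenset({"hydrocodone", "acetaminophen"}),
    "oxycodone-acetaminophen": frozenset({"oxycodone", "acetaminophen"}),
}


def demo_mapping() -> DrugMapping:
    """Small synthetic vocabulary for tests and examples: 20 ingredients,
    13 ATC level-2 classes, two combination products. Identifiers are
    fabricated placeholders, not real RxNorm/UMLS/DrugBank entries."""
    info = {}
    for i, (name, atc) in enumerate(_DEMO_INGREDIENTS, start=1):
        info[name] = IngredientInfo(
            rxcui=f"RX9{i:05d}",
            umls_cui=f"C59{i:05d}",
            drugbank_id=f"DB9{i:04d}",
            atc_code=atc,
            atc_class_name=_DEMO_CLASS_NAMES[atc[:3]],
        )
    codes: dict[str, frozenset[str]] = {
        name: frozenset({name}) for name, _ in _DEMO_INGREDIENTS
    }
    codes.update(DEMO_COMBINATION_PRODUCTS)
    return DrugMapping(
        code_to_ingredients=codes,
        ingredient_info=info,
        class_names=dict(_DEMO_CLASS_NAMES),
    )
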