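"""A minimal worked example of the counting model.

Three drugs A, B and C are taken concomitantly in one window; A and B
belong to drug class Q, C to class R. The window then contributes:

* one **exact** ingredient count, to A+B+C;
* one **at-least** ingredient count to each of A, B, C, A+B, A+C, B+C
  and A+B+C (every non-empty subset);
* one exact class count to Q+R (classes count once per window, however
  many member drugs are present); and
* one at-least class count to each of Q, R and Q+R.

The helpers here build that toy cohort with real package objects so the
enumeration can be reproduced end to end.
"""

from __future__ import annotations

import pandas as pd

from .combos import ExactComboTable, atleast_count, class_exposures, exact_combo_counts
from .vocab import DrugMapping, IngredientInfo
from .windowing import build_exposure_table

#: class codes for the toy: A and B share Q01, C is alone in R02
TOY_CLASS_OF = {"A": "Q01", "B": "Q01", "C": "R02"}


def toy_mapping() -> DrugMapping:
    info = {
        drug: IngredientInfo(
            rxcui=f"RX-{drug}",
            umls_cui=f"C-{drug}",
            drugbank_id=f"DB-{drug}",
            atc_code=f"{cls}AA0{i}",
            atc_class_name=f"class {cls}",
        )
        for i, (drug, cls) in enumerate(sorted(TOY_CLASS_OF.items()), start=1)
    }
    return DrugMapping(
        code_to_ingredients={d: frozenset({d}) for d in info},
        ingredient_info=info,
        class_names={"Q01": "class Q01", "R02": "class R02"},
    )


def toy_claims() -> pd.DataFrame:
    """One patient filling A, B and C together for 30 days."""
    return pd.DataFrame(
        {
            "patient_id": ["p1"] * 3,
            "ingredient": ["A", "B", "C"],
            "fill_age_days": [0, 0, 0],
            "days_supply": [30, 30, 30],
        }
    )


def worked_example() -> dict:
    """Run the toy through the real pipeline stages and return the
    exact/at-least enumerations at ingredient and class level."""
    mapping = toy_mapping()
    exposures, _ = build_exposure_table(toy_claims())
    exact = exact_combo_counts(exposures)
    cls_expo, _ = class_exposures(exposures, mapping)
    exact_cls = exact_combo_counts(cls_expo)
    ing_keys = [
        ("A",), ("B",), ("C",), ("A", "B"), ("A", "C"), ("B", "C"), ("A", "B", "C"),
    ]
    cls_keys = [("Q01",), ("R02",), ("Q01", "R02")]
    return {
        "exact_ingredient_counts": dict(exact.counts),
        "atleast_ingredient_counts": {
            k: atleast_count(k, exact) for k in ing_keys
        },
        "exact_class_counts": dict(exact_cls.counts),
        "atleast_class_counts": {
            k: atleast_count(k, exact_cls) for k in cls_keys
        },
    }
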