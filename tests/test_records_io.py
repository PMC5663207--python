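"""Publication-format record emission, masking, and round-trips."""

import numpy as np
import pandas as pd
import pytest

from polyrx import records_io
from polyrx.records_io import (
    RecordEmissionPolicy,
    class_record_columns,
    drug_record_columns,
    read_records,
    write_class_records,
    write_drug_records,
)


def stats_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "combo",
            "atleast_exposure_count",
            "exact_exposure_count",
            "estimate_drug_combo_cost_per_day",
            "fraction_exact",
            "fraction_all_windows",
            "observe_per_expect_1s",
            "observe_per_expect_N1",
        ],
    )


GOLDEN_HEADERS = {
    1: "drug_name_A\tatleast_exposure_count\texact_exposure_count\t"
       "estimate_drug_cost_per_day\tfraction_exact\tfraction_all_windows",
    2: "drug_name_A\tdrug_name_B\tatleast_exposure_count\texact_exposure_count\t"
       "estimate_drug_cost_per_day\tfraction_exact\tfraction_all_windows\t"
       "observe_per_expect_1s",
    3: "drug_name_A\tdrug_name_B\tdrug_name_C\tatleast_exposure_count\t"
       "exact_exposure_count\testimate_drug_cost_per_day\tfraction_exact\t"
       "fraction_all_windows\tobserve_per_expect_1s\tobserve_per_expect_N1",
}


@pytest.mark.parametrize("n", [1, 2, 3])
def test_drug_headers_golden(tmp_path, n):
    paths = write_drug_records(
        {n: stats_table([])}, RecordEmissionPolicy(), tmp_path
    )
    assert paths[n].read_text().splitlines()[0] == GOLDEN_HEADERS[n]


def test_header_column_applicability():
    assert drug_record_columns(1) == [
        "drug_name_A",
        "atleast_exposure_count",
        "exact_exposure_count",
        "estimate_drug_cost_per_day",
        "fraction_exact",
        "fraction_all_windows",
    ]
    assert "observe_per_expect_1s" in drug_record_columns(2)
    assert "observe_per_expect_N1" not in drug_record_columns(2)
    assert "observe_per_expect_N1" in drug_record_columns(3)
    assert "estimate_drug_cost_per_day" not in class_record_columns(3)
    assert class_record_columns(2)[:4] == [
        "atc_code_A", "atc_name_A", "atc_code_B", "atc_name_B",
    ]


def test_privacy_mask_below_threshold(tmp_path):
    table = stats_table(
        [
            {
                "combo": ("a", "b"),
                "atleast_exposure_count": 150,
                "exact_exposure_count": 99,
                "estimate_drug_combo_cost_per_day": 1.5,
                "fraction_exact": 0.66,
                "fraction_all_windows": 0.01,
                "observe_per_expect_1s": 2.0,
                "observe_per_expect_N1": np.nan,
            }
        ]
    )
    paths = write_drug_records({2: table}, RecordEmissionPolicy(), tmp_path)
    row = paths[2].read_text().splitlines()[1].split("\t")
    assert row[2] == "150"       # at-least at/above threshold: plain
    assert row[3] == "<100"      # exact below threshold: masked


def test_inclusion_threshold_for_large_n(tmp_path):
    rows = [
        {
            "combo": ("a", "b", "c"),
            "atleast_exposure_count": 9_999,
            "exact_exposure_count": 5_000,
            "estimate_drug_combo_cost_per_day": np.nan,
            "fraction_exact": 0.5,
            "fraction_all_windows": 0.1,
            "observe_per_expect_1s": 1.0,
            "observe_per_expect_N1": 1.0,
        },
        {
            "combo": ("a", "b", "d"),
            "atleast_exposure_count": 10_000,
            "exact_exposure_count": 5_000,
            "estimate_drug_combo_cost_per_day": np.nan,
            "fraction_exact": 0.5,
            "fraction_all_windows": 0.1,
            "observe_per_expect_1s": 1.0,
            "observe_per_expect_N1": 1.0,
        },
    ]
    paths = write_drug_records({3: stats_table(rows)}, RecordEmissionPolicy(), tmp_path)
    lines = paths[3].read_text().splitlines()
    assert len(lines) == 2  # header + the 10,000-count row only
    assert lines[1].startswith("a\tb\td")
    # pairs are always included regardless of count
    paths = write_drug_records(
        {2: stats_table(
            [{**rows[0], "combo": ("a", "b"), "observe_per_expect_N1": np.nan}]
        )},
        RecordEmissionPolicy(),
        tmp_path,
    )
    assert len(paths[2].read_text().splitlines()) == 2


def test_rows_sorted_by_descending_atleast(tmp_path):
    rows = [
        {"combo": ("z",), "atleast_exposure_count": 500, "exact_exposure_count": 200,
         "estimate_drug_combo_cost_per_day": np.nan, "fraction_exact": 0.4,
         "fraction_all_windows": 0.1, "observe_per_expect_1s": np.nan,
         "observe_per_expect_N1": np.nan},
        {"combo": ("a",), "atleast_exposure_count": 500, "exact_exposure_count": 100,
         "estimate_drug_combo_cost_per_day": np.nan, "fraction_exact": 0.2,
         "fraction_all_windows": 0.1, "observe_per_expect_1s": np.nan,
         "observe_per_expect_N1": np.nan},
        {"combo": ("m",), "atleast_exposure_count": 900, "exact_exposure_count": 300,
         "estimate_drug_combo_cost_per_day": np.nan, "fraction_exact": 0.33,
         "fraction_all_windows": 0.2, "observe_per_expect_1s": np.nan,
         "observe_per_expect_N1": np.nan},
    ]
    paths = write_drug_records({1: stats_table(rows)}, RecordEmissionPolicy(), tmp_path)
    names = [ln.split("\t")[0] for ln in paths[1].read_text().splitlines()[1:]]
    assert names == ["m", "a", "z"]  # descending count, ties by name


def test_round_trip_with_censoring(tmp_path):
    rows = [
        {"combo": ("a", "b"), "atleast_exposure_count": 150,
         "exact_exposure_count": 99, "estimate_drug_combo_cost_per_day": 1.25,
         "fraction_exact": 0.66, "fraction_all_windows": 0.015,
         "observe_per_expect_1s": 2.25, "observe_per_expect_N1": np.nan},
        {"combo": ("a", "c"), "atleast_exposure_count": 80,
         "exact_exposure_count": 40, "estimate_drug_combo_cost_per_day": np.nan,
         "fraction_exact": 0.5, "fraction_all_windows": 0.008,
         "observe_per_expect_1s": 0.75, "observe_per_expect_N1": np.nan},
    ]
    policy = RecordEmissionPolicy()
    paths = write_drug_records({2: stats_table(rows)}, policy, tmp_path)
    df = read_records(paths[2])
    # censored cells come back as flag + bound, never a number
    assert df.loc[0, "exact_exposure_count_censored"] == np.True_
    assert pd.isna(df.loc[0, "exact_exposure_count"])
    assert df.loc[0, "exact_exposure_count_censored_bound"] == 100
    assert df.loc[0, "atleast_exposure_count"] == 150
    assert df.loc[1, "atleast_exposure_count_censored"] == np.True_
    assert df.loc[1, "observe_per_expect_1s"] == pytest.approx(0.75)
    # a censored cell survives write -> read -> write byte-identically
    first = paths[2].read_bytes()
    rewritten = stats_table(
        [
            {"combo": tuple(r[["drug_name_A", "drug_name_B"]]),
             "atleast_exposure_count": (
                 99 if r["atleast_exposure_count_censored"] else r["atleast_exposure_count"]
             ),
             "exact_exposure_count": (
                 99 if r["exact_exposure_count_censored"] else r["exact_exposure_count"]
             ),
             "estimate_drug_combo_cost_per_day": r["estimate_drug_cost_per_day"],
             "fraction_exact": r["fraction_exact"],
             "fraction_all_windows": r["fraction_all_windows"],
             "observe_per_expect_1s": r["observe_per_expect_1s"],
             "observe_per_expect_N1": np.nan}
            for _, r in df.iterrows()
        ]
    )
    paths2 = write_drug_records({2: rewritten}, policy, tmp_path / "again")
    # same masked cells, same tokens (uncensored numbers identical too)
    assert paths2[2].read_bytes() == first


def test_class_records_masking_and_schema(tmp_path, demo_map):
    rows = [
        {"combo": ("A10", "C09"), "atleast_exposure_count": 50,
         "exact_exposure_count": 20, "estimate_drug_combo_cost_per_day": np.nan,
         "fraction_exact": 0.4, "fraction_all_windows": 0.005,
         "observe_per_expect_1s": 3.0, "observe_per_expect_N1": np.nan},
    ]
    paths = write_class_records(
        {2: stats_table(rows)}, RecordEmissionPolicy(), tmp_path, mapping=demo_map
    )
    lines = paths[2].read_text().splitlines()
    fields = lines[1].split("\t")
    assert fields[:4] == [
        "A10", "Drugs used in diabetes", "C09",
        "Agents acting on the renin-angiotensin system",
    ]
    assert fields[4] == "<100" and fields[5] == "<100"


def test_empty_stats_gives_headered_empty_file(tmp_path):
    paths = write_class_records({1: stats_table([])}, RecordEmissionPolicy(), tmp_path)
    lines = paths[1].read_text().splitlines()
    assert len(lines) == 1
    assert lines[0].split("\t") == class_record_columns(1)


def test_read_rejects_malformed_rows(tmp_path):
    path = tmp_path / "db_drugs_1s.tsv"
    path.write_text(
        "\t".join(drug_record_columns(1)) + "\nmetformin\t10\t5\t0.3\t0.5\n"
    )
    with pytest.raises(ValueError, match=":2"):
        read_records(path)


def test_read_rejects_unknown_columns(tmp_path):
    path = tmp_path / "db_drugs_1s.tsv"
    path.write_text("drug_name_A\tbogus_column\nmetformin\t1\n")
    with pytest.raises(ValueError, match="bogus_column"):
        read_records(path)
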