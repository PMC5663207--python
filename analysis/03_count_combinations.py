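#!/usr/bin/env python
"""Count exact and at-least multi-drug combination exposures.

Summarizes the exposure table into exact combination counts (each
exposed window contributes to exactly one key), then answers at-least
queries through the per-drug inverted index, generating candidate
combinations of 2..5 drugs Apriori-style from the level below. The
support threshold is scaled to the desk-size cohort (the publication
pipeline's threshold of 1,000 windows presumes hundreds of millions of
windows). Writes the exact table and per-size at-least counts.
"""

from pathlib import Path

from polyrx import combos, pipeline
from polyrx.pipeline import count_combinations

EXPOSURES = Path("results/exposures/exposures.tsv")
OUT = Path("results/counts")
SUPPORT_THRESHOLD = 20


def main() -> None:
    exposures = pipeline.read_exposures(EXPOSURES)
    result = count_combinations(exposures, SUPPORT_THRESHOLD, max_n=5)
    exact = result.exact

    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "exact_combos.tsv", "w", encoding="utf-8") as fh:
        fh.write("items\texact_exposure_count\n")
        for key, c in sorted(exact.counts.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write("|".join(key) + f"\t{c}\n")
    with open(OUT / "atleast_combos.tsv", "w", encoding="utf-8") as fh:
        fh.write("n\titems\tatleast_exposure_count\n")
        for n, counts in sorted(result.at_least_by_n.items()):
            for key, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{n}\t" + "|".join(key) + f"\t{c}\n")

    assert sum(exact.counts.values()) == exact.total_exposed_windows
    print(f"exposed windows:         {exact.total_exposed_windows}")
    print(f"unique exact combos:     {len(exact.counts)}")
    print(f"candidates per size:     {result.candidates_by_n}")
    top = sorted(exact.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
    print("top exact combos:")
    for key, c in top:
        print(f"  {'+'.join(key):60s} {c}")
    print(f"wrote {OUT}/exact_combos.tsv, atleast_combos.tsv")


if __name__ == "__main__":
    main()
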