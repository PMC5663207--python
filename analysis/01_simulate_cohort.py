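#!/usr/bin/env python
"""Simulate the study cohort.

Generates the default synthetic claims cohort (2,000 patients; five
chronic-condition clusters over independent acute prescriptions) and
writes the claims, eligibility and ground-truth condition tables under
results/cohort/. Prints the realized enrollment and prescription-duration
mix so the generated data can be compared with the configured targets
(median enrollment ~29-30 months; ~50% 30-day supplies, ~20% of supplies
10 days or shorter).
"""

from pathlib import Path

from polyrx import pipeline, synthetic

OUT = Path("results/cohort")
SEED = 20260929


def main() -> None:
    config = synthetic.default_config(n_patients=2000, seed=SEED)
    cohort = synthetic.simulate_cohort(config)
    OUT.mkdir(parents=True, exist_ok=True)
    pipeline.write_claims(cohort.claims, OUT / "claims.tsv")
    pipeline.write_eligibility(cohort.eligibility, OUT / "eligibility.tsv")
    cohort.condition_assignments.to_csv(
        OUT / "ground_truth_conditions.tsv", sep="\t", index=False
    )

    months = (
        cohort.eligibility["end_age_days"] - cohort.eligibility["start_age_days"] + 1
    ) / 30
    supply = cohort.claims["days_supply"]
    print(f"patients:                {config.n_patients}")
    print(f"claims:                  {len(cohort.claims)}")
    print(f"median enrollment (mo):  {months.median():.1f}")
    print(f"fraction 30-day supply:  {(supply == 30).mean():.3f}")
    print(f"fraction <=10-day:       {(supply <= 10).mean():.3f}")
    print(f"condition assignments:   {len(cohort.condition_assignments)}")
    print(f"wrote {OUT}/claims.tsv, eligibility.tsv, ground_truth_conditions.tsv")


if __name__ == "__main__":
    main()
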