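#!/usr/bin/env python
"""Simulate the two-group longitudinal cohort with rendered image stacks.

Writes the synthetic study inputs under results/cohort/: one multi-page TIFF
per subject-visit, the cohort table (group, ethnicity, visit, months), and
the ground-truth outcome table that downstream stages try to recover.
"""

from pathlib import Path

from trabmri import CohortSpec, generate_cohort, write_stack

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "cohort"
STACKS = ROOT / "scratch" / "cohort_stacks"
SEED = 20130327

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    STACKS.mkdir(parents=True, exist_ok=True)
    # a reduced cohort (6 vs 6) keeps the rendered-image stages quick; the
    # statistical analyses at full study size run on the numeric tables
    cohort = generate_cohort(CohortSpec(n_diabetes=6, n_control=6, seed=SEED),
                             render=True, n_slices=12)
    for (sid, visit), (stack, _) in cohort["stacks"].items():
        write_stack(stack, STACKS / f"{sid}_{visit}.tif")
    cohort["table"].to_csv(OUT / "cohort.csv", index=False)
    cohort["truth"].to_csv(OUT / "truth.csv", index=False)
    n = len(cohort["stacks"])
    print(f"wrote {n} stacks to {STACKS} and cohort/truth tables to {OUT}")
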