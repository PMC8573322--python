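"""Compute the search-measure (SM) index from the fixation log.

Filters sub-50 ms fixations, counts alternative-/dimension-wise AOI
transitions per trial, and reports the Böckenholt-Hynan SM index at trial
and participant level.  Positive SM = predominantly alternative-wise
search; negative = dimension-wise.  Reads the tables written by script 02.
"""

from pathlib import Path

import searchshift as ss
from searchshift.tables import read_fixation_table, write_sm_table

OUT = Path("results/study")


def main() -> None:
    fixations = read_fixation_table(OUT / "fixations.csv")
    sm_trial = ss.sm_per_trial(fixations)
    write_sm_table(sm_trial, OUT / "sm_trial.csv")
    means = ss.sm_participant_means(sm_trial)
    means.to_csv(OUT / "sm_participant.csv", index=False)

    for task in ("ALT", "DIM"):
        block = sm_trial[sm_trial["task"] == task]["sm"]
        print(f"  {task}: mean SM {block.mean():+.2f} (sd {block.std():.2f}, "
              f"{block.notna().sum()} trials)")
    n_missing = sm_trial["sm"].isna().sum()
    print(f"  trials without a defined SM (no transition): {n_missing}")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
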