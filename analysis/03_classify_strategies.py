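"""Classify every participant-task block as EV, maximax, or guessing.

Fits both strategies per block by penalized maximum likelihood, compares
the deviances against the random-choice baseline, and tests whether the
proportion of EV-classified participants differs between tasks (pooled
one-tailed two-proportion z).  Reads the tables written by script 02.
"""

from pathlib import Path

import searchshift as ss
from searchshift.pipeline import classification_summary
from searchshift.tables import read_gamble_table, read_trial_table, write_classification_table

OUT = Path("results/study")


def main() -> None:
    trials = read_trial_table(OUT / "trials.csv")
    pairs = read_gamble_table(OUT / "gambles.csv")
    report = ss.classify_trials(trials, pairs)
    write_classification_table(report, OUT / "classification.csv")

    summary = classification_summary(report)
    for task in ("alt", "dim"):
        n = summary[f"n_{task}"]
        k = summary[f"ev_labelled_{task}"]
        print(f"  {task.upper()}: {k}/{n} participants classified EV "
              f"({100 * summary[f'prop_ev_{task}']:.0f}%)")
    print(f"  EV-share difference: z = {summary['z']:.2f}, "
          f"one-tailed p = {summary['p_one_tailed']:.4f}")
    print(f"report written to {OUT / 'classification.csv'}")


if __name__ == "__main__":
    main()
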