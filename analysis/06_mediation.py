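"""Bootstrap mediation: does search direction carry the task effect on choice?

Path models on the probability scale with task dummy-coded (ALT = 1), the
per-trial SM index as mediator, and EV-consistent choice as outcome; the
95% CI for the indirect effect a*b comes from 5,000 participant-level
bootstrap resamples.  Reads the tables written by scripts 02 and 04.
"""

import json
from pathlib import Path

import searchshift as ss
from searchshift.tables import read_gamble_table, read_sm_table, read_trial_table

OUT = Path("results/study")
SEED = 1


def main() -> None:
    trials = read_trial_table(OUT / "trials.csv")
    sm_trial = read_sm_table(OUT / "sm_trial.csv")
    merged = trials.merge(
        sm_trial[["participant_id", "task", "pair_id", "sm"]],
        on=["participant_id", "task", "pair_id"],
        how="left",
    )
    med = ss.mediation_analysis(merged, n_boot=5000, seed=SEED)
    print("task -> SM -> EV-consistent choice (linear-probability paths):")
    print(f"  a  (task -> SM)            = {med.a:+.3f}")
    print(f"  b  (SM -> choice | task)   = {med.b_path:+.4f}")
    print(f"  c  (total effect)          = {med.c_total:+.3f}")
    print(f"  c' (direct effect)         = {med.c_prime:+.3f}")
    print(f"  ab (indirect effect)       = {med.ab:+.3f}, "
          f"CI95 [{med.ci95_ab[0]:.3f}, {med.ci95_ab[1]:.3f}] "
          f"({med.n_boot} bootstrap resamples of {med.n_participants} participants)")
    with open(OUT / "mediation.json", "w", encoding="utf-8") as fh:
        json.dump(med.as_dict(), fh, indent=2)
    print(f"estimates written to {OUT / 'mediation.json'}")


if __name__ == "__main__":
    main()
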