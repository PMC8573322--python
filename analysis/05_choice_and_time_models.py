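"""Mixed-effect regressions of choice and decision time on task.

Choice: logistic regression of EV-consistent choice on task (ALT = 1) with
crossed random intercepts for participant and item.  Decision time: linear
mixed model of log response time on task, |EV difference| and |outcome
difference|.  Reads the tables written by script 02.
"""

import json
from pathlib import Path

import searchshift as ss
from searchshift.tables import read_gamble_table, read_trial_table

OUT = Path("results/study")


def main() -> None:
    trials = read_trial_table(OUT / "trials.csv")
    pairs = read_gamble_table(OUT / "gambles.csv")

    cm = ss.fit_choice_model(trials)
    print("EV-consistent choice ~ task (mixed logistic):")
    print(f"  b = {cm.b:.2f}, OR = {cm.odds_ratio:.2f}, "
          f"CI95 [{cm.ci95[0]:.2f}, {cm.ci95[1]:.2f}], z = {cm.statistic:.2f}, "
          f"p = {cm.p_value:.2g}")

    rt = ss.fit_rt_model(trials, pairs)
    print("log decision time ~ task + |dEV| + |d outcome| (linear mixed model):")
    for term in ("task", "ev_diff", "outcome_diff"):
        r = rt[term]
        print(f"  {term}: b = {r.b:.4f}, CI95 [{r.ci95[0]:.4f}, {r.ci95[1]:.4f}], "
              f"t = {r.statistic:.2f}, p = {r.p_value:.2g}")

    payload = {"choice_model": cm.as_dict(),
               "rt_model": {k: v.as_dict() for k, v in rt.items()}}
    with open(OUT / "regressions.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
    print(f"estimates written to {OUT / 'regressions.json'}")


if __name__ == "__main__":
    main()
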