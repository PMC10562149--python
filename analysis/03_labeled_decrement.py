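"""Effect of shrinking the labeled set with 40 unlabeled rows held fixed.

Reduces the labeled development set stepwise (710, 670, ... by 40) with the
40 unlabeled observations kept, refits all six variants at each step, and
summarizes how discrimination and calibration react.  Writes
results/decrement_results.csv.

Desk-scale defaults: 3 replicates and a floor of 150 labeled rows; pass
`replicates floor` on the command line to change.
"""

import sys
from pathlib import Path

from ntcp_semisup.experiments import run_labeled_decrement, small_config

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    replicates = int(sys.argv[1]) if len(sys.argv) > 1 else 3
    floor = int(sys.argv[2]) if len(sys.argv) > 2 else 150
    cfg = small_config(replicates=replicates, master_seed=2027)
    cfg.decrement_floor = floor
    table = run_labeled_decrement(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "decrement_results.csv", index=False)

    ok = table[table.status == "ok"]
    failed = table[table.status == "failed"]
    print(f"{len(ok)}/{len(table)} cells ok; {len(failed)} failed "
          f"(separation at small n shows up as failed logistic cells)")
    summary = ok.groupby(["outcome", "n_labeled", "model"])[["auc", "slope"]].mean().round(3)
    print(summary.to_string())


if __name__ == "__main__":
    main()
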