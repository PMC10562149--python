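"""Effect of the labeled/unlabeled ratio with the total held at 750.

Decreases the labeled count in steps of 40 while every removed row becomes
unlabeled, so self-training has progressively more rows to pseudolabel.
Counts incorrect pseudolabels against the generator truth and shows where
the calibration of self-training starts to degrade relative to the
supervised models.  Writes results/ratio_sweep_results.csv.

Desk-scale defaults: 3 replicates, floor 230; pass `replicates floor` to
change.
"""

import sys
from pathlib import Path

from ntcp_semisup.experiments import run_ratio_sweep, small_config

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    replicates = int(sys.argv[1]) if len(sys.argv) > 1 else 3
    floor = int(sys.argv[2]) if len(sys.argv) > 2 else 230
    cfg = small_config(replicates=replicates, master_seed=2029)
    cfg.decrement_floor = floor
    cfg.decrement_step = 120  # coarser grid at desk scale
    table = run_ratio_sweep(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "ratio_sweep_results.csv", index=False)

    ok = table[table.status == "ok"]
    st = ok[ok.model == "selftrain_logistic"]
    print("self-training (logistic) by labeled count, mean over replicates:")
    print(st.groupby(["outcome", "n_labeled"])[["st_pseudolabels", "st_errors", "auc", "slope"]]
          .mean().round(3).to_string())
    lg = ok[ok.model == "logistic"]
    print("\nsupervised logistic for comparison:")
    print(lg.groupby(["outcome", "n_labeled"])[["auc", "slope"]].mean().round(3).to_string())


if __name__ == "__main__":
    main()
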