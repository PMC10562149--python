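"""Generate the synthetic development and validation cohorts.

Writes the complete, amputed and label-masked development cohort (n=750,
40 unlabeled) and the three-center validation cohort (n=395) to
results/cohorts/, and prints the realized toxicity/missingness rates next to
their calibration targets.
"""

from pathlib import Path

from ntcp_semisup.cohort import ampute, generate_cohort, mask_labels, write_cohort_csv
from ntcp_semisup.config import OUTCOMES, development_config, validation_config
from ntcp_semisup.impute import chained_impute

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    dev_cfg = development_config()
    dev = generate_cohort(dev_cfg, seed=SEED)
    write_cohort_csv(dev, OUT / "development_complete.csv")
    print("development cohort (n=%d): 6-month rates vs targets" % len(dev))
    for o in OUTCOMES:
        print(f"  {o:8s} {dev[f'out_{o}'].mean():.3f}  (target {dev_cfg.target_prevalences[o]:.2f})")

    amputed = ampute(dev, dev_cfg.missing_rates, seed=SEED + 1)
    print("realized missingness:")
    for group, col in [("outcome_xerostomia", "out_xer_g2"), ("outcome_dysphagia", "out_dys_g2"),
                       ("baseline_xerostomia", "base_xer_g2"), ("baseline_dysphagia", "base_dys_g2")]:
        print(f"  {group:20s} {amputed[col].isna().mean():.3f}  (target {dev_cfg.missing_rates[group]:.2f})")

    imputed = chained_impute(amputed, m=1, sweeps=10, seed=SEED + 2).cohorts[0]
    masked = mask_labels(imputed, 40, seed=SEED + 3)
    write_cohort_csv(masked, OUT / "development_masked.csv")
    print(f"development cohort written with {int(masked['unlabeled'].sum())} unlabeled rows")

    val_cfg = validation_config()
    val = generate_cohort(val_cfg, seed=SEED + 4)
    val = ampute(val, val_cfg.missing_rates, seed=SEED + 5)
    write_cohort_csv(val, OUT / "validation_amputed.csv")
    print("validation cohort (n=%d) centers:" % len(val))
    print(val["center"].value_counts().to_string())


if __name__ == "__main__":
    main()
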