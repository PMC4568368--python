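#!/usr/bin/env python
"""Pool each simulated animal's field counts into its stereological
estimates: fibroblast numerical density (optical dissector), volume densities
of collagen, vessels and hair follicles (point counting), vessel length
density (2·Q_A on IUR sections) and mean vessel profile diameter.

Reads results/field_counts.csv (from 01_simulate_cohort.py); writes
results/estimates.csv.
"""

import pandas as pd

from stereoheal.pipeline import RunConfig, run_pipeline

SEED = 20150831


def main() -> None:
    cfg = RunConfig(mode="estimate", out_dir="results", seed=SEED,
                    counts_path="results/field_counts.csv")
    run_pipeline(cfg)
    est = pd.read_csv("results/estimates.csv")
    print(f"estimates for {len(est)} animals")
    print("group means (animal as statistical unit):")
    cols = ["nv_fibroblast", "vv_collagen", "lv_vessel", "vessel_diameter_mean"]
    print(est.groupby("group")[cols].mean().round(1).to_string())


if __name__ == "__main__":
    main()
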