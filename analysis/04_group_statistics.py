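#!/usr/bin/env python
"""Group-level statistics.

Point-by-point two-sample t-tests across the (electrode, frequency) grid
with per-electrode BH-FDR (q = 0.05) and the rule that only runs of
significant bins spanning strictly more than 5 Hz count; FCz beta
(14-30 Hz) and gamma (31-50 Hz) band-power t-tests; partial correlations
of band power with the day-3 NRS rating controlling for age, after 3-SD
outlier removal.  Writes statmap.csv and bands.csv and prints the band
results.
"""

import argparse
from pathlib import Path

import pandas as pd

from oscipain.io import read_features, read_meta
from oscipain.pipeline import PipelineConfig, stats_stage

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--features", type=Path, default=Path("results/run/features.csv"))
parser.add_argument("--meta", type=Path, default=Path("results/run/raw/meta.csv"))
parser.add_argument("--config", type=Path, default=Path("results/run/raw/config.yaml"))
parser.add_argument("--out", type=Path, default=Path("results/run/stats"))
args = parser.parse_args()

cfg = PipelineConfig.from_yaml(args.config)
features = read_features(args.features)
metas = read_meta(args.meta)
stats_stage(cfg, features, metas, args.out)

statmap = pd.read_csv(args.out / "statmap.csv")
sig = statmap[statmap.in_significant_interval]
if len(sig):
    by_e = sig.groupby("electrode").freq_hz.agg(["min", "max"])
    print("significant intervals (electrode: lo-hi Hz):")
    for e, row in by_e.iterrows():
        print(f"  {e}: {row['min']}-{row['max']} Hz")
else:
    print("no significant frequency intervals")
print()
print(pd.read_csv(args.out / "bands.csv").to_string(index=False))
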