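#!/usr/bin/env python
"""SFFS-wrapped prediction of postoperative pain.

Features are first shrunk to 20-70 Hz (3030 columns), then sequential
floating forward selection (cap 50) drives LDA classification of the pain
group and MLR regression of the day-3 NRS rating, both scored by
leave-one-out cross-validation.  The default "paper" mode evaluates with
the same LOOCV that drove the selection (optimistically biased — a
leakage warning documents this); --mode nested reruns the selection
inside every outer training fold for a leakage-free estimate.
"""

import argparse
import json
from pathlib import Path

from oscipain.io import read_features, read_meta
from oscipain.pipeline import PipelineConfig, predict_stage

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--features", type=Path, default=Path("results/run/features.csv"))
parser.add_argument("--meta", type=Path, default=Path("results/run/raw/meta.csv"))
parser.add_argument("--config", type=Path, default=Path("results/run/raw/config.yaml"))
parser.add_argument("--mode", choices=["paper", "nested"], default="paper")
parser.add_argument("--out", type=Path, default=Path("results/run/predict"))
args = parser.parse_args()

cfg = PipelineConfig.from_yaml(args.config)
cfg.mode = args.mode
features = read_features(args.features)
metas = read_meta(args.meta)
path = predict_stage(cfg, features, metas, args.out)
out = json.loads(path.read_text())
cls, reg = out["classification"], out["regression"]
print(f"classification ({args.mode}): accuracy {cls['metrics']['accuracy_pct']}% "
      f"({cls['metrics']['n_errors']} errors), {len(cls['selected_features'])} features, "
      f"stop={cls['stop_reason']}")
print(f"regression ({args.mode}): r = {reg['metrics']['pearson_r']:.3f} "
      f"(p = {reg['metrics']['p_value']:.2g}), {len(reg['selected_features'])} features, "
      f"stop={reg['stop_reason']}")
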