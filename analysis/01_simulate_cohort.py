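#!/usr/bin/env python
"""Simulate the synthetic surgical cohort.

Writes one EDF per subject plus meta.csv (age, NRS days 1-3, group,
covariates) and the resolved configuration.  The default here is a
reduced-scale cohort (24 subjects, 160 s at 200 Hz) so the whole analysis
chain runs on a laptop; pass --full for the study-scale conditions
(67 subjects, 5 min at 1000 Hz).
"""

import argparse
from pathlib import Path

from oscipain.pipeline import PipelineConfig, simulate_stage

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out", type=Path, default=Path("results/run/raw"))
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--full", action="store_true",
                    help="study-scale cohort: n=67, 300 s, 1000 Hz")
args = parser.parse_args()

if args.full:
    cfg = PipelineConfig(seed=args.seed)
else:
    cfg = PipelineConfig(n_subjects=24, duration_s=160.0, fs=200.0, seed=args.seed)

args.out.mkdir(parents=True, exist_ok=True)
cfg.to_yaml(args.out / "config.yaml")
paths = simulate_stage(cfg, args.out)
print(f"wrote {cfg.n_subjects} subjects ({cfg.duration_s:.0f} s at {cfg.fs:.0f} Hz) "
      f"to {args.out} ({len(paths)} files)")
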