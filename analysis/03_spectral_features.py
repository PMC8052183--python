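#!/usr/bin/env python
"""Welch spectra and the cohort feature matrix.

Per subject: PSD with 2-s Hamming windows at 50% overlap inside epochs,
restricted to the 0.5-80 Hz grid (160 bins/electrode).  The cohort matrix
is subject × (electrode, frequency) with 30 × 160 = 4800 columns, written
as CSV with a two-row header.
"""

import argparse
from pathlib import Path

from oscipain.io import write_features
from oscipain.pipeline import PipelineConfig, load_epochs_dir
from oscipain.spectral import build_feature_matrix, welch_psd

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--epochs", type=Path, default=Path("results/run/preprocessed"))
parser.add_argument("--config", type=Path, default=Path("results/run/raw/config.yaml"))
parser.add_argument("--out", type=Path, default=Path("results/run/features.csv"))
args = parser.parse_args()

cfg = PipelineConfig.from_yaml(args.config)
store = load_epochs_dir(args.epochs)
spectra = [welch_psd(eps, win_s=cfg.welch_win_s, overlap=cfg.welch_overlap)
           for _, eps in sorted(store.items())]
feats = build_feature_matrix(spectra)
write_features(feats, args.out)
print(f"feature matrix: {feats.X.shape[0]} subjects x {feats.X.shape[1]} features "
      f"({len(feats.electrodes)} electrodes x {len(feats.frequencies)} bins)")
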