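"""End-to-end orchestration: configuration, stage runners, and a manifest.

Every fixed constant of the analysis (montage, filter edges, 5-s epochs,
±75 µV rejection, 2-s/50% Welch windows, beta 14-30 / gamma 31-50 Hz,
FDR q = 0.05, >5 Hz contiguity, 20-70 Hz feature shrinkage, 50-feature
SFFS cap) lives in one flat config.  Unknown config keys are hard errors,
the resolved config is serialized alongside every output, and all
randomness flows from the single root seed, so a rerun from the serialized
config reproduces every artifact bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import group_stats, io, predict, preprocess, simulate, spectral
from .core import CohortFeatures, SubjectMeta
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # cohort simulation
    n_subjects: int = 67
    duration_s: float = 300.0
    fs: float = 1000.0
    pink_exponent: float = 1.0
    pink_scale: float = 9.0
    alpha_power: float = 25.0
    beta_power: float = 5.0
    gamma_power: float = 2.5
    effect_size: float = 1.5
    pain_baseline: float = 3.5
    pain_slope: float = 2.5
    pain_noise_sd: float = 1.0
    blink_rate: float = 6.0
    gross_artifact_rate: float = 0.05
    line_noise_amp: float = 2.0
    seed: int = 0
    # preprocessing
    l_freq: float = 0.5
    h_freq: float = 80.0
    notch_lo: float = 48.0
    notch_hi: float = 52.0
    epoch_len_s: float = 5.0
    reject_threshold_uv: float = 75.0
    run_ica: bool = True
    ica_max_iter: int = 200
    ic_focal_share: float = 0.8
    ic_autocorr_threshold: float = 0.5
    ic_low_freq_share: float = 0.5
    # spectra
    welch_win_s: float = 2.0
    welch_overlap: float = 0.5
    log_features: bool = False
    # statistics
    beta_lo: float = 14.0
    beta_hi: float = 30.0
    gamma_lo: float = 31.0
    gamma_hi: float = 50.0
    fdr_q: float = 0.05
    min_span_hz: float = 5.0
    fdr_family: str = "per_electrode"
    band_electrodes: tuple[str, ...] = ("FCz",)
    outlier_sd: float = 3.0
    # prediction
    shrink_lo: float = 20.0
    shrink_hi: float = 70.0
    max_k: int = 50
    lda_reg: float = 1e-3
    mode: str = "paper"  # "paper" (non-nested) or "nested"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["band_electrodes"] = list(d["band_electrodes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "band_electrodes" in raw:
            raw = dict(raw)
            raw["band_electrodes"] = tuple(raw["band_electrodes"])
        cfg = cls(**raw)
        if cfg.mode not in ("paper", "nested"):
            raise ValidationError(f"mode must be 'paper' or 'nested', got {cfg.mode!r}")
        return cfg

    def sim_params(self) -> simulate.CohortSimParams:
        return simulate.CohortSimParams(
            n_subjects=self.n_subjects, duration_s=self.duration_s, fs=self.fs,
            pink_exponent=self.pink_exponent, pink_scale=self.pink_scale,
            alpha_power=self.alpha_power, beta_power=self.beta_power,
            gamma_power=self.gamma_power, effect_size=self.effect_size,
            pain_baseline=self.pain_baseline, pain_slope=self.pain_slope,
            pain_noise_sd=self.pain_noise_sd, blink_rate=self.blink_rate,
            gross_artifact_rate=self.gross_artifact_rate,
            line_noise_amp=self.line_noise_amp, seed=self.seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_stage(config: PipelineConfig, outdir: Path) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    recs, metas = simulate.simulate_cohort(config.sim_params())
    paths = []
    for rec in recs:
        p = outdir / f"{rec.subject_id}.edf"
        io.write_edf(rec, p)
        paths.append(p)
    meta_path = outdir / "meta.csv"
    io.write_meta(metas, meta_path)
    paths.append(meta_path)
    return paths


def preprocess_stage(
    config: PipelineConfig, indir: Path, outdir: Path
) -> tuple[list[Path], dict]:
    """Preprocess every EDF in `indir`.  Cleaned epochs are written as
    per-subject .npz bundles (and also returned in memory); the cohort-level
    QC report is a CSV."""
    outdir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    rows = []
    epochs_store = {}
    paths = []
    for p in sorted(indir.glob("*.edf")):
        rec = io.read_edf(p)
        eps, report = preprocess.preprocess_recording(
            rec,
            epoch_len_s=config.epoch_len_s,
            l_freq=config.l_freq, h_freq=config.h_freq,
            notch=(config.notch_lo, config.notch_hi),
            reject_threshold_uv=config.reject_threshold_uv,
            ica_seed=config.seed, ica_max_iter=config.ica_max_iter,
            run_ica=config.run_ica,
            focal_share=config.ic_focal_share,
            autocorr_threshold=config.ic_autocorr_threshold,
            low_freq_share=config.ic_low_freq_share,
        )
        logger.info("%s: %d ICs removed, %.1f%% epochs rejected", rec.subject_id,
                    report.n_ics_removed, 100 * report.prop_epochs_rejected)
        rows.append({
            "subject_id": rec.subject_id,
            "n_ics_removed": report.n_ics_removed,
            "removed_ic_indices": ";".join(map(str, report.removed_ic_indices)),
            "prop_epochs_rejected": report.prop_epochs_rejected,
        })
        epochs_store[rec.subject_id] = eps
        ep_path = outdir / f"{rec.subject_id}_epochs.npz"
        np.savez_compressed(
            ep_path, data=eps.data, kept_mask=eps.kept_mask,
            channels=np.array(eps.channels), fs=eps.fs, epoch_len_s=eps.epoch_len_s,
        )
        paths.append(ep_path)
    report_path = outdir / "preprocess_report.csv"
    pd.DataFrame(rows).to_csv(report_path, index=False)
    return [report_path] + paths, epochs_store


def load_epochs_dir(indir: Path) -> dict:
    """Read the .npz epoch bundles written by preprocess_stage."""
    from .core import Epochs

    store = {}
    for p in sorted(Path(indir).glob("*_epochs.npz")):
        sid = p.name.removesuffix("_epochs.npz")
        with np.load(p, allow_pickle=False) as z:
            store[sid] = Epochs(
                subject_id=sid, channels=[str(c) for c in z["channels"]],
                fs=float(z["fs"]), epoch_len_s=float(z["epoch_len_s"]),
                data=z["data"], kept_mask=z["kept_mask"],
            )
    return store


def spectra_stage(config: PipelineConfig, epochs_by_subject: dict, outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    spectra = [
        spectral.welch_psd(eps, win_s=config.welch_win_s, overlap=config.welch_overlap)
        for _, eps in sorted(epochs_by_subject.items())
    ]
    feats = spectral.build_feature_matrix(spectra)
    if config.log_features:
        feats = spectral.log_transform(feats)
    path = outdir / "features.csv"
    io.write_features(feats, path)
    return path


def stats_stage(
    config: PipelineConfig, features: CohortFeatures, metas: list[SubjectMeta],
    outdir: Path,
) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    meta_by_id = {m.subject_id: m for m in metas}
    groups = [meta_by_id[s].group for s in features.subject_ids]
    ages = np.array([meta_by_id[s].age for s in features.subject_ids])
    nrs3 = np.array([meta_by_id[s].nrs_day3 for s in features.subject_ids], dtype=float)

    statmap = group_stats.pointwise_ttest(
        features, groups, q=config.fdr_q, min_span_hz=config.min_span_hz,
        fdr_family=config.fdr_family,
    )
    rows = []
    for i, e in enumerate(statmap.electrodes):
        intervals = statmap.significant_intervals.get(e, [])
        for j, f in enumerate(statmap.freqs):
            in_interval = any(lo <= f <= hi for lo, hi in intervals)
            rows.append({
                "electrode": e, "freq_hz": f, "t": statmap.t[i, j],
                "p": statmap.p[i, j], "fdr_significant": bool(statmap.p_fdr_mask[i, j]),
                "in_significant_interval": in_interval,
            })
    statmap_path = outdir / "statmap.csv"
    pd.DataFrame(rows).to_csv(statmap_path, index=False)

    n_e = len(statmap.electrodes)
    n_f = len(statmap.freqs)
    X = features.X.reshape(len(features.subject_ids), n_e, n_f)
    band_rows = []
    for name, lo, hi in (("beta", config.beta_lo, config.beta_hi),
                         ("gamma", config.gamma_lo, config.gamma_hi)):
        band = spectral.BandDefinition(name, lo, hi)
        e_idx = [statmap.electrodes.index(e) for e in config.band_electrodes]
        bins = band.bins(statmap.freqs)
        bp = X[:, e_idx][:, :, bins].mean(axis=(1, 2))
        t, p = group_stats.band_ttest(bp, groups)
        pc = group_stats.partial_correlation(bp, nrs3, ages, outlier_sd=config.outlier_sd)
        band_rows.append({
            "band": name, "lo_hz": lo, "hi_hz": hi,
            "electrodes": "+".join(config.band_electrodes),
            "t": t, "p": p,
            "partial_r": pc.r, "partial_p": pc.p, "n_used": pc.n_used,
        })
    bands_path = outdir / "bands.csv"
    pd.DataFrame(band_rows).to_csv(bands_path, index=False)
    return [statmap_path, bands_path]


def predict_stage(
    config: PipelineConfig, features: CohortFeatures, metas: list[SubjectMeta],
    outdir: Path,
) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    meta_by_id = {m.subject_id: m for m in metas}
    groups = [meta_by_id[s].group for s in features.subject_ids]
    nrs3 = np.array([meta_by_id[s].nrs_day3 for s in features.subject_ids], dtype=float)
    shrunk = spectral.restrict_features(features, config.shrink_lo, config.shrink_hi)
    nested = config.mode == "nested"
    out = {}
    for task, y, kind in (("classification", groups, "lda"),
                          ("regression", nrs3, "mlr")):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", UserWarning)
            trace, result = predict.sffs(
                shrunk, y, model_kind=kind, max_k=config.max_k,
                nested=nested, reg=config.lda_reg,
            )
        report = predict.evaluate(result)
        out[task] = {
            "selected_features": [list(shrunk.feature_index[j]) for j in trace.selected],
            "stop_reason": trace.stop_reason,
            "history": [[k, int(j), float(v)] for k, j, v in trace.history],
            "mode": config.mode,
            "subjects": result.subject_ids,
            "y_true": np.asarray(result.y_true).tolist(),
            "y_pred": np.asarray(result.y_pred).tolist(),
            "metrics": {
                "accuracy_pct": report.accuracy_pct,
                "n_errors": report.n_errors,
                "pearson_r": report.pearson_r,
                "p_value": report.p_value,
            },
        }
    path = outdir / "predictions.json"
    path.write_text(json.dumps(out, indent=2))
    return path


def run_all(config: PipelineConfig, outdir: str | Path) -> Path:
    """simulate → preprocess → spectra → stats → predict, with a manifest of
    every artifact and its content hash."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    artifacts = [outdir / "config.yaml"]

    stage = "simulate"
    try:
        artifacts += simulate_stage(config, outdir / "raw")
        stage = "preprocess"
        pre_paths, epochs_by_subject = preprocess_stage(
            config, outdir / "raw", outdir / "preprocessed"
        )
        artifacts += pre_paths
        stage = "spectra"
        feats_path = spectra_stage(config, epochs_by_subject, outdir / "spectra")
        artifacts.append(feats_path)
        features = io.read_features(feats_path)
        metas = io.read_meta(outdir / "raw" / "meta.csv")
        stage = "stats"
        artifacts += stats_stage(config, features, metas, outdir / "stats")
        stage = "predict"
        artifacts.append(predict_stage(config, features, metas, outdir / "predict"))
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        str(p.relative_to(outdir)): _sha256(p) for p in artifacts if p.is_file()
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


__all__ = [
    "PipelineConfig",
    "run_all",
    "simulate_stage",
    "preprocess_stage",
    "load_epochs_dir",
    "spectra_stage",
    "stats_stage",
    "predict_stage",
]
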