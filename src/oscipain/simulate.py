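"""Synthetic resting-state EEG cohorts with a planted pain-related effect.

Each subject is a latent pain-sensitivity trait z ~ N(0, 1) that drives two
things at once:

* the variance of frontocentral band-limited beta (14-30 Hz) and gamma
  (31-50 Hz) oscillations, multiplicatively: band power scales as
  ``exp(a * z)`` with ``a = effect_size / 1.596`` so that the two pain
  groups (median split of z when the NRS baseline sits at the group
  threshold) differ by about ``effect_size`` standard deviations in
  log band power;
* the day-3 postoperative NRS rating, linearly:
  ``clip(round(baseline + pain_slope * z + noise), 0, 10)``.

On top of that every recording carries 1/f ("pink") background activity,
an occipital alpha (8-12 Hz) rhythm, 50 Hz line noise, frontal-dominant
eye-blink transients and, in a controlled fraction of 5-s windows, gross
artifacts exceeding the ±75 µV rejection threshold.  All randomness flows
from one root seed through a per-subject counter scheme, so cohorts are
bit-reproducible and individual subjects can be regenerated alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .core import Recording, SubjectMeta, group_from_nrs
from .errors import ParameterError, ValidationError
from .montage import ALL_CHANNELS, SCALP_CHANNELS

#: E[z | z>0] - E[z | z<0] for a standard normal: converts a shift in the
#: latent trait into a between-group difference under a median split.
_HALF_NORMAL_GAP = 2.0 * np.sqrt(2.0 / np.pi)

_EPOCH_LEN_S = 5.0


def _gain_map(spec: dict[str, float], default: float, mastoid: float) -> np.ndarray:
    gains = np.full(len(ALL_CHANNELS), default)
    for i, ch in enumerate(ALL_CHANNELS):
        if ch in spec:
            gains[i] = spec[ch]
        elif ch in ("M1", "M2"):
            gains[i] = mastoid
    return gains


ALPHA_GAINS = _gain_map(
    {"O1": 1.0, "Oz": 1.0, "O2": 1.0, "P7": 0.5, "P3": 0.5, "Pz": 0.5, "P4": 0.5,
     "P8": 0.5, "CP3": 0.25, "CPz": 0.25, "CP4": 0.25, "TP7": 0.25, "TP8": 0.25},
    default=0.08, mastoid=0.02,
)

#: Beta/gamma topography peaking at FCz, the locus of the planted effect.
FRONTOCENTRAL_GAINS = _gain_map(
    {"FCz": 1.0, "FC3": 0.8, "FC4": 0.8, "Cz": 0.8, "F3": 0.6, "Fz": 0.65,
     "F4": 0.6, "C3": 0.45, "C4": 0.45, "FT7": 0.3, "FT8": 0.3, "CPz": 0.25},
    default=0.08, mastoid=0.02,
)

BLINK_GAINS = _gain_map(
    {"Fp1": 1.0, "Fp2": 1.0, "F7": 0.5, "F8": 0.5, "F3": 0.55, "Fz": 0.55,
     "F4": 0.55, "FT7": 0.25, "FT8": 0.25, "FC3": 0.3, "FCz": 0.3, "FC4": 0.3},
    default=0.05, mastoid=0.02,
)


@dataclass
class CohortSimParams:
    """Generator settings; defaults mirror the recording conditions of the
    study cohort (32 channels, 1000 Hz, 5-min eyes-closed rest, n=67)."""

    n_subjects: int = 67
    duration_s: float = 300.0
    fs: float = 1000.0
    pink_exponent: float = 1.0     # 1/f^chi amplitude slope of the background
    pink_scale: float = 9.0        # background sd, µV
    alpha_power: float = 25.0      # occipital alpha variance at unit gain, µV²
    beta_power: float = 5.0        # frontocentral beta variance at unit gain, µV²
    gamma_power: float = 2.5       # frontocentral gamma variance at unit gain, µV²
    effect_size: float = 1.5       # group difference d in log band power
    pain_baseline: float = 3.5     # NRS units; at the group threshold -> balanced groups
    pain_slope: float = 2.5        # NRS units per unit latent trait
    pain_noise_sd: float = 1.0     # NRS units
    blink_rate: float = 6.0        # blink events per minute
    gross_artifact_rate: float = 0.05  # fraction of 5-s windows hit by gross artifacts
    line_noise_amp: float = 2.0    # 50 Hz amplitude, µV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("a cohort needs at least 2 subjects")
        for name in ("pink_scale", "alpha_power", "beta_power", "gamma_power",
                     "pain_noise_sd", "blink_rate", "gross_artifact_rate",
                     "line_noise_amp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValidationError("fs and duration_s must be positive")


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int, exponent: float) -> np.ndarray:
    """Unit-sd 1/f^exponent noise per channel via spectral shaping."""
    freqs = np.fft.rfftfreq(n, d=1.0)          # relative frequencies; shape only
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, len(freqs)))
            + 1j * rng.standard_normal((n_channels, len(freqs)))) * shaping
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _band_source(rng: np.random.Generator, n: int, fs: float,
                 lo: float, hi: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise in [lo, hi] Hz."""
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n + int(2 * fs)))[int(2 * fs):]
    sd = x.std()
    return x / (sd if sd > 0 else 1.0)


def _draw_nrs(params: CohortSimParams, z: float, rng: np.random.Generator) -> tuple[int, int, int]:
    def draw(baseline: float, slope: float, noise_sd: float) -> int:
        value = baseline + slope * z + rng.normal(0.0, noise_sd)
        return int(np.clip(np.round(value), 0, 10))

    day1 = draw(4.8, 0.8 * params.pain_slope / 2.5 if params.pain_slope else 0.0, 1.6)
    day2 = draw(4.4, 1.1 * params.pain_slope / 2.5 if params.pain_slope else 0.0, 1.8)
    day3 = draw(params.pain_baseline, params.pain_slope, params.pain_noise_sd)
    return day1, day2, day3


def _draw_covariates(rng: np.random.Generator) -> dict[str, str]:
    return {
        "gender": rng.choice(["male", "female"], p=[0.43, 0.57]),
        "education": rng.choice(["junior", "high_school", "college"], p=[0.2, 0.27, 0.53]),
        "asa": rng.choice(["I", "II"], p=[0.45, 0.55]),
        "operation": rng.choice(
            ["wedge_resection", "lobectomy", "mediastinotomy"], p=[0.45, 0.46, 0.09]
        ),
    }


def simulate_subject(
    params: CohortSimParams,
    latent_trait: float,
    seed: int | np.random.SeedSequence,
) -> tuple[Recording, SubjectMeta]:
    """One subject: 32-channel recording plus metadata tied to the same trait."""
    if params.duration_s < _EPOCH_LEN_S:
        raise ParameterError(
            f"duration {params.duration_s} s is shorter than one {_EPOCH_LEN_S:.0f}-s epoch"
        )
    rng = np.random.default_rng(seed)
    fs = params.fs
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs

    data = params.pink_scale * _pink_noise(rng, len(ALL_CHANNELS), n, params.pink_exponent)
    # mastoids: background only, attenuated
    data[-2:, :] *= 0.4

    if params.alpha_power > 0:
        alpha = _band_source(rng, n, fs, 8.0, 12.0)
        data += np.sqrt(params.alpha_power) * np.outer(ALPHA_GAINS, alpha)

    # latent trait scales beta/gamma band power as exp(a * z)
    a = params.effect_size / _HALF_NORMAL_GAP
    amp_mult = np.exp(0.5 * a * latent_trait)
    for power, (lo, hi) in ((params.beta_power, (14.0, 30.0)),
                            (params.gamma_power, (31.0, 50.0))):
        if power > 0:
            src = _band_source(rng, n, fs, lo, min(hi, fs / 2 * 0.95))
            data += amp_mult * np.sqrt(power) * np.outer(FRONTOCENTRAL_GAINS, src)

    if params.line_noise_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        line = params.line_noise_amp * np.sin(2 * np.pi * 50.0 * t + phase)
        channel_gain = rng.uniform(0.8, 1.2, size=len(ALL_CHANNELS))
        data += np.outer(channel_gain, line)

    subject_id = "sub"
    rec = Recording(subject_id=subject_id, channels=list(ALL_CHANNELS), fs=fs,
                    data=data, reference="M2")
    rec = inject_artifacts(rec, params, int(rng.integers(2 ** 31)))

    day1, day2, day3 = _draw_nrs(params, latent_trait, rng)
    cov = _draw_covariates(rng)
    meta = SubjectMeta(
        subject_id=subject_id,
        age=float(int(np.clip(np.round(rng.normal(55.8, 6.9)), 35, 65))),
        nrs_day1=day1, nrs_day2=day2, nrs_day3=day3,
        group=group_from_nrs(day3), **cov,
    )
    return rec, meta


def inject_artifacts(
    recording: Recording, params: CohortSimParams, seed: int | np.random.SeedSequence
) -> Recording:
    """Add blink transients and gross ±75 µV-exceeding artifacts.

    Gross artifacts hit exactly ``round(rate * n_windows)`` distinct 5-s
    windows (windows counted from t=0, matching the epoch segmentation), each
    receiving a 150 µV, 10 Hz, 0.5-s burst on one random scalp channel.
    Blinks are 300-500 ms smooth frontal-dominant deflections at
    ``blink_rate`` events per minute.
    """
    rng = np.random.default_rng(seed)
    data = recording.data.copy()
    fs = recording.fs
    n = data.shape[1]

    n_blinks = rng.poisson(params.blink_rate * (n / fs) / 60.0) if params.blink_rate > 0 else 0
    for _ in range(n_blinks):
        dur = int(rng.uniform(0.3, 0.5) * fs)
        start = int(rng.integers(0, max(1, n - dur)))
        amp = rng.uniform(60.0, 90.0)
        bump = amp * np.hanning(dur)
        data[:, start:start + dur] += np.outer(BLINK_GAINS, bump)

    if params.gross_artifact_rate > 0:
        n_windows = int(n // int(_EPOCH_LEN_S * fs))
        n_art = int(round(params.gross_artifact_rate * n_windows))
        if n_art > 0:
            windows = rng.choice(n_windows, size=min(n_art, n_windows), replace=False)
            burst_len = int(0.5 * fs)
            envelope = np.hanning(burst_len)
            carrier = np.sin(2 * np.pi * 10.0 * np.arange(burst_len) / fs)
            burst = 150.0 * envelope * carrier
            win_len = int(_EPOCH_LEN_S * fs)
            for w in np.sort(windows):
                ch = int(rng.integers(0, len(SCALP_CHANNELS)))
                start = w * win_len + (win_len - burst_len) // 2
                data[ch, start:start + burst_len] += burst

    return replace(recording, data=data)


def simulate_cohort(
    params: CohortSimParams,
) -> tuple[list[Recording], list[SubjectMeta]]:
    """Simulate ``n_subjects`` subjects with i.i.d. standard-normal latent traits."""
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(params.n_subjects + 1)
    traits = np.random.default_rng(children[-1]).standard_normal(params.n_subjects)

    recordings, metas = [], []
    for i in range(params.n_subjects):
        rec, meta = simulate_subject(params, float(traits[i]), children[i])
        sid = f"sub-{i + 1:03d}"
        rec.subject_id = sid
        meta.subject_id = sid
        recordings.append(rec)
        metas.append(meta)
    return recordings, metas


def simulate_weak_feature_cohort(
    n_subjects: int = 60,
    n_features: int = 200,
    signal_sd: float = 0.15,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature-level cohort with many weakly informative, mutually
    independent predictors of a continuous pain rating.

    Every feature j carries an independent weight beta_j ~ N(0, signal_sd);
    the rating is ``X @ beta + N(0, noise_sd)`` and the binary label is its
    median split.  With hundreds of such features the greedy LOOCV search
    criterion keeps finding improvements instead of plateauing, which is the
    regime where a capped wrapper selection runs to its feature limit.

    Returns (X, ratings, labels).
    """
    rng = np.random.default_rng(seed)
    beta = rng.normal(0.0, signal_sd, n_features)
    X = rng.standard_normal((n_subjects, n_features))
    ratings = X @ beta + rng.normal(0.0, noise_sd, n_subjects)
    labels = (ratings > np.median(ratings)).astype(int)
    return X, ratings, labels


__all__ = [
    "CohortSimParams",
    "simulate_weak_feature_cohort",
    "simulate_subject",
    "simulate_cohort",
    "inject_artifacts",
    "ALPHA_GAINS",
    "FRONTOCENTRAL_GAINS",
    "BLINK_GAINS",
]
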