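"""Domain types shared by all pipeline stages.

Conventions: signal amplitudes are in microvolts (µV), power spectral
densities in µV²/Hz, frequencies in Hz.  The spectral grid is fixed at
0.5–80 Hz in 0.5 Hz steps (160 bins); every stage downstream of the Welch
estimator validates against it and fails fast on a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConsistencyError, ValidationError

#: The fixed 160-bin frequency grid (Hz).
FREQ_GRID: np.ndarray = np.round(np.arange(1, 161) * 0.5, 1)

#: Day-3 NRS strictly above this value defines the moderate/high-pain group.
NRS_GROUP_THRESHOLD: int = 3

GROUP_LOW = "low"
GROUP_MODERATE_HIGH = "moderate_high"


def group_from_nrs(nrs_day3: int) -> str:
    """Pain-group label from the day-3 NRS rating (strictly greater than 3 → moderate/high)."""
    return GROUP_MODERATE_HIGH if nrs_day3 > NRS_GROUP_THRESHOLD else GROUP_LOW


@dataclass
class Recording:
    """Continuous multichannel EEG, channel × sample, in µV."""

    subject_id: str
    channels: list[str]
    fs: float
    data: np.ndarray
    reference: str = "M2"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = list(self.channels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValidationError(
                f"data has {self.data.shape[0] if self.data.ndim == 2 else '?'} rows "
                f"but {len(self.channels)} channel labels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel labels are not unique")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            from .errors import LabeledChannelError

            raise LabeledChannelError(f"channel {label!r} not in recording") from None

    def copy_with(self, **kwargs) -> "Recording":
        out = replace(self, **kwargs)
        if "data" not in kwargs:
            out.data = self.data.copy()
        return out


@dataclass
class Epochs:
    """Segmented EEG (epoch × channel × sample) with rejection bookkeeping.

    ``kept_mask`` covers the originally segmented epochs; ``data`` holds only
    the kept ones, so ``kept_mask.sum() == data.shape[0]``.
    """

    subject_id: str
    channels: list[str]
    fs: float
    epoch_len_s: float
    data: np.ndarray
    kept_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValidationError("epoch data must be epoch x channel x sample")
        if self.data.shape[1] != len(self.channels):
            raise ValidationError("channel count mismatch in epochs")
        expected = int(round(self.epoch_len_s * self.fs))
        if self.data.shape[2] != expected:
            raise ValidationError(
                f"epochs have {self.data.shape[2]} samples, expected {expected}"
            )
        if int(self.kept_mask.sum()) != self.data.shape[0]:
            raise ValidationError("kept_mask true-count does not match number of kept epochs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectSpectrum:
    """Per-channel Welch PSD on the fixed 0.5–80 Hz grid (µV²/Hz)."""

    subject_id: str
    channels: list[str]
    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        validate_grid(self.freqs)
        if self.psd.shape != (len(self.channels), len(self.freqs)):
            raise ValidationError("psd shape does not match channels x freqs")
        if np.any(self.psd < 0):
            raise ValidationError("psd contains negative values")

    def channel_psd(self, label: str) -> np.ndarray:
        from .errors import LabeledChannelError

        try:
            return self.psd[self.channels.index(label)]
        except ValueError:
            raise LabeledChannelError(f"channel {label!r} not in spectrum") from None


def validate_grid(freqs: np.ndarray) -> None:
    """Fail fast unless `freqs` is exactly the 0.5–80 Hz, 0.5 Hz-step grid."""
    if freqs.shape != FREQ_GRID.shape or not np.allclose(freqs, FREQ_GRID, atol=1e-9):
        raise ConsistencyError(
            "frequency grid must be 0.5-80 Hz in 0.5 Hz steps (160 bins); "
            f"got {len(freqs)} bins"
            + (f" from {freqs[0]} to {freqs[-1]} Hz" if len(freqs) else "")
        )


_VALID_GROUPS = (GROUP_LOW, GROUP_MODERATE_HIGH)


@dataclass
class SubjectMeta:
    """Per-subject metadata: age, postoperative NRS pain ratings, group, covariates."""

    subject_id: str
    age: float
    nrs_day1: int
    nrs_day2: int
    nrs_day3: int
    group: str | None = None
    gender: str = ""
    education: str = ""
    asa: str = ""
    operation: str = ""

    def __post_init__(self) -> None:
        for name in ("nrs_day1", "nrs_day2", "nrs_day3"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) or float(v).is_integer()):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            v = int(v)
            setattr(self, name, v)
            if not 0 <= v <= 10:
                raise ValidationError(f"{name}={v} outside the 0-10 NRS range")
        derived = group_from_nrs(self.nrs_day3)
        if self.group is None or self.group == "":
            self.group = derived
        elif self.group not in _VALID_GROUPS:
            raise ValidationError(f"unknown group label {self.group!r}")
        elif self.group != derived:
            raise ValidationError(
                f"group {self.group!r} inconsistent with nrs_day3={self.nrs_day3} "
                f"(threshold {NRS_GROUP_THRESHOLD})"
            )


@dataclass
class CohortFeatures:
    """Cohort feature matrix: subject × (electrode, frequency) PSD values."""

    subject_ids: list[str]
    feature_index: list[tuple[str, float]]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.feature_index = [(str(e), float(f)) for e, f in self.feature_index]
        if self.X.shape != (len(self.subject_ids), len(self.feature_index)):
            raise ValidationError(
                f"X shape {self.X.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_index)} features"
            )
        if len(set(self.feature_index)) != len(self.feature_index):
            raise ValidationError("duplicate (electrode, frequency) pairs in feature index")

    @property
    def electrodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e, _ in self.feature_index:
            seen.setdefault(e)
        return list(seen)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array(sorted({f for _, f in self.feature_index}))

    def column(self, electrode: str, freq: float) -> np.ndarray:
        key = (electrode, float(freq))
        try:
            j = self.feature_index.index(key)
        except ValueError:
            raise ConsistencyError(f"feature {key} not in index") from None
        return self.X[:, j]


@dataclass
class PreprocessReport:
    """Quality-control counts mirrored on what clinical EEG studies report."""

    subject_id: str = ""
    n_ics_removed: int = 0
    removed_ic_indices: list[int] = field(default_factory=list)
    prop_epochs_rejected: float = 0.0
    filter_settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_epochs_rejected <= 1.0:
            raise ValidationError("prop_epochs_rejected must lie in [0, 1]")
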