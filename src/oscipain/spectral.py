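"""Welch spectral estimation and the subject × (electrode, frequency)
feature matrix.

The PSD is estimated with 2-s Hamming windows at 50% overlap taken inside
epochs (no window straddles an epoch boundary, since epochs are no longer
contiguous after rejection), averaged over all windows of all kept epochs,
and restricted to the fixed 0.5-80 Hz grid: 160 bins per electrode, hence
4800 features for the 30-channel montage.  Features are linear-power
µV²/Hz values; an optional log10 transform can be applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import FREQ_GRID, CohortFeatures, Epochs, SubjectSpectrum, validate_grid
from .errors import ConsistencyError, LabeledChannelError, ParameterError


@dataclass(frozen=True)
class BandDefinition:
    """Inclusive frequency band on the 0.5 Hz grid."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.5 <= self.lo < self.hi <= 80.0):
            raise ParameterError(f"band [{self.lo}, {self.hi}] outside 0.5-80 Hz")
        for edge in (self.lo, self.hi):
            if abs(edge * 2 - round(edge * 2)) > 1e-9:
                raise ParameterError(f"band edge {edge} is not a multiple of 0.5 Hz")

    def bins(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.lo - 1e-9) & (freqs <= self.hi + 1e-9)


BETA = BandDefinition("beta", 14.0, 30.0)
GAMMA = BandDefinition("gamma", 31.0, 50.0)


def welch_psd(epochs: Epochs, win_s: float = 2.0, overlap: float = 0.5) -> SubjectSpectrum:
    """Welch PSD per channel, averaged over all windows of all kept epochs."""
    fs = epochs.fs
    nperseg = int(round(win_s * fs))
    if win_s > epochs.epoch_len_s:
        raise ParameterError(
            f"Welch window of {win_s} s exceeds the {epochs.epoch_len_s} s epoch length"
        )
    if epochs.n_epochs < 1:
        raise ParameterError("no kept epochs to estimate a spectrum from")
    if fs < 160.0:
        raise ParameterError(f"sampling rate {fs} Hz cannot resolve the 80 Hz band edge")
    noverlap = int(round(nperseg * overlap))
    freqs, pxx = sps.welch(
        epochs.data,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    psd = pxx.mean(axis=0)  # equal window count per epoch -> plain average
    # restrict to the 0.5-80 Hz grid
    idx = []
    lookup = {round(f * 2): i for i, f in enumerate(freqs)}
    for f in FREQ_GRID:
        key = round(f * 2)
        if key not in lookup:
            raise ConsistencyError(
                f"native Welch grid (df={freqs[1] - freqs[0]:.3g} Hz) lacks the "
                f"{f} Hz bin; use a {1 / 0.5:.0f}-s-resolution window"
            )
        idx.append(lookup[key])
    psd = psd[:, idx]
    validate_grid(FREQ_GRID)
    return SubjectSpectrum(
        subject_id=epochs.subject_id,
        channels=list(epochs.channels),
        freqs=FREQ_GRID.copy(),
        psd=np.maximum(psd, 0.0),
    )


def band_power(
    spectrum: SubjectSpectrum,
    band: BandDefinition,
    electrodes: tuple[str, ...] | list[str] = ("FCz",),
) -> float:
    """Mean PSD over the band's bins and the listed electrodes (default FCz)."""
    rows = []
    for e in electrodes:
        if e not in spectrum.channels:
            raise LabeledChannelError(f"electrode {e!r} not in spectrum")
        rows.append(spectrum.channels.index(e))
    mask = band.bins(spectrum.freqs)
    if not mask.any():
        raise ParameterError(f"band {band.name} has no bins on the grid")
    return float(spectrum.psd[np.ix_(rows, np.flatnonzero(mask))].mean())


def build_feature_matrix(spectra: list[SubjectSpectrum]) -> CohortFeatures:
    """Stack spectra into a subject × (electrode-major, frequency-minor) matrix."""
    if not spectra:
        raise ParameterError("no spectra to build a feature matrix from")
    ref_channels = spectra[0].channels
    for s in spectra[1:]:
        if s.channels != ref_channels:
            raise ConsistencyError(
                f"channel list of {s.subject_id} differs from {spectra[0].subject_id}"
            )
        if not np.allclose(s.freqs, spectra[0].freqs):
            raise ConsistencyError(f"frequency grid of {s.subject_id} differs")
    feature_index = [(e, float(f)) for e in ref_channels for f in spectra[0].freqs]
    X = np.stack([s.psd.reshape(-1) for s in spectra])
    return CohortFeatures(
        subject_ids=[s.subject_id for s in spectra],
        feature_index=feature_index,
        X=X,
    )


def restrict_features(features: CohortFeatures, lo: float, hi: float) -> CohortFeatures:
    """Keep columns with lo ≤ frequency ≤ hi (inclusive), preserving order."""
    if not lo < hi:
        raise ParameterError(f"invalid restriction range [{lo}, {hi}]")
    cols = [j for j, (_, f) in enumerate(features.feature_index)
            if lo - 1e-9 <= f <= hi + 1e-9]
    if not cols:
        raise ParameterError(f"restriction to [{lo}, {hi}] Hz leaves no features")
    return CohortFeatures(
        subject_ids=list(features.subject_ids),
        feature_index=[features.feature_index[j] for j in cols],
        X=features.X[:, cols],
    )


def log_transform(features: CohortFeatures, floor: float = 1e-12) -> CohortFeatures:
    """Optional log10 transform of the linear-power features."""
    return CohortFeatures(
        subject_ids=list(features.subject_ids),
        feature_index=list(features.feature_index),
        X=np.log10(np.maximum(features.X, floor)),
    )


__all__ = [
    "BandDefinition",
    "BETA",
    "GAMMA",
    "welch_psd",
    "band_power",
    "build_feature_matrix",
    "restrict_features",
    "log_transform",
]
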