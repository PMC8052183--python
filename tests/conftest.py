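"""Shared fixtures.

The heavier fixtures (ICA decompositions, the planted-effect cohort) are
session-scoped so several tests can interrogate the same computation.
Recording lengths and sampling rates are reduced relative to the 5-min,
1000 Hz study conditions where the property under test does not depend on
them (the 0.5 Hz spectral grid only requires 2-s Welch windows and a
Nyquist above 80 Hz).
"""

from __future__ import annotations

import numpy as np
import pytest

from oscipain.preprocess import epoch, filter_recording, rereference
from oscipain.simulate import CohortSimParams, simulate_cohort
from oscipain.spectral import build_feature_matrix, welch_psd


def clean_params(**kwargs) -> CohortSimParams:
    """Generator settings with artifact channels silenced."""
    defaults = dict(blink_rate=0.0, gross_artifact_rate=0.0, line_noise_amp=0.0)
    defaults.update(kwargs)
    return CohortSimParams(**defaults)


def cohort_feature_matrix(params: CohortSimParams):
    """simulate → re-reference → epoch → Welch → cohort matrix (no ICA:
    these cohorts are artifact-free by construction)."""
    recs, metas = simulate_cohort(params)
    spectra = [welch_psd(epoch(rereference(r))) for r in recs]
    return build_feature_matrix(spectra), metas


@pytest.fixture(scope="session")
def planted_cohort():
    """60 subjects, 20-s recordings at 200 Hz, frontocentral beta+gamma
    effect of d = 1.5 coupled to the day-3 NRS rating."""
    params = clean_params(n_subjects=60, duration_s=20.0, fs=200.0,
                          effect_size=1.5, seed=77)
    features, metas = cohort_feature_matrix(params)
    return features, metas


@pytest.fixture(scope="session")
def gamma_only_cohort():
    """Planted effect carried by gamma band only (beta source silenced):
    used for contribution-map localization."""
    params = clean_params(n_subjects=40, duration_s=20.0, fs=200.0,
                          effect_size=1.5, beta_power=0.0, seed=11)
    features, metas = cohort_feature_matrix(params)
    return features, metas


@pytest.fixture(scope="session")
def blinky_decomposition():
    """One 155-s, 200 Hz subject with blinks and gross artifacts, carried
    through re-reference → filter → epoch → ICA.  155 s gives 31 epochs,
    just above the 30-epoch ICA precondition."""
    from oscipain.preprocess import ica_decompose
    from oscipain.simulate import simulate_subject

    params = CohortSimParams(duration_s=155.0, fs=200.0, blink_rate=6.0,
                             gross_artifact_rate=0.05, line_noise_amp=2.0, seed=5)
    rec, meta = simulate_subject(params, 0.3, 7)
    eps = epoch(filter_recording(rereference(rec)))
    decomp = ica_decompose(eps, seed=0)
    return rec, eps, decomp
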