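"""Group-level statistics: point-by-point spectrum t-tests with BH-FDR and
a frequency-contiguity rule, band-power tests, partial correlation with an
outlier policy, and summary-statistics utilities for demographic tables.

The point-by-point map follows the convention of spectral biomarker
studies: an independent two-sample t-test at every (electrode, frequency)
cell, Benjamini-Hochberg correction across the 160 bins within each
electrode (a config flag widens the family to all 30 × 160 cells), and the
conservative rule that only runs of significant bins spanning strictly
more than 5 Hz count as findings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

from .core import GROUP_LOW, GROUP_MODERATE_HIGH, CohortFeatures
from .errors import StatisticsError

DEFAULT_Q = 0.05
DEFAULT_MIN_SPAN_HZ = 5.0


@dataclass
class StatMap:
    """Per-(electrode, frequency) t, p, FDR mask, and significant intervals."""

    electrodes: list[str]
    freqs: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_fdr_mask: np.ndarray
    significant_intervals: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def electrode_intervals(self, electrode: str) -> list[tuple[float, float]]:
        return self.significant_intervals.get(electrode, [])


@dataclass
class PartialCorrResult:
    r: float
    p: float
    n_used: int
    outlier_ids: list[int]


def _pooled_ttest(a: np.ndarray, b: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Student (pooled-variance) two-sample t with two-tailed p; degenerate
    zero-variance cells yield t=0, p=1 with a warning rather than NaN."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.shape[axis], b.shape[axis]
    m1, m2 = a.mean(axis=axis), b.mean(axis=axis)
    v1 = a.var(axis=axis, ddof=1)
    v2 = b.var(axis=axis, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    degenerate = denom == 0
    if np.any(degenerate):
        warnings.warn(
            "zero pooled variance in some cells; reporting t=0, p=1 there",
            RuntimeWarning, stacklevel=2,
        )
        t = np.where(degenerate & (m1 == m2), 0.0, t)
        t = np.where(degenerate & (m1 != m2), np.inf * np.sign(m1 - m2), t)
    p = 2.0 * ss.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(degenerate & (np.asarray(m1) == np.asarray(m2)), 1.0, p)
    return t, p


def fdr_bh(p: np.ndarray, q: float = DEFAULT_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise StatisticsError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def contiguous_intervals(
    mask: np.ndarray,
    freqs: np.ndarray,
    min_span_hz: float = DEFAULT_MIN_SPAN_HZ,
) -> list[tuple[float, float]]:
    """Maximal runs of True bins whose bandwidth (run length × grid step)
    strictly exceeds ``min_span_hz``; returns (lo, hi) frequency pairs."""
    mask = np.asarray(mask, dtype=bool)
    freqs = np.asarray(freqs, dtype=float)
    if mask.shape != freqs.shape:
        raise StatisticsError("mask is not aligned to the frequency grid")
    if not mask.any():
        return []
    step = float(freqs[1] - freqs[0]) if len(freqs) > 1 else 0.5
    intervals = []
    padded = np.concatenate([[False], mask, [False]])
    starts = np.flatnonzero(padded[1:].astype(int) - padded[:-1].astype(int) == 1)
    ends = np.flatnonzero(padded[1:].astype(int) - padded[:-1].astype(int) == -1)
    for s, e in zip(starts, ends):
        run_len = e - s
        if run_len * step > min_span_hz:
            intervals.append((float(freqs[s]), float(freqs[e - 1])))
    return intervals


def pointwise_ttest(
    features: CohortFeatures,
    groups: list[str] | np.ndarray,
    q: float = DEFAULT_Q,
    min_span_hz: float = DEFAULT_MIN_SPAN_HZ,
    fdr_family: str = "per_electrode",
) -> StatMap:
    """Point-by-point two-sample t-test across the (electrode, frequency)
    grid with BH-FDR and the >5 Hz contiguity rule.

    ``fdr_family`` is "per_electrode" (BH across the 160 bins of each
    electrode, the default) or "global" (across all cells at once).
    """
    groups = np.asarray(groups)
    in_high = groups == GROUP_MODERATE_HIGH
    in_low = groups == GROUP_LOW
    if in_high.sum() < 2 or in_low.sum() < 2:
        raise StatisticsError(
            f"both groups need >= 2 subjects (moderate/high={int(in_high.sum())}, "
            f"low={int(in_low.sum())})"
        )
    electrodes = features.electrodes
    freqs = np.array(sorted({f for _, f in features.feature_index}))
    n_e, n_f = len(electrodes), len(freqs)
    if n_e * n_f != len(features.feature_index):
        raise StatisticsError("feature index is not a full electrode x frequency grid")
    X = features.X.reshape(len(features.subject_ids), n_e, n_f)
    t, p = _pooled_ttest(X[in_high], X[in_low], axis=0)

    if fdr_family == "global":
        mask = fdr_bh(p.reshape(-1), q=q).reshape(n_e, n_f)
    elif fdr_family == "per_electrode":
        mask = np.stack([fdr_bh(p[i], q=q) for i in range(n_e)])
    else:
        raise StatisticsError(f"unknown fdr_family {fdr_family!r}")

    intervals = {
        e: contiguous_intervals(mask[i], freqs, min_span_hz=min_span_hz)
        for i, e in enumerate(electrodes)
    }
    return StatMap(
        electrodes=electrodes, freqs=freqs, t=t, p=p, p_fdr_mask=mask,
        significant_intervals=intervals,
    )


def band_ttest(
    band_powers: np.ndarray, groups: list[str] | np.ndarray
) -> tuple[float, float]:
    """Pooled-variance two-sample t-test of per-subject band power
    (moderate/high minus low)."""
    groups = np.asarray(groups)
    a = np.asarray(band_powers, dtype=float)[groups == GROUP_MODERATE_HIGH]
    b = np.asarray(band_powers, dtype=float)[groups == GROUP_LOW]
    if len(a) < 2 or len(b) < 2:
        raise StatisticsError("both groups need at least 2 subjects")
    t, p = _pooled_ttest(a, b)
    return float(t), float(p)


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariate: np.ndarray,
    outlier_sd: float = 3.0,
) -> PartialCorrResult:
    """Partial Pearson correlation of x (EEG power) and y (pain rating)
    controlling for the covariate (age).

    Subjects whose x lies more than ``outlier_sd`` sample standard
    deviations from the mean of x are removed first; both variables are then
    residualized on the covariate and the residuals correlated.  The p-value
    uses a t reference with n_used - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    sd = x.std(ddof=1)
    if sd > 0:
        keep = np.abs(x - x.mean()) <= outlier_sd * sd
    else:
        keep = np.ones_like(x, dtype=bool)
    outlier_ids = [int(i) for i in np.flatnonzero(~keep)]
    x, y, covariate = x[keep], y[keep], covariate[keep]
    n = len(x)
    if n < 5:
        raise StatisticsError(f"only {n} subjects left after outlier removal; need >= 5")
    design = np.column_stack([np.ones(n), covariate])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    ss_rx, ss_ry = (rx ** 2).sum(), (ry ** 2).sum()
    ss_x = ((x - x.mean()) ** 2).sum()
    ss_y = ((y - y.mean()) ** 2).sum()
    # a variable fully explained by the covariate has no residual variance
    if ss_rx <= 1e-24 * max(ss_x, 1.0) or ss_ry <= 1e-24 * max(ss_y, 1.0):
        r = 0.0
    else:
        r = float((rx * ry).sum() / np.sqrt(ss_rx * ss_ry))
    r = max(-1.0, min(1.0, r))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        tval = r * np.sqrt(df / (1.0 - r ** 2))
        p = float(2.0 * ss.t.sf(abs(tval), df))
    return PartialCorrResult(r=r, p=p, n_used=n, outlier_ids=outlier_ids)


def summary_ttest(
    mean1: float, disp1: float, n1: int,
    mean2: float, disp2: float, n2: int,
    dispersion_kind: str = "sd",
) -> tuple[float, float, float]:
    """Pooled-variance two-sample t-test from summary statistics
    (mean ± sd or mean ± sem per group); returns (t, df, p)."""
    if n1 < 2 or n2 < 2:
        raise StatisticsError("each group needs n >= 2")
    if disp1 < 0 or disp2 < 0:
        raise StatisticsError("dispersions must be non-negative")
    if dispersion_kind == "sem":
        sd1, sd2 = disp1 * np.sqrt(n1), disp2 * np.sqrt(n2)
    elif dispersion_kind == "sd":
        sd1, sd2 = disp1, disp2
    else:
        raise StatisticsError(f"unknown dispersion kind {dispersion_kind!r}")
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, float(df), 1.0
        return float(np.inf * np.sign(mean1 - mean2)), float(df), 0.0
    t, p = ss.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(t), float(df), float(p)


def chisq_test(contingency: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction)."""
    table = np.asarray(contingency)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise StatisticsError("contingency table must be at least 2 x 2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise StatisticsError("contingency table must hold non-negative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise StatisticsError("contingency table has a zero marginal")
    res = ss.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


__all__ = [
    "StatMap",
    "PartialCorrResult",
    "pointwise_ttest",
    "fdr_bh",
    "contiguous_intervals",
    "band_ttest",
    "partial_correlation",
    "summary_ttest",
    "chisq_test",
]
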