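"""Prediction of postoperative pain from spectral features: regularized
linear discriminant analysis (two-class), multiple linear regression,
leave-one-out cross-validation, single-feature contribution maps, and the
sequential floating forward selection (SFFS) wrapper.

SFFS starts from the empty set; each forward step inserts the candidate
that maximizes the LOOCV criterion (classification accuracy for LDA,
Pearson r between predicted and true ratings for MLR), and after every
forward step backward steps delete any in-set feature whose removal
strictly improves the criterion.  The search stops when no step improves
the criterion or when 50 features are selected.

Two evaluation modes exist.  The default ("paper") mode scores the final
feature set with the same LOOCV that drove the selection; because every
fold's data also guided the search, this estimate is optimistically biased
and a leakage warning is emitted.  The nested mode reruns the entire
selection inside each outer training fold and is leakage-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as ss

from .core import GROUP_MODERATE_HIGH, CohortFeatures
from .errors import FitError, FoldError, ParameterError

logger = logging.getLogger(__name__)

#: An improvement smaller than this is treated as a tie (no improvement).
IMPROVEMENT_TOL = 1e-12

DEFAULT_LDA_REG = 1e-3
MAX_FEATURES = 50


# ---------------------------------------------------------------------------
# models


@dataclass
class LDAModel:
    weights: np.ndarray
    bias: float
    class_means: tuple[np.ndarray, np.ndarray]
    pooled_cov_reg: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1 for the positive (moderate/high) class, 0 otherwise."""
        return (self.decision(X) > 0).astype(int)


@dataclass
class MLRModel:
    coefficients: np.ndarray
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.coefficients + self.intercept


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        return (y == GROUP_MODERATE_HIGH).astype(int)
    return (np.asarray(y) > 0).astype(int)


def lda_fit(X: np.ndarray, y, reg: float = DEFAULT_LDA_REG) -> LDAModel:
    """Two-class LDA with a ridge-regularized pooled covariance.

    w = (Σ_pooled + reg·(tr(Σ)/p)·I)⁻¹ (μ₁ − μ₀); the bias places the
    boundary at the midpoint of the projected class means shifted by the
    log prior ratio.  reg is scaled by the mean eigenvalue so it is
    dimensionless.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y01 = _as_binary(y)
    if reg < 0:
        raise ParameterError("reg must be non-negative")
    n, p = X.shape
    n1 = int(y01.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise FitError("both classes must be present to fit LDA")
    if p == 0:  # empty feature set: fall back to the prior
        return LDAModel(weights=np.zeros(0), bias=float(np.log(n1 / n0)),
                        class_means=(np.zeros(0), np.zeros(0)), pooled_cov_reg=reg)
    mu0 = X[y01 == 0].mean(axis=0)
    mu1 = X[y01 == 1].mean(axis=0)
    Xc = X - np.where(y01[:, None] == 1, mu1, mu0)
    scatter = Xc.T @ Xc
    cov = scatter / max(n - 2, 1)
    trace = float(np.trace(cov))
    # floor keeps zero-within-class-variance (perfectly separable) features
    # solvable; the boundary midpoint is invariant to the ridge magnitude
    ridge = max(reg * trace / p, 1e-12)
    A = cov + ridge * np.eye(p)
    diff = mu1 - mu0
    try:
        w = np.linalg.solve(A, diff)
    except np.linalg.LinAlgError:
        w = np.linalg.pinv(A) @ diff
    b = -0.5 * float(w @ (mu0 + mu1)) + float(np.log(n1 / n0))
    return LDAModel(weights=w, bias=b, class_means=(mu0, mu1), pooled_cov_reg=reg)


def mlr_fit(X: np.ndarray, y: np.ndarray) -> MLRModel:
    """Ordinary least squares with intercept via a rank-revealing solver;
    rank-deficient designs get the minimum-norm solution (logged)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ParameterError("regression needs at least 2 rows")
    Z = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < p + 1:
        logger.info("rank-deficient design (rank %d < %d); minimum-norm solution",
                    rank, p + 1)
    return MLRModel(coefficients=beta[1:], intercept=float(beta[0]))


# ---------------------------------------------------------------------------
# leave-one-out cross-validation


@dataclass
class PredictionResult:
    """Per-subject LOOCV predictions; each subject is the test case once."""

    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    kind: str  # "lda" or "mlr"

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true)
        self.y_pred = np.asarray(self.y_pred)
        if len(self.subject_ids) != len(self.y_true) or len(self.y_true) != len(self.y_pred):
            raise ParameterError("one prediction per subject is required")

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))

    @property
    def pearson_r(self) -> float | None:
        if np.std(self.y_pred) == 0 or np.std(self.y_true) == 0:
            return None
        return float(np.corrcoef(self.y_true.astype(float),
                                 self.y_pred.astype(float))[0, 1])


def _check_loocv_classes(y01: np.ndarray, subject_ids: list[str]) -> None:
    for cls in (0, 1):
        count = int(np.sum(y01 == cls))
        if count == 0:
            raise FitError("both classes must be present")
        if count == 1:
            sid = subject_ids[int(np.flatnonzero(y01 == cls)[0])]
            raise FoldError(
                f"class {cls} has a single member ({sid}); its fold loses the class"
            )


def _loocv_lda_fast(X: np.ndarray, y01: np.ndarray, reg: float) -> np.ndarray:
    """Exact LOOCV class predictions for the regularized LDA, all folds at
    once via a rank-one downdate of the pooled scatter."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    n1 = int(y01.sum())
    n0 = n - n1
    if k == 0:  # prior-only prediction per training fold
        n1_tr = np.where(y01 == 1, n1 - 1, n1)
        n0_tr = np.where(y01 == 0, n0 - 1, n0)
        return (n1_tr > n0_tr).astype(int)
    mu0 = X[y01 == 0].mean(axis=0)
    mu1 = X[y01 == 1].mean(axis=0)
    Xc0 = X[y01 == 0] - mu0
    Xc1 = X[y01 == 1] - mu1
    S = Xc0.T @ Xc0 + Xc1.T @ Xc1

    nc = np.where(y01 == 1, n1, n0).astype(float)
    mu_own = np.where(y01[:, None] == 1, mu1, mu0)
    D = X - mu_own
    f = nc / (nc - 1.0)
    S_fold = S[None, :, :] - np.einsum("i,ij,il->ijl", f, D, D)
    cov = S_fold / (n - 3)
    trace = np.einsum("ijj->i", cov)
    ridge = np.maximum(reg * trace / k, 1e-12)
    A = cov + ridge[:, None, None] * np.eye(k)[None, :, :]

    # leave-one-out class means
    mu0_adj = np.where(
        y01[:, None] == 0, (n0 * mu0[None, :] - X) / (n0 - 1.0), mu0[None, :]
    )
    mu1_adj = np.where(
        y01[:, None] == 1, (n1 * mu1[None, :] - X) / (n1 - 1.0), mu1[None, :]
    )
    diff = mu1_adj - mu0_adj
    try:
        w = np.linalg.solve(A, diff[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        w = np.stack([np.linalg.pinv(A[i]) @ diff[i] for i in range(n)])
    n1_tr = np.where(y01 == 1, n1 - 1, n1).astype(float)
    n0_tr = np.where(y01 == 0, n0 - 1, n0).astype(float)
    b = -0.5 * np.einsum("ij,ij->i", w, mu0_adj + mu1_adj) + np.log(n1_tr / n0_tr)
    scores = np.einsum("ij,ij->i", w, X) + b
    return (scores > 0).astype(int)


def _loocv_mlr_fast(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact LOOCV predictions for OLS via the hat-matrix identity
    (full-rank designs); falls back to explicit refits otherwise."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank == p + 1:
        Q, _ = np.linalg.qr(Z)
        h = np.einsum("ij,ij->i", Q, Q)
        if np.all(h < 1.0 - 1e-10):
            e = y - Z @ beta
            return y - e / (1.0 - h)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = mlr_fit(X[mask], y[mask])
        preds[i] = model.predict(X[i:i + 1])[0]
    return preds


def loocv(
    X: np.ndarray,
    y,
    model_kind: str = "lda",
    features: list[int] | np.ndarray | None = None,
    reg: float = DEFAULT_LDA_REG,
    subject_ids: list[str] | None = None,
    fast: bool = True,
) -> PredictionResult:
    """Leave-one-out cross-validation of LDA (labels) or MLR (ratings).

    ``fast=False`` refits explicitly per fold; the fast paths are exact and
    used by default (and asserted equal to the naive path in the test suite).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 3:
        raise ParameterError("LOOCV needs at least 3 subjects")
    if features is not None:
        X = X[:, np.asarray(features, dtype=int)]
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(n)]
    if model_kind == "lda":
        y01 = _as_binary(y)
        _check_loocv_classes(y01, subject_ids)
        if fast:
            preds = _loocv_lda_fast(X, y01, reg)
        else:
            preds = np.empty(n, dtype=int)
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                model = lda_fit(X[mask], y01[mask], reg=reg)
                preds[i] = model.predict(X[i:i + 1])[0]
        return PredictionResult(subject_ids=subject_ids, y_true=y01, y_pred=preds,
                                kind="lda")
    elif model_kind == "mlr":
        y = np.asarray(y, dtype=float)
        if fast:
            preds = _loocv_mlr_fast(X, y)
        else:
            preds = np.empty(n)
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                model = mlr_fit(X[mask], y[mask])
                preds[i] = model.predict(X[i:i + 1])[0]
        return PredictionResult(subject_ids=subject_ids, y_true=y, y_pred=preds,
                                kind="mlr")
    raise ParameterError(f"unknown model kind {model_kind!r}")


@dataclass
class EvalReport:
    kind: str
    n: int
    accuracy_pct: float | None = None
    n_errors: int | None = None
    pearson_r: float | None = None
    p_value: float | None = None
    constant_predictions: bool = False


def evaluate(result: PredictionResult) -> EvalReport:
    """Accuracy as a percentage (2 d.p.) for classification; Pearson r with
    a two-tailed p for regression."""
    n = len(result.y_true)
    if result.kind == "lda":
        errors = int(np.sum(result.y_true != result.y_pred))
        return EvalReport(
            kind="lda", n=n,
            accuracy_pct=round(100.0 * (n - errors) / n, 2),
            n_errors=errors,
        )
    if n < 3:
        raise ParameterError("need at least 3 predictions for a correlation")
    if np.std(result.y_pred) == 0 or np.std(result.y_true) == 0:
        return EvalReport(kind="mlr", n=n, constant_predictions=True)
    r, p = ss.pearsonr(result.y_true.astype(float), result.y_pred.astype(float))
    return EvalReport(kind="mlr", n=n, pearson_r=float(r), p_value=float(p))


# ---------------------------------------------------------------------------
# single-feature contribution maps


def single_feature_maps(
    features: CohortFeatures,
    groups=None,
    ratings: np.ndarray | None = None,
    reg: float = DEFAULT_LDA_REG,
) -> dict:
    """LOOCV score of every single (electrode, frequency) feature plus the
    per-electrode (max over frequencies) and per-frequency (max over
    electrodes) contribution profiles."""
    import pandas as pd

    electrodes = features.electrodes
    freqs = sorted({f for _, f in features.feature_index})
    out: dict = {}
    index = {(e, f): j for j, (e, f) in enumerate(features.feature_index)}

    def score_matrix(score_fn) -> "pd.DataFrame":
        M = np.full((len(electrodes), len(freqs)), np.nan)
        for ei, e in enumerate(electrodes):
            for fi, f in enumerate(freqs):
                j = index.get((e, f))
                if j is None:
                    continue
                M[ei, fi] = score_fn(features.X[:, j:j + 1])
        return pd.DataFrame(M, index=electrodes, columns=freqs)

    if groups is not None:
        y01 = _as_binary(groups)

        def acc(Xj):
            return float(np.mean(_loocv_lda_fast(Xj, y01, reg) == y01))

        df = score_matrix(acc)
        out["accuracy"] = df
        out["electrode_accuracy"] = df.max(axis=1)
        out["frequency_accuracy"] = df.max(axis=0)
    if ratings is not None:
        yr = np.asarray(ratings, dtype=float)

        def rscore(Xj):
            preds = _loocv_mlr_fast(Xj, yr)
            if np.std(preds) == 0 or np.std(yr) == 0:
                return np.nan
            return float(np.corrcoef(preds, yr)[0, 1])

        df = score_matrix(rscore)
        out["r"] = df
        out["electrode_r"] = df.max(axis=1)
        out["frequency_r"] = df.max(axis=0)
    return out


# ---------------------------------------------------------------------------
# SFFS


@dataclass
class SFFSTrace:
    selected: list[int]
    history: list[tuple[str, int, float]] = field(default_factory=list)
    stop_reason: str = "no_improvement"


def _criterion_factory(X: np.ndarray, y, model_kind: str, reg: float):
    if model_kind == "lda":
        y01 = _as_binary(y)

        def crit(cols: list[int]) -> float | None:
            preds = _loocv_lda_fast(X[:, cols], y01, reg)
            return float(np.mean(preds == y01))

        return crit
    elif model_kind == "mlr":
        yr = np.asarray(y, dtype=float)

        def crit(cols: list[int]) -> float | None:
            preds = _loocv_mlr_fast(X[:, cols], yr)
            if np.std(preds) == 0 or np.std(yr) == 0:
                return None  # undefined correlation; candidate is skipped
            return float(np.corrcoef(preds, yr)[0, 1])

        return crit
    raise ParameterError(f"unknown model kind {model_kind!r}")


def _sffs_select(
    X: np.ndarray, y, model_kind: str, max_k: int, reg: float
) -> SFFSTrace:
    n_features = X.shape[1]
    crit = _criterion_factory(X, y, model_kind, reg)
    selected: list[int] = []
    history: list[tuple[str, int, float]] = []
    current = -np.inf
    stop_reason = "no_improvement"
    while True:
        # forward step: best candidate outside the set (ties -> lowest index)
        best_j, best_val = None, current
        for j in range(n_features):
            if j in selected:
                continue
            val = crit(selected + [j])
            if val is None:
                logger.debug("candidate %d skipped: criterion undefined", j)
                continue
            if val > best_val + IMPROVEMENT_TOL:
                best_j, best_val = j, val
        if best_j is None:
            stop_reason = "no_improvement"
            break
        selected.append(best_j)
        current = best_val
        history.append(("forward", best_j, current))
        just_added = best_j

        # backward steps: drop any feature whose removal strictly improves
        while len(selected) > 2:
            best_drop, best_drop_val = None, current
            for fjx in selected:
                if fjx == just_added:
                    continue  # never remove the feature just added
                cols = [c for c in selected if c != fjx]
                val = crit(cols)
                if val is None:
                    continue
                if val > best_drop_val + IMPROVEMENT_TOL:
                    best_drop, best_drop_val = fjx, val
            if best_drop is None:
                break
            selected.remove(best_drop)
            current = best_drop_val
            history.append(("backward", best_drop, current))

        if len(selected) >= max_k:
            stop_reason = "max_k"
            break
    return SFFSTrace(selected=selected, history=history, stop_reason=stop_reason)


def sffs(
    features: CohortFeatures | np.ndarray,
    y,
    model_kind: str = "lda",
    max_k: int = MAX_FEATURES,
    nested: bool = False,
    reg: float = DEFAULT_LDA_REG,
    subject_ids: list[str] | None = None,
) -> tuple[SFFSTrace, PredictionResult]:
    """SFFS-wrapped LOOCV prediction.

    Non-nested (default): the reported LOOCV is the selection criterion
    itself — the historical convention for this analysis — and a leakage
    warning is emitted because the estimate is optimistically biased.
    Nested: the whole selection is rerun inside each outer training fold;
    the returned predictions are leakage-free while the returned trace is
    the full-data selection (the feature set one would deploy).
    """
    X = features.X if isinstance(features, CohortFeatures) else np.atleast_2d(
        np.asarray(features, dtype=float))
    if X.shape[1] < 1:
        raise ParameterError("SFFS needs at least one candidate feature")
    if max_k < 1:
        raise ParameterError("max_k must be at least 1")
    n = X.shape[0]
    if subject_ids is None:
        subject_ids = (features.subject_ids if isinstance(features, CohortFeatures)
                       else [f"s{i}" for i in range(n)])
    trace = _sffs_select(X, y, model_kind, max_k, reg)

    if not nested:
        warnings.warn(
            "non-nested SFFS: the reported LOOCV performance also drove the "
            "feature selection and is optimistically biased",
            UserWarning, stacklevel=2,
        )
        result = loocv(X, y, model_kind=model_kind, features=trace.selected,
                       reg=reg, subject_ids=subject_ids)
        return trace, result

    y_arr = _as_binary(y) if model_kind == "lda" else np.asarray(y, dtype=float)
    preds = np.empty(n, dtype=float)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        inner = _sffs_select(X[mask], y_arr[mask], model_kind, max_k, reg)
        cols = inner.selected
        if model_kind == "lda":
            model = lda_fit(X[mask][:, cols], y_arr[mask], reg=reg)
            preds[i] = model.predict(X[i:i + 1, cols])[0]
        else:
            model = mlr_fit(X[mask][:, cols], y_arr[mask])
            preds[i] = model.predict(X[i:i + 1, cols])[0]
    if model_kind == "lda":
        preds = preds.astype(int)
    result = PredictionResult(subject_ids=list(subject_ids), y_true=y_arr,
                              y_pred=preds, kind=model_kind)
    return trace, result


__all__ = [
    "LDAModel",
    "MLRModel",
    "PredictionResult",
    "EvalReport",
    "SFFSTrace",
    "lda_fit",
    "mlr_fit",
    "loocv",
    "evaluate",
    "single_feature_maps",
    "sffs",
    "DEFAULT_LDA_REG",
    "MAX_FEATURES",
]
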