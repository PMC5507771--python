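"""Permutation validation of cross-validated models and ROC analysis.

The goodness-of-prediction Q2 of a cross-validated O-PLS(-DA) model is
compared against its null distribution obtained by permuting the response
and re-running the *entire* cross-validation (folds re-drawn inside each
iteration, the conservative choice).  Empirical p-values use the add-one
convention p = (1 + #{permuted >= observed}) / (n_iter + 1), one-sided in
the direction of large Q2, so p = 0 is impossible and the smallest
attainable value is 1/(n_iter + 1).

ROC curves are computed on held-out cross-validated predictive scores; the
AUC uses the midrank Mann-Whitney formulation (ties contribute 1/2), which
agrees with trapezoidal integration of the curve to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .opls import CvResult, kfold_cv

__all__ = [
    "PermutationTest",
    "RocResult",
    "permutation_pvalue",
    "roc_curve",
    "mann_whitney_auc",
    "validate_model",
    "ValidationReport",
]


@dataclass
class PermutationTest:
    observed: float
    permuted: np.ndarray
    n_iter: int
    p_value: float
    seed: int | None = None

    def summary(self) -> str:
        return (
            f"observed = {self.observed:.4f}, permutation p = {self.p_value:.4g} "
            f"({self.n_iter} iterations)"
        )


def permutation_pvalue(
    model_fn, X, y, n_iter: int = 10_000, seed: int | None = 0
) -> PermutationTest:
    """One-sided empirical p for ``model_fn(X, y, rng) -> statistic``.

    Each iteration permutes y uniformly at random and recomputes the full
    statistic; any stochastic internals (e.g. CV fold assignment) should
    draw from the ``rng`` handed to ``model_fn``.  A failing iteration is
    resampled once; a second failure propagates.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    observed = float(model_fn(X, y, rng))
    if not np.isfinite(observed):
        raise ValueError("statistic is not finite on the original data")
    permuted = np.empty(n_iter)
    for i in range(n_iter):
        y_perm = rng.permutation(y)
        try:
            permuted[i] = model_fn(X, y_perm, rng)
        except Exception:
            y_perm = rng.permutation(y)
            permuted[i] = model_fn(X, y_perm, rng)  # second failure propagates
    p = (1.0 + int((permuted >= observed).sum())) / (n_iter + 1.0)
    return PermutationTest(observed, permuted, n_iter, p, seed)


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def summary(self) -> str:
        return f"AUC = {self.auc:.4f} ({self.fpr.size} curve points)"


def mann_whitney_auc(scores, labels) -> float:
    """AUC by midranks: P(score_1 > score_0) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def roc_curve(scores, labels) -> RocResult:
    """ROC over all unique score thresholds plus rank-formulation AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(thr, fpr, tpr, mann_whitney_auc(scores, labels))


@dataclass
class ValidationReport:
    cv: CvResult
    permutation: PermutationTest
    roc: RocResult | None
    mode: str
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "mode": self.mode,
            "q2": self.cv.q2,
            "press": self.cv.press,
            "tss": self.cv.tss,
            "p_value": self.permutation.p_value,
            "n_iter": self.permutation.n_iter,
            "auc": None if self.roc is None else self.roc.auc,
        }
        out.update(self.config)
        return out


def validate_model(
    X,
    y,
    mode: str = "regression",
    k: int = 7,
    n_orth: int = 1,
    scaling: str = "uv",
    n_iter: int = 10_000,
    seed: int | None = 0,
) -> ValidationReport:
    """Cross-validate, permutation-test Q2, and (classification) ROC.

    ``mode='da'`` expects 0/1 coded y, stratifies folds, and adds a ROC on
    the held-out predictive scores; ``mode='regression'`` omits the ROC.
    """
    if mode not in ("regression", "da"):
        raise ValueError("mode must be 'regression' or 'da'")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    stratified = mode == "da"

    rng_cv = np.random.default_rng(
        np.random.SeedSequence([0x5CF, int(seed)]) if seed is not None else None
    )
    cv = kfold_cv(X, y, k=k, n_orth=n_orth, scaling=scaling,
                  stratified=stratified, rng=rng_cv, seed=seed)

    def q2_stat(Xp, yp, rng):
        return kfold_cv(Xp, yp, k=k, n_orth=n_orth, scaling=scaling,
                        stratified=stratified, rng=rng, seed=None).q2

    perm = permutation_pvalue(q2_stat, X, y, n_iter=n_iter, seed=seed)
    roc = roc_curve(cv.cv_scores, y) if mode == "da" else None
    cfg = {"k": k, "n_orth": n_orth, "scaling": scaling, "seed": seed, "n": int(y.size)}
    return ValidationReport(cv, perm, roc, mode, cfg)
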