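"""Orthogonal projections to latent structures (O-PLS / O-PLS-DA).

Single-response PLS with response-orthogonal variation filtered out of X
before the predictive component, in the statsmodels idiom: construct a
model from data, call :meth:`OPLS.fit`, get an :class:`OPLSResults`
carrying weights, loadings, scores, variance fractions and prediction.

For a single response the predictive weight vector w ∝ X'y is invariant
under orthogonal-component deflation (t_o'y = 0 exactly), so the algorithm
is deterministic and non-iterative:

1. center X (and optionally scale), center y;
2. w = X'y / ||X'y||, t = Xw, p = X't/t't;
3. for each orthogonal component: w_o ∝ p - (w'p)w, t_o = Xw_o,
   p_o = X't_o/t_o't_o, X <- X - t_o p_o';
4. refit the predictive component on the filtered X; q = y't/t't.

Predicted response for new samples: apply training centering/scaling,
strip the stored orthogonal components in order, then yhat = (Xw)q + ymean.

``kfold_cv`` provides seeded (optionally class-stratified) k-fold
cross-validation with the pooled PRESS and Q2 = 1 - PRESS/TSS, TSS about
the full-sample mean (the chemometrics convention; switchable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OPLS",
    "OPLSDA",
    "OPLSResults",
    "CvResult",
    "fit_pls1",
    "kfold_cv",
    "encode_classes",
]

_WNORM_TOL = 1e-12


def _prepare_scale(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray]:
    x_mean = X.mean(axis=0)
    if scaling == "none":
        x_scale = np.ones(X.shape[1])
    elif scaling == "uv":
        sd = X.std(axis=0, ddof=1)
        x_scale = np.where(sd > 0, sd, 1.0)
    elif scaling == "pareto":
        sd = X.std(axis=0, ddof=1)
        x_scale = np.where(sd > 0, np.sqrt(sd), 1.0)
    else:
        raise ValueError("scaling must be 'none', 'uv' or 'pareto'")
    return x_mean, x_scale


@dataclass
class OPLSResults:
    """Fitted O-PLS model: estimates, diagnostics and prediction."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    w: np.ndarray          # predictive weights, unit norm
    p: np.ndarray          # predictive X-loadings
    q: float               # y-loading
    w_orth: list = field(default_factory=list)
    p_orth: list = field(default_factory=list)
    t: np.ndarray | None = None        # training predictive scores
    t_orth: np.ndarray | None = None   # training orthogonal scores (n x n_orth)
    r2x: float = np.nan
    r2y: float = np.nan
    n_obs: int = 0
    scaling: str = "uv"
    class_mapping: dict | None = None
    feature_names: list | None = None

    @property
    def n_orth(self) -> int:
        return len(self.w_orth)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.t * self.q + self.y_mean

    def coefficients(self) -> np.ndarray:
        """Back-transformed regression coefficients on the original X scale."""
        # orthogonal filtering is linear; fold it into the coefficient vector
        beta = self.w.copy()
        for w_o, p_o in zip(reversed(self.w_orth), reversed(self.p_orth)):
            beta = beta - w_o * (p_o @ beta)
        return beta * self.q / self.x_scale

    def _filter(self, Xs: np.ndarray) -> np.ndarray:
        for w_o, p_o in zip(self.w_orth, self.p_orth):
            t_o = Xs @ w_o
            Xs = Xs - np.outer(t_o, p_o)
        return Xs

    def predict(self, X_new, return_scores: bool = False):
        """Predicted response; optionally also the predictive scores."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.x_mean.size:
            raise ValueError(
                f"X has {X_new.shape[1]} columns, model was fit with {self.x_mean.size}"
            )
        Xs = (X_new - self.x_mean) / self.x_scale
        Xs = self._filter(Xs)
        t = Xs @ self.w
        yhat = t * self.q + self.y_mean
        return (yhat, t) if return_scores else yhat

    def summary(self) -> str:
        lines = [
            "O-PLS results",
            "=" * 46,
            f"n observations        {self.n_obs}",
            f"n features            {self.x_mean.size}",
            f"orthogonal components {self.n_orth}",
            f"scaling               {self.scaling}",
            f"R2X (model)           {self.r2x:.4f}",
            f"R2Y (fit)             {self.r2y:.4f}",
        ]
        if self.class_mapping:
            lines.append(f"class coding          {self.class_mapping}")
        beta = self.coefficients()
        top = np.argsort(-np.abs(beta))[:10]
        lines.append("-" * 46)
        lines.append("top |coefficient| features:")
        for j in top:
            name = self.feature_names[j] if self.feature_names else f"x{j}"
            lines.append(f"  {name:<28} {beta[j]: .4g}")
        return "\n".join(lines)

    def plot_scores(self, y=None, ax=None):
        """Predictive vs first orthogonal score scatter (convenience)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t2 = self.t_orth[:, 0] if self.n_orth else np.zeros_like(self.t)
        sc = ax.scatter(self.t, t2, c=None if y is None else np.asarray(y))
        ax.set_xlabel("predictive score t")
        ax.set_ylabel("orthogonal score t_o1")
        if y is not None:
            plt.colorbar(sc, ax=ax)
        return ax


class OPLS:
    """O-PLS regression model for a single quantitative response.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response vector.
    exog : array-like, shape (n, k)
        Feature matrix (e.g. log-SRV cluster intensities).
    n_orth : int
        Number of response-orthogonal components to strip (0 = plain PLS1).
    scaling : {'uv', 'none', 'pareto'}
        Column scaling applied after centering; unit variance by default.
    """

    def __init__(self, endog, exog, n_orth: int = 1, scaling: str = "uv",
                 feature_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("endog and exog row counts differ")
        if n_orth < 0:
            raise ValueError("n_orth must be >= 0")
        if self.endog.size < n_orth + 3:
            raise ValueError("need n >= n_orth + 3 observations")
        self.n_orth = n_orth
        self.scaling = scaling
        self.feature_names = list(feature_names) if feature_names is not None else None

    @classmethod
    def from_feature_table(cls, ft, y, **kwargs):
        """Build from a :class:`~metabopredict.srv.FeatureTable` and an
        id-indexed response Series (rows matched on sample id)."""
        y = pd.Series(y)
        ids = [i for i in ft.sample_ids if i in set(map(str, y.index))]
        sub = ft.subset_samples(ids)
        return cls(y.loc[ids].to_numpy(dtype=float), sub.values,
                   feature_names=sub.labels, **kwargs)

    def fit(self) -> OPLSResults:
        y = self.endog
        if np.std(y) == 0:
            raise ValueError("zero-variance response")
        x_mean, x_scale = _prepare_scale(self.exog, self.scaling)
        Xs = (self.exog - x_mean) / x_scale
        y_mean = float(y.mean())
        yc = y - y_mean

        cov = Xs.T @ yc
        nrm = np.linalg.norm(cov)
        if nrm < _WNORM_TOL:
            raise ValueError("X'y is (numerically) zero; no predictive direction")
        w = cov / nrm

        Xf = Xs.copy()
        w_orth_list, p_orth_list, t_orth_cols = [], [], []
        for _ in range(self.n_orth):
            t = Xf @ w
            p = Xf.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            n_o = np.linalg.norm(w_o)
            if n_o < _WNORM_TOL:
                break  # no orthogonal variation left; record actual count
            w_o = w_o / n_o
            t_o = Xf @ w_o
            p_o = Xf.T @ t_o / (t_o @ t_o)
            Xf = Xf - np.outer(t_o, p_o)
            w_orth_list.append(w_o)
            p_orth_list.append(p_o)
            t_orth_cols.append(t_o)

        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        q = float(yc @ t / (t @ t))

        fitted = t * q
        ssy = float(yc @ yc)
        r2y = 1.0 - float((yc - fitted) @ (yc - fitted)) / ssy if ssy > 0 else np.nan
        ssx = float((Xs**2).sum())
        modelled = float((np.outer(t, p) ** 2).sum()) + sum(
            float((np.outer(t_o, p_o) ** 2).sum())
            for t_o, p_o in zip(t_orth_cols, p_orth_list)
        )
        r2x = modelled / ssx if ssx > 0 else np.nan

        return OPLSResults(
            x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
            w=w, p=p, q=q,
            w_orth=w_orth_list, p_orth=p_orth_list,
            t=t,
            t_orth=np.column_stack(t_orth_cols) if t_orth_cols else np.empty((y.size, 0)),
            r2x=r2x, r2y=r2y, n_obs=y.size, scaling=self.scaling,
            feature_names=self.feature_names,
        )


def encode_classes(labels) -> tuple[np.ndarray, dict]:
    """Dummy-code a two-level factor as 0/1 by sorted level name."""
    labels = pd.Series(labels).astype(str)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(
            f"O-PLS-DA needs exactly 2 class levels, got {levels}; "
            "use a one-vs-rest configuration for more"
        )
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples")
    mapping = {levels[0]: 0, levels[1]: 1}
    return labels.map(mapping).to_numpy(dtype=float), mapping


class OPLSDA(OPLS):
    """O-PLS discriminant analysis on a dummy-coded two-class factor."""

    def __init__(self, labels, exog, n_orth: int = 1, scaling: str = "uv",
                 feature_names=None):
        y, mapping = encode_classes(labels)
        super().__init__(y, exog, n_orth=n_orth, scaling=scaling,
                         feature_names=feature_names)
        self.class_mapping = mapping

    def fit(self) -> OPLSResults:
        res = super().fit()
        res.class_mapping = self.class_mapping
        return res


@dataclass
class CvResult:
    """Pooled k-fold cross-validation of a single-response O-PLS model."""

    folds: np.ndarray          # fold index per sample, 1..k
    y: np.ndarray
    y_pred: np.ndarray         # held-out predictions, one per sample
    cv_scores: np.ndarray      # held-out predictive scores
    press: float
    tss: float
    q2: float
    k: int
    n_orth: int
    seed: int | None = None

    def summary(self) -> str:
        return (
            f"{self.k}-fold CV (n={len(self.y)}, n_orth={self.n_orth}): "
            f"Q2 = {self.q2:.4f}, PRESS = {self.press:.4g}, TSS = {self.tss:.4g}"
        )


def _fold_assignment(n, k, seed, y=None, stratified=False, rng=None):
    rng = rng if rng is not None else np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if stratified and y is not None:
        ok = True
        for level in np.unique(y):
            if (y == level).sum() < k:
                ok = False
        if not ok:
            warnings.warn(
                "a class has fewer samples than folds; falling back to "
                "unstratified fold assignment"
            )
            stratified = False
    if stratified and y is not None:
        for level in np.unique(y):
            idx = np.flatnonzero(y == level)
            rng.shuffle(idx)
            folds[idx] = np.arange(idx.size) % k + 1
    else:
        idx = rng.permutation(n)
        folds[idx] = np.arange(n) % k + 1
    return folds


def kfold_cv(
    X,
    y,
    k: int = 7,
    n_orth: int = 1,
    scaling: str = "uv",
    seed: int | None = 0,
    stratified: bool = False,
    rng=None,
    folds=None,
) -> CvResult:
    """Seeded k-fold CV; every sample predicted exactly once.

    Q2 = 1 - PRESS/TSS with TSS about the full-sample mean of y.  For
    discriminant problems pass ``stratified=True`` with the 0/1 coded y.
    An explicit ``folds`` array (1..k per sample) overrides the seeded
    assignment; an explicit ``rng`` overrides ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    if folds is None:
        folds = _fold_assignment(n, k, seed, y=y, stratified=stratified, rng=rng)
    else:
        folds = np.asarray(folds, dtype=int)
    y_pred = np.empty(n)
    scores = np.empty(n)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        res = OPLS(y[train], X[train], n_orth=n_orth, scaling=scaling).fit()
        yhat, t = res.predict(X[test], return_scores=True)
        y_pred[test] = yhat
        scores[test] = t
    press = float(((y - y_pred) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / tss
    return CvResult(folds, y, y_pred, scores, press, tss, q2, int(k), n_orth, seed)


def fit_pls1(X, y, scaling: str = "uv") -> OPLSResults:
    """Single-component PLS1 (the n_orth = 0 special case of O-PLS)."""
    return OPLS(y, X, n_orth=0, scaling=scaling).fit()
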