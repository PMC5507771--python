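"""Metabolome-wide association mapping.

Spearman rank correlations between (day-0) metabolite cluster intensities
and (day-20) quantitative phenotypes, with per-cell permutation empirical
p-values (two-sided on |rho|, add-one corrected) and a significance mask at
alpha.  Each cell draws its permutations from a seed derived from
(master seed, feature index, phenotype index), so subsetting features or
parallelizing columns never shifts another cell's p-value.  No
multiple-testing correction is applied by default (per-cell p < alpha
masking, matching the heatmap convention); Benjamini-Hochberg FDR masking
is available as an option.

Also provides the phenotype prediction screen: one permutation-validated
O-PLS regression per (timepoint, phenotype) pair.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .srv import FeatureTable
from .validation import validate_model

__all__ = [
    "AssociationMatrix",
    "spearman_rho",
    "spearman_perm_p",
    "build_association_matrix",
    "phenotype_prediction_screen",
]


def _midranks_pair(x, y):
    """Pairwise-complete midranks; returns (rx, ry, n) or None if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return None
    rx = rankdata(x[ok])
    ry = rankdata(y[ok])
    if rx.std() == 0 or ry.std() == 0:
        return None
    return rx, ry, n


def _pearson(a, b) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def spearman_rho(x, y) -> tuple[float, int]:
    """Spearman rho = Pearson correlation of midranks, pairwise-complete.

    Returns (rho, n used); rho is NaN when fewer than 3 complete pairs
    remain or either variable has zero rank variance.
    """
    pair = _midranks_pair(x, y)
    if pair is None:
        ok = int((np.isfinite(np.asarray(x, float)) & np.isfinite(np.asarray(y, float))).sum())
        return float("nan"), ok
    rx, ry, n = pair
    return _pearson(rx, ry), n


def spearman_perm_p(x, y, n_iter: int = 10_000, seed=0) -> tuple[float, float, int]:
    """Two-sided permutation p on |rho|, permuting y; add-one corrected.

    ``seed`` may be any ``numpy.random.default_rng`` seed, including a
    ``SeedSequence``.  Returns (rho, p, n); both are NaN when rho is
    undefined.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    pair = _midranks_pair(x, y)
    if pair is None:
        rho, n = spearman_rho(x, y)
        return rho, float("nan"), n
    rx, ry, n = pair
    rho = _pearson(rx, ry)
    rng = np.random.default_rng(seed)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    # vectorized: one gather + one matmul for the whole permutation sample
    perm_idx = np.argsort(rng.random((n_iter, n)), axis=1)
    rho_perm = (ryc[perm_idx] @ rxc) / denom
    exceed = int((np.abs(rho_perm) >= abs(rho) - 1e-12).sum())
    p = (1.0 + exceed) / (n_iter + 1.0)
    return rho, p, n


@dataclass
class AssociationMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    alpha: float
    n_iter: int
    seed: int

    @property
    def mask(self) -> pd.DataFrame:
        """Significance mask (p < alpha); recomputed from p, so changing
        ``alpha`` re-masks without recomputing p."""
        return self.p < self.alpha

    def masked(self, alpha: float | None = None) -> pd.DataFrame:
        a = self.alpha if alpha is None else alpha
        return self.rho.where(self.p < a)

    def fdr_mask(self, alpha: float | None = None) -> pd.DataFrame:
        """Optional Benjamini-Hochberg mask over all finite cells."""
        from statsmodels.stats.multitest import multipletests

        a = self.alpha if alpha is None else alpha
        flat = self.p.to_numpy().ravel()
        ok = np.isfinite(flat)
        rej = np.zeros(flat.size, dtype=bool)
        if ok.any():
            rej[ok] = multipletests(flat[ok], alpha=a, method="fdr_bh")[0]
        return pd.DataFrame(
            rej.reshape(self.p.shape), index=self.p.index, columns=self.p.columns
        )

    def n_significant(self) -> int:
        return int(self.mask.to_numpy().sum())

    def to_long(self) -> pd.DataFrame:
        long = self.rho.stack().rename("rho").to_frame()
        long["p"] = self.p.stack()
        long["n"] = self.n.stack()
        long["significant"] = long["p"] < self.alpha
        return long.reset_index(names=["feature", "phenotype"])

    def write(self, outdir, sep: str = "\t") -> None:
        os.makedirs(outdir, exist_ok=True)
        self.rho.to_csv(os.path.join(outdir, "rho.tsv"), sep=sep)
        self.p.to_csv(os.path.join(outdir, "p.tsv"), sep=sep)
        self.mask.astype(int).to_csv(os.path.join(outdir, "mask.tsv"), sep=sep)
        self.to_long().to_csv(os.path.join(outdir, "associations_long.tsv"),
                              sep=sep, index=False)

    def plot_heatmap(self, ax=None):
        """Significant-cell heatmap (non-significant cells blank)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(0.3 * len(self.rho.columns) + 2,
                                          0.25 * len(self.rho) + 2))
        data = self.masked().to_numpy(dtype=float)
        im = ax.imshow(data, cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
        ax.set_xticks(range(len(self.rho.columns)), self.rho.columns, rotation=90)
        ax.set_yticks(range(len(self.rho.index)), self.rho.index)
        plt.colorbar(im, ax=ax, label="Spearman rho (p < alpha)")
        return ax


def build_association_matrix(
    features: FeatureTable | pd.DataFrame,
    phenotypes: pd.DataFrame,
    alpha: float = 0.05,
    n_iter: int = 10_000,
    seed: int = 0,
) -> AssociationMatrix:
    """rho, permutation p and mask for every feature x phenotype pair.

    Rows are matched on shared animal ids (order of the feature table);
    per-cell permutation streams are seeded by (seed, feature index,
    phenotype index).
    """
    fdf = features.to_dataframe() if isinstance(features, FeatureTable) else features
    shared = [i for i in fdf.index if i in set(map(str, phenotypes.index))]
    if not shared:
        raise ValueError("no shared animal ids between features and phenotypes")
    fdf = fdf.loc[shared]
    pdf = phenotypes.loc[shared]

    rho = np.full((fdf.shape[1], pdf.shape[1]), np.nan)
    pmat = np.full_like(rho, np.nan)
    nmat = np.zeros(rho.shape, dtype=int)
    for i in range(fdf.shape[1]):
        x = fdf.iloc[:, i].to_numpy(dtype=float)
        for j in range(pdf.shape[1]):
            y = pdf.iloc[:, j].to_numpy(dtype=float)
            cell_seed = np.random.SeedSequence([int(seed), i, j])
            r, p, n = spearman_perm_p(x, y, n_iter=n_iter, seed=cell_seed)
            rho[i, j], pmat[i, j], nmat[i, j] = r, p, n
    idx = list(fdf.columns)
    cols = list(pdf.columns)
    return AssociationMatrix(
        pd.DataFrame(rho, idx, cols),
        pd.DataFrame(pmat, idx, cols),
        pd.DataFrame(nmat, idx, cols),
        alpha, n_iter, int(seed),
    )


def phenotype_prediction_screen(
    features_by_timepoint: dict,
    phenotypes: pd.DataFrame,
    k: int = 7,
    n_orth: int = 1,
    n_iter: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One validated O-PLS regression per (timepoint, phenotype).

    Returns a long table with columns timepoint, phenotype, q2, p_value,
    significant.  Phenotypes with zero variance are skipped with a note
    column rather than an error.
    """
    rows = []
    for tp, ft in features_by_timepoint.items():
        fdf = ft.to_dataframe() if isinstance(ft, FeatureTable) else ft
        shared = [i for i in fdf.index if i in set(map(str, phenotypes.index))]
        X = fdf.loc[shared].to_numpy(dtype=float)
        for col in phenotypes.columns:
            y = phenotypes.loc[shared, col].to_numpy(dtype=float)
            if np.nanstd(y) == 0 or not np.all(np.isfinite(y)):
                rows.append({"timepoint": tp, "phenotype": col, "q2": np.nan,
                             "p_value": np.nan, "significant": False,
                             "note": "skipped: zero variance or missing values"})
                continue
            sub_seed = int(np.random.SeedSequence(
                [int(seed), int(tp), zlib.crc32(str(col).encode())]
            ).generate_state(1)[0] % 2**31)
            rep = validate_model(X, y, mode="regression", k=k, n_orth=n_orth,
                                 n_iter=n_iter, seed=sub_seed)
            rows.append({"timepoint": tp, "phenotype": col,
                         "q2": rep.cv.q2, "p_value": rep.permutation.p_value,
                         "significant": rep.permutation.p_value < alpha, "note": ""})
    return pd.DataFrame(rows)
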