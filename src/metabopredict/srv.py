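"""Statistical recoupling of variables (SRV): collapse correlated adjacent
spectral variables into clusters and build the variance-stabilized feature
table used by all downstream models.

The correlation landscape r_j is the Pearson correlation across samples
between consecutive columns j and j+1 (constant columns contribute 0).
Maximal runs with r_j >= ``corr_threshold`` become clusters; runs covering
fewer than ``min_size`` columns are discarded.  Cluster boundaries are
therefore local minima of the landscape by construction.  Features are the
per-sample mean (or sum) of member columns, optionally log-transformed
with a recorded offset, and annotated against a metabolite library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import MetaboliteSpec
from .spectra import SpectralDataset

__all__ = [
    "SrvCluster",
    "FeatureTable",
    "srv_cluster",
    "cluster_intensities",
    "log_transform",
    "annotate_clusters",
]


@dataclass
class SrvCluster:
    start: int  # inclusive column index
    end: int    # inclusive column index
    ppm_lo: float
    ppm_hi: float
    label: str = "unassigned"

    @property
    def n_columns(self) -> int:
        return self.end - self.start + 1

    @property
    def header(self) -> str:
        return f"{self.ppm_lo:.4f}:{self.ppm_hi:.4f}:{self.label}"


@dataclass
class FeatureTable:
    values: np.ndarray
    clusters: list[SrvCluster]
    sample_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.sample_ids), len(self.clusters)):
            raise ValueError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")

    @property
    def labels(self) -> list[str]:
        return [c.header for c in self.clusters]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.labels)

    def write(self, path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index_label="sample")

    def subset_samples(self, ids: list[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(str(i)) for i in ids]
        return FeatureTable(self.values[idx], self.clusters, [str(i) for i in ids], dict(self.meta))


def correlation_landscape(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between consecutive columns; constant columns -> 0."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    num = (Xc[:, :-1] * Xc[:, 1:]).sum(axis=0)
    den = X.shape[0] * sd[:-1] * sd[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return r


def srv_cluster(
    ds: SpectralDataset,
    corr_threshold: float = 0.9,
    min_size: int = 3,
    singlet_window: int = 0,
) -> list[SrvCluster]:
    """Cluster adjacent columns whose consecutive correlation stays high.

    ``singlet_window`` > 0 additionally rescues isolated single-column
    peaks: uncovered columns that are local maxima of the mean spectrum
    within +/- that window become one-column clusters (bypassing
    ``min_size``).  Requires >= 3 samples.
    """
    if not 0 < corr_threshold < 1:
        raise ValueError("corr_threshold must lie in (0, 1)")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if ds.n_samples < 3:
        raise ValueError("SRV needs >= 3 samples for stable correlations")
    r = correlation_landscape(ds.intensities)
    good = r >= corr_threshold
    clusters: list[SrvCluster] = []
    j = 0
    while j < len(good):
        if good[j]:
            start = j
            while j < len(good) and good[j]:
                j += 1
            end = j  # run over r[start..j-1] couples columns start..j
            if end - start + 1 >= min_size:
                clusters.append(
                    SrvCluster(start, end, float(ds.ppm[start]), float(ds.ppm[end]))
                )
        else:
            j += 1
    if singlet_window > 0:
        covered = np.zeros(ds.n_points, dtype=bool)
        for c in clusters:
            covered[c.start : c.end + 1] = True
        mean_spec = ds.intensities.mean(axis=0)
        for j in range(ds.n_points):
            if covered[j]:
                continue
            lo = max(0, j - singlet_window)
            hi = min(ds.n_points, j + singlet_window + 1)
            if mean_spec[j] == mean_spec[lo:hi].max() and mean_spec[j] > 0:
                clusters.append(SrvCluster(j, j, float(ds.ppm[j]), float(ds.ppm[j])))
                covered[j] = True
        clusters.sort(key=lambda c: c.start)
    return clusters


def cluster_intensities(
    ds: SpectralDataset, clusters: list[SrvCluster], mode: str = "mean"
) -> FeatureTable:
    """Per-sample cluster representative: mean (default) or sum of columns."""
    if not clusters:
        raise ValueError("empty cluster list")
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    cols = []
    for c in clusters:
        if not 0 <= c.start <= c.end < ds.n_points:
            raise ValueError(f"cluster {c} out of range for dataset")
        block = ds.intensities[:, c.start : c.end + 1]
        cols.append(block.mean(axis=1) if mode == "mean" else block.sum(axis=1))
    return FeatureTable(
        np.column_stack(cols), list(clusters), list(ds.sample_ids), {"mode": mode}
    )


def log_transform(ft: FeatureTable, offset: float | None = None) -> FeatureTable:
    """Variance-stabilizing log: value -> log(value + offset).

    The default offset is 1% of the positive median of the matrix and is
    recorded in the output metadata.  Raises naming the first offending
    cell if value + offset <= 0.
    """
    vals = ft.values
    if offset is None:
        pos = vals[vals > 0]
        if pos.size == 0:
            raise ValueError("no positive values; supply an explicit offset")
        offset = 0.01 * float(np.median(pos))
    shifted = vals + offset
    if np.any(shifted <= 0):
        i, j = map(int, np.argwhere(shifted <= 0)[0])
        raise ValueError(
            f"value + offset <= 0 at sample {ft.sample_ids[i]!r}, "
            f"cluster {ft.clusters[j].header!r}"
        )
    meta = dict(ft.meta)
    meta["log_offset"] = float(offset)
    return FeatureTable(np.log(shifted), list(ft.clusters), list(ft.sample_ids), meta)


def annotate_clusters(
    clusters: list[SrvCluster], library: list[MetaboliteSpec]
) -> list[SrvCluster]:
    """Label each cluster with the library metabolite owning a peak center
    inside the cluster's ppm span (nearest center to the span midpoint
    wins; ties break lexicographically by name); else ``unassigned``."""
    if not library:
        raise ValueError("library is empty")
    out = []
    for c in clusters:
        lo, hi = min(c.ppm_lo, c.ppm_hi), max(c.ppm_lo, c.ppm_hi)
        mid = 0.5 * (lo + hi)
        best: tuple[float, str] | None = None
        for m in library:
            for center, _, _ in m.peaks:
                if lo <= center <= hi:
                    cand = (abs(center - mid), m.name)
                    if best is None or cand < best:
                        best = cand
        label = best[1] if best is not None else "unassigned"
        out.append(SrvCluster(c.start, c.end, c.ppm_lo, c.ppm_hi, label))
    return out
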