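"""Spectral preprocessing: reference selection, RSPA alignment, region
exclusion, and probabilistic quotient normalization (PQN).

Recursive segment-wise peak alignment is specified operationally here: for
each sample, segments are aligned to the reference spectrum by exhaustive
integer-shift search maximizing Pearson correlation, then recursively
bisected at the reference's interior intensity minimum until segments fall
below ``min_segment`` points.  Shifted segments are edge-padded with the
segment-edge value.  A sample is reverted if the procedure would lower its
full-spectrum correlation to the reference, so alignment can never make the
dataset worse.

PQN estimates each sample's dilution as the median intensity quotient
against a reference spectrum (the column-wise median spectrum by default)
and divides the sample by it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import SpectralDataset

__all__ = [
    "AlignmentResult",
    "select_reference",
    "rspa_align",
    "exclude_regions",
    "pqn_normalize",
    "pqn_normalize_matrix",
]


@dataclass
class AlignmentResult:
    aligned: SpectralDataset
    shifts: list  # (sample_id, start, stop, shift) for every applied shift
    reference_id: str


def select_reference(ds: SpectralDataset) -> str:
    """Sample with the highest mean Pearson correlation to all others.

    All-constant spectra are excluded from candidacy; ties break by
    lexicographic sample id.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples to select a reference")
    X = ds.intensities
    sd = X.std(axis=1)
    ok = sd > 0
    if not ok.any():
        raise ValueError("all spectra are constant; no reference can be chosen")
    idx = np.flatnonzero(ok)
    C = np.corrcoef(X[idx])
    if C.ndim == 0:  # single candidate
        return ds.sample_ids[idx[0]]
    mean_corr = (C.sum(axis=1) - 1.0) / max(len(idx) - 1, 1)
    order = sorted(
        range(len(idx)), key=lambda i: (-mean_corr[i], ds.sample_ids[idx[i]])
    )
    return ds.sample_ids[idx[order[0]]]


def _shift_segment(seg: np.ndarray, s: int) -> np.ndarray:
    if s == 0:
        return seg
    out = np.empty_like(seg)
    if s > 0:
        out[s:] = seg[:-s]
        out[:s] = seg[0]
    else:
        out[:s] = seg[-s:]
        out[s:] = seg[-1]
    return out


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))


def _best_shift(seg: np.ndarray, ref_seg: np.ndarray, max_shift: int) -> tuple[int, float, float]:
    """Exhaustive integer-shift search; returns (shift, best corr, corr at 0).

    All candidate shifts are evaluated at once on an edge-padded sliding
    window; ties prefer the smallest |shift|.
    """
    L, S = seg.size, max_shift
    padded = np.concatenate([np.full(S, seg[0]), seg, np.full(S, seg[-1])])
    # row r = shift s = S - r
    wins = np.lib.stride_tricks.sliding_window_view(padded, L)
    wc = wins - wins.mean(axis=1, keepdims=True)
    rc = ref_seg - ref_seg.mean()
    denom = np.sqrt((wc**2).sum(axis=1) * (rc @ rc))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, wc @ rc / np.maximum(denom, 1e-300), 0.0)
    base = float(corr[S])
    best = corr.max()
    cand = np.flatnonzero(corr >= best)
    shifts = S - cand
    best_s = int(shifts[np.argmin(np.abs(shifts))])
    return best_s, float(best), base


def _align_recursive(row, ref, lo, hi, max_shift, min_segment, gain_thr, shifts, sid):
    length = hi - lo
    if length < min_segment:
        return
    ms = min(max_shift, length - 1)
    seg, ref_seg = row[lo:hi], ref[lo:hi]
    s, best, base = _best_shift(seg, ref_seg, ms)
    if s != 0 and best - base > gain_thr:
        row[lo:hi] = _shift_segment(seg, s)
        shifts.append((sid, lo, hi, s))
    if length >= 2 * min_segment:
        interior = ref[lo + min_segment // 2 : hi - min_segment // 2]
        split = lo + min_segment // 2 + int(np.argmin(interior))
        _align_recursive(row, ref, lo, split, max_shift, min_segment, gain_thr, shifts, sid)
        _align_recursive(row, ref, split, hi, max_shift, min_segment, gain_thr, shifts, sid)


def rspa_align(
    ds: SpectralDataset,
    reference_id: str | None = None,
    max_shift: int = 20,
    min_segment: int = 32,
    corr_gain_threshold: float = 0.0,
) -> AlignmentResult:
    """Recursive segment-wise peak alignment to a reference sample.

    The reference is returned unshifted; every applied (sample, segment,
    shift) is recorded.  Raises if ``max_shift`` is not smaller than the
    spectrum length or ``min_segment`` < 8.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if min_segment < 8:
        raise ValueError("min_segment must be >= 8 points")
    if max_shift >= ds.n_points:
        raise ValueError("max_shift must be smaller than the spectrum length")
    ref_id = reference_id or select_reference(ds)
    if ref_id not in ds.sample_ids:
        raise ValueError(f"reference sample {ref_id!r} not in dataset")
    ref = ds.row(ref_id).copy()
    out = ds.intensities.copy()
    shifts: list = []
    for i, sid in enumerate(ds.sample_ids):
        if sid == ref_id or max_shift == 0:
            continue
        row = out[i].copy()
        before = _corr(row, ref)
        applied: list = []
        _align_recursive(
            row, ref, 0, ds.n_points, max_shift, min_segment,
            corr_gain_threshold, applied, sid,
        )
        if _corr(row, ref) >= before:
            out[i] = row
            shifts.extend(applied)
    aligned = SpectralDataset(ds.ppm.copy(), out, list(ds.sample_ids), ds.metadata)
    return AlignmentResult(aligned, shifts, ref_id)


def exclude_regions(
    ds: SpectralDataset, regions: list[tuple[float, float]]
) -> SpectralDataset:
    """Drop ppm columns inside any half-open [lo, hi) region.

    Overlapping regions are unioned; removing every column is an error.
    """
    if not regions:
        return ds.copy()
    keep = np.ones(ds.n_points, dtype=bool)
    for lo, hi in regions:
        if lo > hi:
            lo, hi = hi, lo
        keep &= ~((ds.ppm >= lo) & (ds.ppm < hi))
    if not keep.any():
        raise ValueError("exclusion regions remove every column")
    return SpectralDataset(
        ds.ppm[keep], ds.intensities[:, keep], list(ds.sample_ids), ds.metadata
    )


def pqn_normalize_matrix(
    X: np.ndarray,
    reference: np.ndarray | str = "median",
    floor: float = 0.0,
    sample_ids: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilistic quotient normalization of a samples x variables matrix.

    Negative intensities are floored at 0 first.  The reference is the
    column-wise median spectrum unless an explicit vector is given.
    Quotients are taken over columns where the reference exceeds ``floor``;
    each sample is divided by its median quotient (the dilution estimate).
    Returns (normalized matrix, dilution estimates).
    """
    X = np.maximum(np.atleast_2d(np.asarray(X, dtype=float)), 0.0)
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    if isinstance(reference, str):
        if reference != "median":
            raise ValueError("reference must be 'median' or an explicit vector")
        ref = np.median(X, axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (X.shape[1],):
            raise ValueError("explicit reference length must match column count")
    usable = ref > floor
    if not usable.any():
        raise ValueError("reference has no entries above the floor")
    dil = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        quot = X[i, usable] / ref[usable]
        pos = quot > 0
        if not pos.any():
            sid = sample_ids[i] if sample_ids else f"row {i}"
            raise ValueError(f"sample {sid!r} has all-zero overlap with the reference")
        dil[i] = np.median(quot[pos])
    return X / dil[:, None], dil


def pqn_normalize(
    ds: SpectralDataset,
    reference: np.ndarray | str = "median",
    floor: float = 0.0,
) -> tuple[SpectralDataset, pd.Series]:
    """PQN on a :class:`SpectralDataset`; see :func:`pqn_normalize_matrix`."""
    norm, dil = pqn_normalize_matrix(
        ds.intensities, reference, floor, sample_ids=ds.sample_ids
    )
    out = SpectralDataset(ds.ppm.copy(), norm, list(ds.sample_ids), ds.metadata)
    return out, pd.Series(dil, index=ds.sample_ids, name="dilution")
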