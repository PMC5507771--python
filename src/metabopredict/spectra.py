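"""Spectral data container and delimited-text I/O.

A :class:`SpectralDataset` holds a shared strictly monotone ppm axis, one
intensity row per sample, unique sample identifiers, and optional per-sample
metadata (animal, timepoint, diet).  The on-disk format is plain delimited
text: the first row is the ppm axis (first cell ``ppm``), each following row
is a sample id followed by its intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpectralDataset"]


@dataclass
class SpectralDataset:
    ppm: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.ppm.ndim != 1:
            raise ValueError("ppm axis must be one-dimensional")
        d = np.diff(self.ppm)
        if self.ppm.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if self.intensities.shape != (len(self.sample_ids), self.ppm.size):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.ppm.size} ppm points"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.metadata is not None:
            missing = set(self.sample_ids) - set(map(str, self.metadata.index))
            if missing:
                raise ValueError(f"metadata missing sample ids: {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_points(self) -> int:
        return self.ppm.size

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            self.ppm.copy(),
            self.intensities.copy(),
            list(self.sample_ids),
            None if self.metadata is None else self.metadata.copy(),
        )

    def row(self, sample_id: str) -> np.ndarray:
        return self.intensities[self.sample_ids.index(sample_id)]

    def subset_samples(self, ids: list[str]) -> "SpectralDataset":
        idx = [self.sample_ids.index(str(i)) for i in ids]
        meta = None
        if self.metadata is not None:
            meta = self.metadata.loc[[str(i) for i in ids]]
        return SpectralDataset(self.ppm, self.intensities[idx], list(ids), meta)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.sample_ids, columns=self.ppm)

    # ---- delimited-text round trip -------------------------------------
    def write(self, path, sep: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(sep.join(["ppm"] + [repr(float(v)) for v in self.ppm]) + "\n")
            for sid, row in zip(self.sample_ids, self.intensities):
                fh.write(sep.join([sid] + [repr(float(v)) for v in row]) + "\n")

    @classmethod
    def read(cls, path, sep: str = "\t") -> "SpectralDataset":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
            if header[0] != "ppm":
                raise ValueError(f"{path}: first cell must be 'ppm'")
            ppm = np.array([float(v) for v in header[1:]])
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(sep)
                if len(parts) < 2:
                    continue
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(ppm, np.array(rows), ids)
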