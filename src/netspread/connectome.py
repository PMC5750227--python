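"""Parcel-level connectivity matrices and their I/O.

Three modalities are handled: ``functional`` (resting-state correlation,
values in [-1, 1] with unit diagonal), ``structural`` (non-negative
tractography-derived connection weights), and ``distance`` (pairwise
Euclidean centroid distance in mm, used as a geometric comparator for the
propagation model).  All matrices are square, symmetric and indexed by
parcel_id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .atlas import ParcelAtlas

MODALITIES = ("functional", "structural", "distance")
SYMMETRY_TOL = 1e-8


@dataclass(frozen=True)
class Connectome:
    """Square parcel x parcel weight matrix tagged by modality."""

    weights: np.ndarray
    parcel_ids: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        object.__setattr__(self, "parcel_ids", np.asarray(self.parcel_ids, int))
        self.validate()

    def validate(self) -> None:
        w = self.weights
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectome matrix must be square, got {w.shape}")
        if len(self.parcel_ids) != w.shape[0]:
            raise ValueError("parcel_ids length does not match matrix size")
        if len(np.unique(self.parcel_ids)) != len(self.parcel_ids):
            raise ValueError("duplicate parcel_ids in connectome")
        nan = np.argwhere(~np.isfinite(w))
        if len(nan):
            i, j = nan[0]
            raise ValueError(
                "non-finite weight at parcels "
                f"({self.parcel_ids[i]}, {self.parcel_ids[j]})"
            )
        asym = np.max(np.abs(w - w.T)) if w.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"connectome asymmetric beyond tolerance (max |w-w.T| = {asym:.3g})"
            )
        if self.modality == "functional":
            if w.size and (w.min() < -1 - 1e-12 or w.max() > 1 + 1e-12):
                raise ValueError("functional weights must lie in [-1, 1]")
            if w.size and np.max(np.abs(np.diag(w) - 1.0)) > 1e-9:
                raise ValueError("functional connectome must have unit diagonal")
        elif self.modality == "structural":
            if w.size and w.min() < 0:
                raise ValueError("structural weights must be non-negative")
        elif self.modality == "distance":
            if w.size and w.min() < 0:
                raise ValueError("distances must be non-negative")
            if w.size and np.max(np.abs(np.diag(w))) > 1e-9:
                raise ValueError("distance matrix must have zero diagonal")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def index_of(self, parcel_ids) -> np.ndarray:
        """Row/column positions of the given parcel_ids."""
        lookup = pd.Series(np.arange(self.n), index=self.parcel_ids)
        missing = sorted(set(np.atleast_1d(parcel_ids)) - set(self.parcel_ids))
        if missing:
            raise KeyError(f"parcel_ids not in connectome: {missing[:5]}")
        return lookup.loc[np.atleast_1d(parcel_ids)].to_numpy()

    def block(self, row_ids, col_ids) -> np.ndarray:
        """Weight sub-block for the given row/column parcel_ids."""
        ri = self.index_of(row_ids)
        ci = self.index_of(col_ids)
        return self.weights[np.ix_(ri, ci)]


def functional_from_timeseries(
    series: np.ndarray, parcel_ids: np.ndarray
) -> Connectome:
    """Pairwise Pearson correlation of parcel time series.

    ``series`` is parcels x time with at least 3 time points; a constant
    series has no defined correlation and raises an error naming the parcel.
    """
    series = np.asarray(series, float)
    parcel_ids = np.asarray(parcel_ids, int)
    if series.ndim != 2 or series.shape[1] < 3:
        raise ValueError("time series must be parcels x time with >= 3 time points")
    sd = series.std(axis=1)
    flat = np.where(sd == 0)[0]
    if len(flat):
        raise ValueError(f"constant time series for parcel {parcel_ids[flat[0]]}")
    w = np.corrcoef(series)
    # clamp numerical overshoot and force exact symmetry/unit diagonal
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return Connectome(w, parcel_ids, "functional")


def distance_connectome(atlas: ParcelAtlas) -> Connectome:
    """Pairwise Euclidean distance (mm) between all parcel centroids."""
    cent = atlas.centroids()
    d = squareform(pdist(cent))
    return Connectome(d, atlas.parcel_ids, "distance")


def write_connectome(conn: Connectome, path) -> None:
    """Write as delimited text with parcel_ids as header row and first column."""
    df = pd.DataFrame(conn.weights, index=conn.parcel_ids, columns=conn.parcel_ids)
    df.index.name = "parcel_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_connectome(path, modality: str, atlas: ParcelAtlas | None = None) -> Connectome:
    """Read a delimited square matrix with parcel_id header row/column.

    Validates modality invariants; when ``atlas`` is given the stored ids
    must exactly match the atlas parcel set.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    row_ids = df.index.to_numpy(int)
    col_ids = df.columns.to_numpy(int)
    if not np.array_equal(row_ids, col_ids):
        raise ValueError(f"{path}: row and column parcel_ids differ")
    if atlas is not None and not np.array_equal(
        np.sort(row_ids), np.sort(atlas.parcel_ids)
    ):
        raise ValueError(f"{path}: parcel_ids do not match the atlas")
    w = df.to_numpy(float)
    nan = np.argwhere(np.isnan(w))
    if len(nan):
        i, j = nan[0]
        raise ValueError(f"{path}: NaN entry at parcels ({row_ids[i]}, {col_ids[j]})")
    return Connectome(w, row_ids, modality)
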