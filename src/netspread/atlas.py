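"""Brain parcellation model: parcels, vertex surfaces, and vertex->parcel mapping.

The analyses in this package operate on a whole-brain parcellation of
cortical and subcortical grey matter (by default 448 cortical and 15
subcortical parcels across the two hemispheres).  Cortical-thickness data
live on a triangulated surface mesh; every surface vertex is assigned to its
nearest cortical parcel centroid so that vertex-wise statistics can be
summarised at the parcel level and related to parcel-wise connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial.distance import cdist

HEMISPHERES = ("L", "R", "M")
TISSUES = ("cortical", "subcortical")

#: The seven canonical intrinsic (resting-state) cortical networks.
NETWORKS_7 = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)

ATLAS_COLUMNS = ["parcel_id", "hemisphere", "tissue", "x", "y", "z", "network"]


@dataclass(frozen=True)
class ParcelAtlas:
    """Table of brain parcels with hemisphere, tissue class and centroid.

    ``table`` columns: ``parcel_id`` (int, unique, contiguous from 1),
    ``hemisphere`` (L/R/M), ``tissue`` (cortical/subcortical), ``x,y,z``
    (centroid, mm), ``network`` (one of :data:`NETWORKS_7` or missing) and an
    optional ``name`` column used to identify named subcortical structures
    (e.g. ``caudate_L``) for reservoir subsetting.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        t = self.table
        missing = [c for c in ATLAS_COLUMNS if c not in t.columns and c != "network"]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        ids = t["parcel_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("parcel_ids are not unique")
        if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
            raise ValueError("parcel_ids must be contiguous integers starting at 1")
        bad_hemi = set(t["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        bad_tissue = set(t["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValueError(f"unknown tissue labels: {sorted(bad_tissue)}")
        cort = t[t["tissue"] == "cortical"]
        if (cort["hemisphere"] == "M").any():
            raise ValueError("cortical parcels must have hemisphere L or R")
        xyz = t[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("parcel centroids must be finite")
        if "network" in t.columns:
            labelled = t["network"].dropna()
            bad = set(labelled) - set(NETWORKS_7)
            if bad:
                raise ValueError(f"unknown network labels: {sorted(bad)}")
            sub = t[t["tissue"] == "subcortical"]
            if sub["network"].notna().any():
                raise ValueError("subcortical parcels must not carry network labels")

    # -- accessors -------------------------------------------------------
    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def cortical(self) -> pd.DataFrame:
        return self.table[self.table["tissue"] == "cortical"]

    @property
    def subcortical(self) -> pd.DataFrame:
        return self.table[self.table["tissue"] == "subcortical"]

    @property
    def parcel_ids(self) -> np.ndarray:
        return self.table["parcel_id"].to_numpy()

    def centroids(self, parcel_ids: np.ndarray | None = None) -> np.ndarray:
        t = self.table.set_index("parcel_id")
        if parcel_ids is None:
            parcel_ids = self.parcel_ids
        return t.loc[parcel_ids, ["x", "y", "z"]].to_numpy(float)

    def hemisphere_of(self) -> pd.Series:
        """parcel_id -> hemisphere label."""
        return self.table.set_index("parcel_id")["hemisphere"]

    # -- I/O -------------------------------------------------------------
    @classmethod
    def read_table(cls, path) -> "ParcelAtlas":
        t = pd.read_csv(path)
        if "network" not in t.columns:
            t["network"] = pd.NA
        return cls(t)

    def write_table(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class VertexSurface:
    """Surface vertices (positions, hemisphere) with triangulation-style adjacency.

    ``vertices`` columns: ``vertex_id`` (int, unique), ``x,y,z`` (mm),
    ``hemisphere`` (L or R).  ``edges`` is an (E, 2) integer array of
    undirected vertex_id pairs; edges never cross hemispheres.
    """

    vertices: pd.DataFrame
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.vertices
        for col in ("vertex_id", "x", "y", "z", "hemisphere"):
            if col not in v.columns:
                raise ValueError(f"surface vertex table missing column {col!r}")
        if v["vertex_id"].duplicated().any():
            raise ValueError("vertex_ids are not unique")
        if not np.all(np.isfinite(v[["x", "y", "z"]].to_numpy(float))):
            raise ValueError("vertex positions must be finite")
        bad = set(v["hemisphere"]) - {"L", "R"}
        if bad:
            raise ValueError(f"unknown vertex hemisphere labels: {sorted(bad)}")
        e = np.asarray(self.edges)
        if e.size:
            hemi = v.set_index("vertex_id")["hemisphere"]
            ha = hemi.loc[e[:, 0]].to_numpy()
            hb = hemi.loc[e[:, 1]].to_numpy()
            if (ha != hb).any():
                raise ValueError("surface edges must not cross hemispheres")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def vertex_ids(self) -> np.ndarray:
        return self.vertices["vertex_id"].to_numpy()

    def positions(self) -> np.ndarray:
        return self.vertices[["x", "y", "z"]].to_numpy(float)

    def adjacency_matrix(self) -> sparse.csr_matrix:
        """Symmetric vertex adjacency in the row order of ``vertices``."""
        idx = pd.Series(np.arange(self.n_vertices), index=self.vertex_ids)
        e = np.asarray(self.edges)
        if e.size == 0:
            return sparse.csr_matrix((self.n_vertices, self.n_vertices))
        i = idx.loc[e[:, 0]].to_numpy()
        j = idx.loc[e[:, 1]].to_numpy()
        data = np.ones(len(i))
        a = sparse.coo_matrix((data, (i, j)), shape=(self.n_vertices, self.n_vertices))
        a = a + a.T
        a.data[:] = 1.0
        return a.tocsr()

    @classmethod
    def read_tables(cls, vertex_path, edge_path) -> "VertexSurface":
        v = pd.read_csv(vertex_path)
        e = pd.read_csv(edge_path).to_numpy(int)
        return cls(v, e)

    def write_tables(self, vertex_path, edge_path) -> None:
        self.vertices.to_csv(vertex_path, index=False)
        pd.DataFrame(self.edges, columns=["vertex_a", "vertex_b"]).to_csv(
            edge_path, index=False
        )


def map_vertices_to_parcels(surface: VertexSurface, atlas: ParcelAtlas) -> pd.Series:
    """Assign every surface vertex to its nearest cortical parcel centroid.

    Distances are Euclidean (mm) and restricted to the vertex's own
    hemisphere; exact ties are broken toward the lower ``parcel_id``, making
    the mapping deterministic and independent of vertex order.

    Returns a Series indexed by ``vertex_id`` with parcel_id values.
    """
    out = pd.Series(index=surface.vertex_ids, dtype=int, name="parcel_id")
    out.index.name = "vertex_id"
    for hemi in ("L", "R"):
        vmask = surface.vertices["hemisphere"] == hemi
        if not vmask.any():
            continue
        parcels = atlas.cortical[atlas.cortical["hemisphere"] == hemi]
        if parcels.empty:
            raise ValueError(
                f"hemisphere {hemi!r} has vertices but no cortical parcels"
            )
        # sort ascending by id so argmin's first-occurrence rule = lowest id
        parcels = parcels.sort_values("parcel_id")
        cent = parcels[["x", "y", "z"]].to_numpy(float)
        pos = surface.vertices.loc[vmask, ["x", "y", "z"]].to_numpy(float)
        d = cdist(pos, cent)
        nearest = parcels["parcel_id"].to_numpy()[np.argmin(d, axis=1)]
        out.loc[surface.vertices.loc[vmask, "vertex_id"].to_numpy()] = nearest
    return out


def aggregate_to_parcels(
    vertex_parcel_map: pd.Series,
    vertex_values: pd.Series,
    atlas: ParcelAtlas | None = None,
) -> pd.Series:
    """Per-parcel unweighted mean of member-vertex values.

    Every vertex in the map must carry a finite value.  When ``atlas`` is
    given, cortical parcels with no member vertices appear with NaN so the
    result always covers the full cortical parcel set.
    """
    vals = vertex_values.reindex(vertex_parcel_map.index)
    bad = vals.index[~np.isfinite(vals.to_numpy(float))]
    if len(bad):
        raise ValueError(f"non-finite vertex value at vertex_id {bad[0]}")
    means = vals.groupby(vertex_parcel_map).mean()
    means.index.name = "parcel_id"
    means.name = "value"
    if atlas is not None:
        means = means.reindex(atlas.cortical["parcel_id"].to_numpy())
        means.index.name = "parcel_id"
    return means


def assign_networks(atlas: ParcelAtlas, labels: pd.Series | dict) -> ParcelAtlas:
    """Attach one of the seven intrinsic-network labels to every cortical parcel.

    ``labels`` maps parcel_id -> network name and must cover all cortical
    parcels with labels from :data:`NETWORKS_7`; subcortical parcels must not
    appear and remain unlabelled.
    """
    labels = pd.Series(labels)
    bad = set(labels) - set(NETWORKS_7)
    if bad:
        raise ValueError(f"unknown network labels: {sorted(bad)}")
    sub_ids = set(atlas.subcortical["parcel_id"])
    on_sub = sorted(sub_ids & set(labels.index))
    if on_sub:
        raise ValueError(f"network label supplied for subcortical parcel {on_sub[0]}")
    cort_ids = atlas.cortical["parcel_id"]
    missing = sorted(set(cort_ids) - set(labels.index))
    if missing:
        raise ValueError(
            f"{len(missing)} cortical parcels lack a network label (first: {missing[0]})"
        )
    t = atlas.table.copy()
    t["network"] = t["parcel_id"].map(labels)
    t.loc[t["tissue"] == "subcortical", "network"] = pd.NA
    return ParcelAtlas(t)
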