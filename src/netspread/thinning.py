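"""Longitudinal cortical-thinning statistics on the vertex surface.

The core contrast is the group difference in one-year thickness change,
Δt = t1 − t2 (positive = thinning), estimated vertex-wise by ordinary least
squares of Δt on a PD-group indicator plus covariates (acquisition site,
age, sex).  Supra-threshold clusters are corrected by permuting group labels
within site strata and comparing observed cluster extents with the null
distribution of the maximum cluster size.  Network summaries average the
vertex t-statistics within the seven intrinsic cortical networks, with a
label-permutation p-value and a percentile bootstrap CI over vertices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .atlas import NETWORKS_7, ParcelAtlas, VertexSurface

GROUPS = ("PD", "HC")
PANEL_COLUMNS = [
    "subject", "group", "site", "age", "sex", "timepoint", "vertex_id",
    "thickness_mm",
]


@dataclass(frozen=True)
class ThicknessPanel:
    """Two-timepoint vertex thickness with subject covariates.

    ``subjects``: one row per subject with columns subject, group (PD/HC),
    site, age, sex.  ``t1``/``t2``: (n_subjects, n_vertices) thickness in mm,
    rows aligned with ``subjects`` and columns with ``vertex_ids``.
    """

    subjects: pd.DataFrame
    vertex_ids: np.ndarray
    t1: np.ndarray
    t2: np.ndarray

    def __post_init__(self) -> None:
        n, v = len(self.subjects), len(self.vertex_ids)
        for name, arr in (("t1", self.t1), ("t2", self.t2)):
            if arr.shape != (n, v):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, v)}")
        bad = set(self.subjects["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.t1 <= 0).any() or (self.t2 <= 0).any():
            raise ValueError("thickness values must be positive")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def delta(self) -> np.ndarray:
        """Thinning Δt = t1 − t2 (positive = cortex got thinner)."""
        return self.t1 - self.t2

    def group_mask(self, group: str) -> np.ndarray:
        return (self.subjects["group"] == group).to_numpy()

    # -- long-format I/O --------------------------------------------------
    def to_long_table(self) -> pd.DataFrame:
        frames = []
        for tp, arr in (("t1", self.t1), ("t2", self.t2)):
            df = pd.DataFrame(arr, columns=self.vertex_ids)
            df = pd.concat([self.subjects.reset_index(drop=True), df], axis=1)
            long = df.melt(
                id_vars=["subject", "group", "site", "age", "sex"],
                var_name="vertex_id", value_name="thickness_mm",
            )
            long.insert(5, "timepoint", tp)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)[PANEL_COLUMNS]

    @classmethod
    def from_long_table(cls, table: pd.DataFrame) -> "ThicknessPanel":
        missing = [c for c in PANEL_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        subjects = (
            table[["subject", "group", "site", "age", "sex"]]
            .drop_duplicates("subject")
            .reset_index(drop=True)
        )
        wide = {}
        for tp in ("t1", "t2"):
            sub = table[table["timepoint"] == tp]
            wide[tp] = sub.pivot(
                index="subject", columns="vertex_id", values="thickness_mm"
            )
        v1, v2 = wide["t1"], wide["t2"]
        if not v1.columns.equals(v2.columns) or not v1.index.equals(v2.index):
            raise ValueError("both timepoints must cover the same subjects and vertices")
        if v1.isna().any().any() or v2.isna().any().any():
            raise ValueError("panel has missing thickness values")
        order = subjects["subject"].to_numpy()
        return cls(
            subjects,
            v1.columns.to_numpy(),
            v1.loc[order].to_numpy(float),
            v2.loc[order].to_numpy(float),
        )

    @classmethod
    def read_table(cls, path) -> "ThicknessPanel":
        return cls.from_long_table(pd.read_csv(path))

    def write_table(self, path) -> None:
        self.to_long_table().to_csv(path, index=False)


@dataclass(frozen=True)
class ThinningMap:
    """Per-vertex group-contrast statistics for the thinning model."""

    tvalues: pd.Series   # vertex_id -> t (positive = more thinning in PD)
    effect: pd.Series    # vertex_id -> group coefficient, mm
    df: int
    covariates: tuple

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("model degrees of freedom must be positive")
        if not np.all(np.isfinite(self.tvalues.to_numpy())):
            raise ValueError("non-finite t-statistics in thinning map")


@dataclass(frozen=True)
class ClusterTable:
    """Supra-threshold clusters: extent, peak, and optional permutation p."""

    table: pd.DataFrame  # cluster_id, nverts, peak_vertex, peak_t, p_perm
    vertices: dict       # cluster_id -> tuple of vertex_ids
    t_threshold: float

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class WholeBrainChange:
    mean_t1: float
    mean_t2: float
    t: float
    p: float
    df: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Design matrix and vectorised vertex-wise OLS
# ---------------------------------------------------------------------------

def _design_matrix(subjects: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(subjects))}
    cols["group_PD"] = (subjects["group"] == "PD").to_numpy(float)
    for cov in covariates:
        if cov not in subjects.columns:
            raise ValueError(f"covariate {cov!r} not present in panel")
        col = subjects[cov]
        if cov == "site" or col.dtype == object:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols[name] = dummies[name].to_numpy(float)
        else:
            cols[cov] = col.to_numpy(float)
    X = pd.DataFrame(cols, index=subjects.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the culprits: columns whose removal restores full rank
        bad = []
        arr = X.to_numpy()
        for j, name in enumerate(X.columns):
            rest = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                bad.append(name)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X


def _vertexwise_group_t(X: np.ndarray, Y: np.ndarray, gidx: int):
    """OLS of every column of Y on X; return (beta_g, t_g, df)."""
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError("not enough subjects for the model")
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ (X.T @ Y)
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[gidx, gidx], 1e-300))
    return B[gidx], B[gidx] / se, df


def longitudinal_contrast(
    panel: ThicknessPanel, covariates=("site", "age", "sex")
) -> ThinningMap:
    """Vertex-wise group difference in thinning, [(PD1−PD2) − (HC1−HC2)].

    Fits Δt = β0 + βg·[group==PD] + covariates by OLS at every vertex and
    returns the group-coefficient t-statistic (positive = more thinning in
    PD) and the coefficient itself in mm.
    """
    for g in GROUPS:
        if panel.group_mask(g).sum() < 2:
            raise ValueError(f"need at least 2 subjects in group {g}")
    X = _design_matrix(panel.subjects, covariates)
    gidx = list(X.columns).index("group_PD")
    beta, t, df = _vertexwise_group_t(X.to_numpy(), panel.delta(), gidx)
    return ThinningMap(
        tvalues=pd.Series(t, index=panel.vertex_ids, name="t"),
        effect=pd.Series(beta, index=panel.vertex_ids, name="effect_mm"),
        df=df,
        covariates=tuple(covariates),
    )


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------

def _components(adj: sparse.csr_matrix, mask: np.ndarray):
    """Connected components of the masked vertex subgraph (row indices)."""
    idx = np.where(mask)[0]
    if len(idx) == 0:
        return []
    sub = adj[idx][:, idx]
    n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)
    return [idx[labels == k] for k in range(n_comp)]


def find_clusters(
    tmap: ThinningMap, surface: VertexSurface, t_threshold: float
) -> ClusterTable:
    """Connected components of vertices with t >= threshold.

    Clusters are ordered by decreasing extent; an empty table is a valid
    result when nothing survives the threshold.
    """
    if t_threshold <= 0:
        raise ValueError("t_threshold must be positive")
    t = tmap.tvalues.reindex(surface.vertex_ids).to_numpy(float)
    adj = surface.adjacency_matrix()
    comps = _components(adj, t >= t_threshold)
    comps.sort(key=len, reverse=True)
    rows, verts = [], {}
    vids = surface.vertex_ids
    for k, comp in enumerate(comps, start=1):
        peak = comp[np.argmax(t[comp])]
        rows.append(
            dict(cluster_id=k, nverts=len(comp), peak_vertex=int(vids[peak]),
                 peak_t=float(t[peak]), p_perm=np.nan)
        )
        verts[k] = tuple(int(v) for v in vids[comp])
    table = pd.DataFrame(
        rows, columns=["cluster_id", "nverts", "peak_vertex", "peak_t", "p_perm"]
    )
    return ClusterTable(table, verts, t_threshold)


def _permute_groups_within_sites(subjects: pd.DataFrame, rng) -> np.ndarray:
    """Group labels shuffled within site strata; one-group strata left fixed."""
    groups = subjects["group"].to_numpy().copy()
    for site in subjects["site"].unique():
        idx = np.where(subjects["site"].to_numpy() == site)[0]
        if len(set(groups[idx])) < 2:
            continue
        groups[idx] = groups[idx][rng.permutation(len(idx))]
    return groups


def cluster_correction_permutation(
    panel: ThicknessPanel,
    surface: VertexSurface,
    covariates=("site", "age", "sex"),
    t_threshold: float = 2.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterTable:
    """Cluster-extent correction by permuting group labels within sites.

    The null distribution is the maximum supra-threshold cluster size under
    group-label permutation (stratified by site so site effects survive the
    shuffle); each observed cluster gets p = (1 + #{null max >= size}) /
    (n_perm + 1).  Site strata containing only one group cannot be permuted
    and are left fixed, with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    one_group = [
        s for s in panel.subjects["site"].unique()
        if panel.subjects.loc[panel.subjects["site"] == s, "group"].nunique() < 2
    ]
    if one_group:
        warnings.warn(
            f"site strata with a single group are excluded from permutation: {one_group}",
            stacklevel=2,
        )
    observed = find_clusters(
        longitudinal_contrast(panel, covariates), surface, t_threshold
    )
    adj = surface.adjacency_matrix()
    Y = panel.delta()
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=int)
    subjects = panel.subjects
    for b in range(n_perm):
        perm_subjects = subjects.copy()
        perm_subjects["group"] = _permute_groups_within_sites(subjects, rng)
        X = _design_matrix(perm_subjects, covariates)
        gidx = list(X.columns).index("group_PD")
        _, t, _ = _vertexwise_group_t(X.to_numpy(), Y, gidx)
        comps = _components(adj, t >= t_threshold)
        null_max[b] = max((len(c) for c in comps), default=0)
    table = observed.table.copy()
    table["p_perm"] = [
        (1 + int(np.sum(null_max >= nv))) / (n_perm + 1) for nv in table["nverts"]
    ]
    return ClusterTable(table, observed.vertices, t_threshold)


# ---------------------------------------------------------------------------
# Whole-brain change and network summaries
# ---------------------------------------------------------------------------

def whole_brain_change(panel: ThicknessPanel, group: str) -> WholeBrainChange:
    """Paired t-test on subject-level whole-brain mean thickness, t1 vs t2."""
    mask = panel.group_mask(group)
    if mask.sum() < 2:
        raise ValueError(f"need at least 2 subjects in group {group}")
    m1 = panel.t1[mask].mean(axis=1)
    m2 = panel.t2[mask].mean(axis=1)
    diff = m1 - m2
    df = len(diff) - 1
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return WholeBrainChange(
                float(m1.mean()), float(m2.mean()), 0.0, 1.0, df
            )
        # constant nonzero change: t is undefined (zero variance)
        return WholeBrainChange(
            float(m1.mean()), float(m2.mean()), np.nan, np.nan, df, degenerate=True
        )
    t, p = stats.ttest_rel(m1, m2)
    return WholeBrainChange(float(m1.mean()), float(m2.mean()), float(t), float(p), df)


def network_summary(
    tmap: ThinningMap,
    atlas: ParcelAtlas,
    vertex_parcel_map: pd.Series,
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean vertex thinning-t per intrinsic network with inference.

    The permutation null shuffles the network labels across vertices (all
    networks share one set of label permutations); p compares |mean| against
    the null, using the add-one estimator.  The CI is a percentile bootstrap
    over vertices within the network.  Empty networks get a NaN row.
    """
    if n_perm < 1 or n_boot < 1:
        raise ValueError("n_perm and n_boot must be >= 1")
    parcel_net = atlas.table.set_index("parcel_id")["network"]
    if parcel_net.dropna().empty:
        raise ValueError("atlas has no network labels; run assign_networks first")
    vert_net = vertex_parcel_map.map(parcel_net)
    t = tmap.tvalues.reindex(vert_net.index).to_numpy(float)
    labelled = vert_net.notna().to_numpy()
    t_lab = t[labelled]
    net_lab = vert_net[labelled].to_numpy()
    rng = np.random.default_rng(seed)

    # indicator matrix (networks x labelled vertices) for fast group means
    codes = pd.Categorical(net_lab, categories=list(NETWORKS_7)).codes
    counts = np.bincount(codes, minlength=len(NETWORKS_7)).astype(float)
    rows = []
    mu_obs = np.full(len(NETWORKS_7), np.nan)
    for k in range(len(NETWORKS_7)):
        if counts[k]:
            mu_obs[k] = t_lab[codes == k].mean()

    # permutation: shuffling labels over vertices == shuffling t values
    n = len(t_lab)
    exceed = np.zeros(len(NETWORKS_7))
    chunk = max(1, min(n_perm, int(5e7 // max(n, 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = np.argsort(rng.random((m, n)), axis=1)
        tp = t_lab[perm]  # (m, n)
        sums = np.zeros((m, len(NETWORKS_7)))
        for k in range(len(NETWORKS_7)):
            if counts[k]:
                sums[:, k] = tp[:, codes == k].sum(axis=1)
        mu_perm = sums / np.where(counts == 0, np.nan, counts)
        with np.errstate(invalid="ignore"):
            exceed += np.nansum(
                np.abs(mu_perm) >= np.abs(mu_obs)[None, :] - 1e-12, axis=0
            )
        done += m

    for k, net in enumerate(NETWORKS_7):
        if counts[k] == 0:
            rows.append(dict(network=net, n_vertices=0, mu=np.nan,
                             ci_low=np.nan, ci_high=np.nan, p_perm=np.nan))
            continue
        vals = t_lab[codes == k]
        bidx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
        boots = vals[bidx].mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(dict(
            network=net, n_vertices=int(counts[k]), mu=float(mu_obs[k]),
            ci_low=float(lo), ci_high=float(hi),
            p_perm=(exceed[k] + 1) / (n_perm + 1),
        ))
    out = pd.DataFrame(rows)
    out["n_perm"] = n_perm
    return out
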