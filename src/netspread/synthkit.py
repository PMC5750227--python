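"""Synthetic atlases, connectomes, reservoir atrophy and thickness panels.

The generator embodies the propagation hypothesis itself: one-year cortical
thinning is global aging plus a PD-specific term proportional to the
connectivity-weighted disease exposure of each vertex's parcel, plus site
offsets and measurement noise.  Every downstream stage of the analysis can
therefore be exercised — and its parameter recovery checked — without any
real imaging data.

All generators are pure functions of (config, seed): the same seed yields
byte-identical outputs.

Geometry: cortical parcel centroids sit on two mirrored hemispheric shells
(radius 55-75 mm); the default 15 subcortical parcels are placed at
approximate anatomical positions (thalamus, caudate, putamen, pallidum,
accumbens, hippocampus, amygdala bilaterally, plus brainstem) so that named
reservoir subsets such as the basal ganglia are resolvable.  Synthetic
connectomes decay exponentially with centroid distance; structural matrices
are sparse with attenuated interhemispheric weights, mimicking the known
difficulty of diffusion tractography in capturing inter-hemispheric
connections.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .atlas import NETWORKS_7, ParcelAtlas, VertexSurface, map_vertices_to_parcels
from .connectome import Connectome
from .propagation import AtrophyMap, disease_exposure
from .thinning import ThicknessPanel

#: (structure, hemisphere, x, y, z) — approximate positions, mm; the list is
#: truncated when a configuration asks for fewer than 15 subcortical parcels.
SUBCORTICAL_SEATS = [
    ("thalamus", "L", -11.0, -18.0, 8.0),
    ("thalamus", "R", 11.0, -18.0, 8.0),
    ("caudate", "L", -13.0, 10.0, 10.0),
    ("caudate", "R", 13.0, 10.0, 10.0),
    ("putamen", "L", -26.0, 0.0, 0.0),
    ("putamen", "R", 26.0, 0.0, 0.0),
    ("pallidum", "L", -20.0, -4.0, -1.0),
    ("pallidum", "R", 20.0, -4.0, -1.0),
    ("accumbens", "L", -9.0, 10.0, -7.0),
    ("accumbens", "R", 9.0, 10.0, -7.0),
    ("hippocampus", "L", -28.0, -22.0, -14.0),
    ("hippocampus", "R", 28.0, -22.0, -14.0),
    ("amygdala", "L", -24.0, -4.0, -18.0),
    ("amygdala", "R", 24.0, -4.0, -18.0),
    ("brainstem", "M", 0.0, -30.0, -35.0),
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults emulate the modelled cohort: 105 PD / 57 HC subjects across 4
    acquisition sites, a 448-cortical + 15-subcortical parcellation, mean
    baseline thickness 3.055 mm, 0.019 mm/yr of normal aging thinning, and a
    spread coefficient sized so the average PD-specific extra thinning is of
    the order of the ~0.009 mm/yr excess observed between groups.
    """

    n_cortical: int = 448
    n_subcortical: int = 15
    vertices_per_parcel: int = 10
    n_pd: int = 105
    n_hc: int = 57
    baseline_mean: float = 3.055        # mm
    between_subject_sd: float = 0.10    # mm, subject-level offset
    within_subject_sd: float = 0.15     # mm, vertex-level baseline variation
    aging_thinning: float = 0.019       # mm per year, both groups
    spread_coefficient: float = 0.003   # b, mm of extra thinning per unit exposure
    noise_sd: float = 0.03              # mm, measurement noise on follow-up
    n_sites: int = 4
    site_sd: float = 0.02               # mm, additive site offsets on follow-up
    interhemi_attenuation: float = 0.2  # structural cross-hemisphere scaling
    distance_decay: float = 25.0        # lambda, mm
    conn_gain_sd: float = 0.6           # log-sd of pairwise functional gains
    conn_hub_sd: float = 0.5            # log-sd of per-node strength factors
    homotopic_factor: float = 0.8       # functional cross-hemisphere strength
    conn_noise_sd: float = 0.01         # additive functional connectome noise
    atrophy_mean: float = 2.5           # reservoir z-value location
    atrophy_sd: float = 0.8
    vertex_jitter: float = 3.0          # mm, vertex scatter around centroids
    knn: int = 6                        # surface adjacency neighbours
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cortical % 2:
            raise ValueError("n_cortical must be even (hemispheric balance required)")
        if self.n_cortical < 2 or self.n_subcortical < 1:
            raise ValueError("parcel counts must be >= 1")
        if self.n_pd < 1 or self.n_hc < 1 or self.n_sites < 1:
            raise ValueError("subject and site counts must be >= 1")
        for name in ("between_subject_sd", "within_subject_sd", "noise_sd",
                     "site_sd", "conn_noise_sd", "atrophy_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.interhemi_attenuation <= 1.0:
            raise ValueError("interhemi_attenuation must lie in [0, 1]")
        if self.distance_decay <= 0:
            raise ValueError("distance_decay must be positive")
        if self.spread_coefficient < 0:
            raise ValueError("spread coefficient b must be non-negative")
        if self.n_subcortical > len(SUBCORTICAL_SEATS):
            raise ValueError(
                f"at most {len(SUBCORTICAL_SEATS)} subcortical parcels supported"
            )

    @classmethod
    def small(cls, **overrides) -> "SynthConfig":
        """Desk-scale configuration for calibration studies and fast tests."""
        base = dict(n_cortical=40, n_subcortical=6, vertices_per_parcel=10,
                    n_pd=20, n_hc=20, n_sites=2)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=config.seed, spawn_key=(zlib.crc32(stream.encode()),)
        )
    )


# ---------------------------------------------------------------------------
# Atlas and surface
# ---------------------------------------------------------------------------

def gen_atlas(config: SynthConfig) -> tuple[ParcelAtlas, VertexSurface]:
    """Mirrored two-hemisphere atlas plus a jittered vertex surface.

    Cortical centroids are sampled on a left-hemisphere shell and mirrored to
    the right; each cortical parcel receives ``vertices_per_parcel`` vertices
    jittered around its centroid, connected by a symmetric k-nearest-
    neighbour adjacency within hemisphere.  Cortical parcels are assigned to
    the seven intrinsic networks by contiguous spatial sectors, mirrored
    across hemispheres.
    """
    rng = _rng(config, "atlas")
    half = config.n_cortical // 2
    # directions on the left (x < 0) half of a sphere, pushed off the midline
    u = rng.normal(size=(half, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    u[:, 0] = -np.abs(u[:, 0]) - 0.15
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radius = rng.uniform(55.0, 75.0, size=half)
    left = u * radius[:, None]
    right = left * np.array([-1.0, 1.0, 1.0])

    # contiguous network sectors by polar angle around the y axis, mirrored
    angle = np.arctan2(left[:, 2], left[:, 1])
    sector = np.searchsorted(
        np.quantile(angle, np.linspace(0, 1, len(NETWORKS_7) + 1)[1:-1]), angle
    )
    networks = np.array(NETWORKS_7)[sector]

    rows = []
    pid = 1
    for hemi, pts in (("L", left), ("R", right)):
        for k in range(half):
            rows.append(dict(
                parcel_id=pid, hemisphere=hemi, tissue="cortical",
                x=pts[k, 0], y=pts[k, 1], z=pts[k, 2],
                network=networks[k], name=f"cortical_{hemi}_{k + 1}",
            ))
            pid += 1
    for struct, hemi, x, y, z in SUBCORTICAL_SEATS[: config.n_subcortical]:
        suffix = "" if hemi == "M" else f"_{hemi}"
        rows.append(dict(
            parcel_id=pid, hemisphere=hemi, tissue="subcortical",
            x=x, y=y, z=z, network=pd.NA, name=f"{struct}{suffix}",
        ))
        pid += 1
    atlas = ParcelAtlas(pd.DataFrame(rows))

    # vertices jittered around cortical centroids
    cort = atlas.cortical
    centers = np.repeat(cort[["x", "y", "z"]].to_numpy(float),
                        config.vertices_per_parcel, axis=0)
    hemis = np.repeat(cort["hemisphere"].to_numpy(), config.vertices_per_parcel)
    pos = centers + rng.normal(scale=config.vertex_jitter, size=centers.shape)
    # keep jitter from crossing the midline, which defines vertex hemisphere
    pos[:, 0] = np.where(hemis == "L", -np.abs(pos[:, 0]), np.abs(pos[:, 0]))
    vertices = pd.DataFrame(dict(
        vertex_id=np.arange(1, len(pos) + 1),
        x=pos[:, 0], y=pos[:, 1], z=pos[:, 2], hemisphere=hemis,
    ))

    edges = []
    for hemi in ("L", "R"):
        mask = vertices["hemisphere"].to_numpy() == hemi
        ids = vertices.loc[mask, "vertex_id"].to_numpy()
        pts = pos[mask]
        k = min(config.knn + 1, len(pts))
        _, nbr = cKDTree(pts).query(pts, k=k)
        for i in range(len(pts)):
            for j in nbr[i, 1:]:
                a, b = ids[i], ids[j]
                edges.append((min(a, b), max(a, b)))
    edges = np.array(sorted(set(edges)), dtype=int)
    surface = VertexSurface(vertices, edges)
    return atlas, surface


# ---------------------------------------------------------------------------
# Connectomes
# ---------------------------------------------------------------------------

def gen_connectomes(atlas: ParcelAtlas, config: SynthConfig) -> dict:
    """Distance, functional and structural connectomes for the atlas.

    distance: pairwise Euclidean centroid distance (mm).
    functional: exp(-d / lambda) scaled by lognormal per-node strength
    factors (hub structure: node strengths are heavy-tailed) and symmetric
    lognormal pairwise gains (connectivity scatters widely around its
    distance trend), plus symmetric additive noise, clipped to [-1, 1],
    unit diagonal.  Cross-hemisphere functional weights decay with the
    *mirrored* distance scaled by ``homotopic_factor``, reproducing the
    strong homotopic coupling of resting-state connectivity.
    structural: sparse non-negative decaying weights (weakest half zeroed)
    with cross-hemisphere entries scaled by ``interhemi_attenuation``,
    mimicking tractography's difficulty with interhemispheric pathways.
    """
    rng = _rng(config, "connectomes")
    ids = atlas.parcel_ids
    cent = atlas.centroids()
    d = squareform(pdist(cent))
    lam = config.distance_decay
    hemi = atlas.table["hemisphere"].to_numpy()
    cross = hemi[:, None] != hemi[None, :]

    base = np.exp(-d / lam)

    # functional: same-hemisphere weights follow the distance trend, cross-
    # hemisphere weights follow the mirrored (homotopic) distance
    from scipy.spatial.distance import cdist

    d_mirror = cdist(cent, cent * np.array([-1.0, 1.0, 1.0]))
    d_mirror = (d_mirror + d_mirror.T) / 2.0
    func_base = np.where(
        cross, config.homotopic_factor * np.exp(-d_mirror / lam), base
    )
    gains = rng.normal(scale=config.conn_gain_sd, size=d.shape)
    gains = np.exp((gains + gains.T) / 2.0)
    hubs = np.exp(rng.normal(scale=config.conn_hub_sd, size=len(ids)))
    hub_gain = hubs[:, None] * hubs[None, :]
    noise = rng.normal(scale=config.conn_noise_sd, size=d.shape)
    noise = (noise + noise.T) / 2.0
    func = np.clip(func_base * gains * hub_gain + noise, -1.0, 1.0)
    func = (func + func.T) / 2.0
    np.fill_diagonal(func, 1.0)
    lognoise = rng.normal(scale=0.3, size=d.shape)
    lognoise = (lognoise + lognoise.T) / 2.0
    struct = base * np.exp(lognoise)
    struct[cross] *= config.interhemi_attenuation
    off = ~np.eye(len(ids), dtype=bool)
    cutoff = np.quantile(struct[off], 0.5)
    struct[struct < cutoff] = 0.0
    np.fill_diagonal(struct, 0.0)
    struct = (struct + struct.T) / 2.0

    return {
        "functional": Connectome(func, ids, "functional"),
        "structural": Connectome(struct, ids, "structural"),
        "distance": Connectome(d, ids, "distance"),
    }


# ---------------------------------------------------------------------------
# Reservoir atrophy
# ---------------------------------------------------------------------------

def gen_atrophy(
    atlas: ParcelAtlas, config: SynthConfig, reservoir=None
) -> AtrophyMap:
    """Positive atrophy z-values on (a subset of) the subcortical parcels.

    ``reservoir`` defaults to every subcortical parcel; requesting a
    non-subcortical parcel is an error.  Cortical parcels always carry zero,
    reflecting the convention that regions without significant baseline
    atrophy contribute nothing to exposure.
    """
    rng = _rng(config, "atrophy")
    sub_ids = atlas.subcortical["parcel_id"].to_numpy()
    if len(sub_ids) == 0:
        raise ValueError("atlas has no subcortical parcels")
    if reservoir is None:
        reservoir = sub_ids
    reservoir = np.asarray(reservoir, int)
    bad = sorted(set(reservoir) - set(sub_ids))
    if bad:
        raise ValueError(f"requested reservoir parcel {bad[0]} is not subcortical")
    z = np.abs(rng.normal(config.atrophy_mean, config.atrophy_sd, size=len(reservoir)))
    z = np.maximum(z, 0.1)  # strictly positive reservoir
    values = pd.Series(0.0, index=pd.Index(atlas.parcel_ids, name="parcel_id"))
    values.loc[reservoir] = z
    return AtrophyMap(values)


# ---------------------------------------------------------------------------
# Thickness panel
# ---------------------------------------------------------------------------

def gen_thickness(
    atlas: ParcelAtlas,
    surface: VertexSurface,
    vertex_parcel_map: pd.Series,
    conn: Connectome,
    atrophy: AtrophyMap,
    config: SynthConfig,
    parcel_effect: pd.Series | None = None,
) -> ThicknessPanel:
    """Two-group, two-timepoint vertex thickness with a planted spread effect.

    baseline  t1 = baseline_mean + subject offset + vertex noise
    follow-up t2 = t1 - aging_thinning - site offset
                   - [group==PD] * b * exposure(parcel of vertex)
                   + measurement noise

    ``parcel_effect`` (mm of extra PD thinning per cortical parcel) overrides
    the b * exposure term — used e.g. to plant a distance-driven mechanism.
    Thickness is floored at 0.05 mm.
    """
    if config.spread_coefficient < 0:
        raise ValueError("spread coefficient b must be non-negative")
    rng = _rng(config, "thickness")
    if parcel_effect is None:
        expo = disease_exposure(conn, atrophy, atlas)
        parcel_effect = config.spread_coefficient * expo.values
    vert_effect = vertex_parcel_map.map(parcel_effect).reindex(
        surface.vertex_ids
    ).to_numpy(float)
    if not np.all(np.isfinite(vert_effect)):
        raise ValueError("parcel effect does not cover every mapped parcel")

    n = config.n_pd + config.n_hc
    v = surface.n_vertices
    groups = np.array(["PD"] * config.n_pd + ["HC"] * config.n_hc)
    sites = np.array([f"site{1 + i % config.n_sites}" for i in range(n)])
    age = np.where(
        groups == "PD", rng.normal(61.0, 9.4, n), rng.normal(59.0, 11.0, n)
    ).round(1)
    sex = rng.binomial(1, 0.34, size=n)  # 1 = female, cohort is ~1/3 female
    subjects = pd.DataFrame(dict(
        subject=[f"S{i + 1:04d}" for i in range(n)],
        group=groups, site=sites, age=age, sex=sex,
    ))

    subj_offset = rng.normal(0.0, config.between_subject_sd, size=n)
    t1 = (config.baseline_mean + subj_offset[:, None]
          + rng.normal(0.0, config.within_subject_sd, size=(n, v)))
    site_levels = [f"site{k + 1}" for k in range(config.n_sites)]
    site_offsets = rng.normal(0.0, config.site_sd, size=config.n_sites)
    site_of = dict(zip(site_levels, site_offsets))
    per_subj_site = np.array([site_of[s] for s in sites])
    is_pd = (groups == "PD").astype(float)
    t2 = (t1 - config.aging_thinning - per_subj_site[:, None]
          - is_pd[:, None] * vert_effect[None, :]
          + rng.normal(0.0, config.noise_sd, size=(n, v)))
    floor = 0.05
    t1 = np.maximum(t1, floor)
    t2 = np.maximum(t2, floor)
    return ThicknessPanel(subjects, surface.vertex_ids, t1, t2)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

#: Group means/sds used for clinical draws (PD, HC), loosely matching the
#: modelled de novo cohort.
CLINICAL_DISTRIBUTIONS = {
    "moca_t1": ((27.5, 2.1), (28.3, 1.1)),
    "updrs_t1": ((21.7, 9.6), (1.0, 1.5)),
    "asyn": ((1841.5, 729.7), (1898.8, 753.1)),
    "abeta42": ((370.3, 97.0), (373.4, 92.5)),
    "ttau": ((44.8, 18.4), (46.1, 19.7)),
    "ptau181": ((15.9, 9.7), (17.3, 9.8)),
}


def gen_clinical(
    config: SynthConfig,
    subjects: pd.DataFrame | None = None,
    equal_group_means: bool = False,
    cluster_thinning: np.ndarray | None = None,
    moca_slopes: np.ndarray | None = None,
    moca_noise_sd: float = 1.5,
) -> pd.DataFrame:
    """Clinical/CSF table with optional planted ΔMoCA dependence.

    Draws group-specific normal values for MoCA, UPDRS-III and the four CSF
    measures (pg/ml, truncated positive).  With ``equal_group_means`` both
    groups share the PD distribution (null configuration).  When
    ``cluster_thinning`` (n_subjects x 4) and ``moca_slopes`` (length 4) are
    given, MoCA change t1->t2 is slopes @ thinning + noise, enabling
    regression-recovery checks.
    """
    rng = _rng(config, "clinical")
    if subjects is None:
        n = config.n_pd + config.n_hc
        subjects = pd.DataFrame(dict(
            subject=[f"S{i + 1:04d}" for i in range(n)],
            group=np.array(["PD"] * config.n_pd + ["HC"] * config.n_hc),
            site=[f"site{1 + i % config.n_sites}" for i in range(n)],
            age=np.where(np.arange(n) < config.n_pd,
                         rng.normal(61.0, 9.4, n), rng.normal(59.0, 11.0, n)).round(1),
            sex=rng.binomial(1, 0.34, size=n),
        ))
    out = subjects.copy().reset_index(drop=True)
    n = len(out)
    is_pd = (out["group"] == "PD").to_numpy()
    for var, ((m_pd, s_pd), (m_hc, s_hc)) in CLINICAL_DISTRIBUTIONS.items():
        if equal_group_means:
            m_hc, s_hc = m_pd, s_pd
        vals = np.where(is_pd, rng.normal(m_pd, s_pd, n), rng.normal(m_hc, s_hc, n))
        if var in ("asyn", "abeta42", "ttau", "ptau181"):
            vals = np.maximum(vals, 1.0)
        out[var] = vals
    if cluster_thinning is not None and moca_slopes is not None:
        cluster_thinning = np.asarray(cluster_thinning, float)
        delta = cluster_thinning @ np.asarray(moca_slopes, float)
        delta = delta + rng.normal(0.0, moca_noise_sd, size=n)
        out["moca_t2"] = out["moca_t1"] - delta
        for j in range(cluster_thinning.shape[1]):
            out[f"cluster{j + 1}_thinning"] = cluster_thinning[:, j]
    else:
        drift = np.where(is_pd, 0.8, 0.2)
        out["moca_t2"] = out["moca_t1"] - rng.normal(drift, 1.0)
    out["updrs_t2"] = np.where(
        is_pd, out["updrs_t1"] + rng.normal(1.4, 4.0, n), out["updrs_t1"]
    )
    return out


# ---------------------------------------------------------------------------
# Bundled dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthDataset:
    """All synthetic inputs for one run, plus the config that produced them."""

    config: SynthConfig
    atlas: ParcelAtlas
    surface: VertexSurface
    vertex_parcel_map: pd.Series
    connectomes: dict
    atrophy: AtrophyMap
    panel: ThicknessPanel
    clinical: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path
        from .connectome import write_connectome

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.atlas.write_table(outdir / "atlas.csv")
        self.surface.write_tables(outdir / "vertices.csv", outdir / "edges.csv")
        self.vertex_parcel_map.reset_index().to_csv(
            outdir / "vertex_parcel_map.csv", index=False
        )
        for name, conn in self.connectomes.items():
            write_connectome(conn, outdir / f"connectome_{name}.tsv")
        self.atrophy.write_table(outdir / "atrophy.csv")
        self.panel.write_table(outdir / "thickness_panel.csv")
        self.clinical.to_csv(outdir / "clinical.csv", index=False)
        manifest = dict(config=self.config.to_dict(), seed=self.config.seed)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Run every generator once and bundle the results."""
    atlas, surface = gen_atlas(config)
    vmap = map_vertices_to_parcels(surface, atlas)
    conns = gen_connectomes(atlas, config)
    atrophy = gen_atrophy(atlas, config)
    panel = gen_thickness(
        atlas, surface, vmap, conns["functional"], atrophy, config
    )
    clinical = gen_clinical(config, subjects=panel.subjects)
    return SynthDataset(config, atlas, surface, vmap, conns, atrophy, panel, clinical)
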