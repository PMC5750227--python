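"""Disease-exposure propagation model and its statistical inference.

The network-spread hypothesis holds that cortical degeneration is driven by
connectivity to a subcortical "disease reservoir" — the set of regions
already atrophic at baseline.  The exposure of cortical parcel *i* is the
connectivity-weighted sum of reservoir atrophy,

    exposure(i) = sum_j Conn_ij * Atrophy(j),

where Atrophy(j) is the baseline atrophy z-value of reservoir parcel *j*.
Exposure is then related to longitudinal cortical thinning with Spearman
correlation, a permutation null obtained by shuffling the thinning values
over parcels (connectivity and atrophy held fixed), and a percentile
bootstrap over parcels for the confidence interval.  A Euclidean-distance
comparator replaces connectivity with centroid distance (hypothesised
direction: nearer reservoir, more thinning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .atlas import ParcelAtlas
from .connectome import Connectome

SCOPES = ("whole", "left", "right")

#: Subcortical structures forming the basal-ganglia reservoir subset.
BASAL_GANGLIA_STRUCTURES = ("caudate", "putamen", "pallidum", "accumbens")


@dataclass(frozen=True)
class AtrophyMap:
    """Baseline reservoir atrophy: parcel_id -> z-value, zero outside the reservoir.

    Nonzero entries are only permitted on subcortical parcels (validated
    against the atlas when supplied).
    """

    values: pd.Series  # indexed by parcel_id

    def __post_init__(self) -> None:
        v = self.values.astype(float)
        v.index.name = "parcel_id"
        v.name = "atrophy_z"
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v.to_numpy())):
            raise ValueError("atrophy values must be finite")

    @property
    def reservoir(self) -> np.ndarray:
        """parcel_ids with nonzero atrophy."""
        return self.values.index[self.values.to_numpy() != 0.0].to_numpy()

    def validate_against(self, atlas: ParcelAtlas) -> None:
        cort = set(atlas.cortical["parcel_id"])
        bad = sorted(set(self.reservoir) & cort)
        if bad:
            raise ValueError(f"nonzero atrophy on cortical parcel {bad[0]}")

    @classmethod
    def read_table(cls, path) -> "AtrophyMap":
        t = pd.read_csv(path)
        return cls(t.set_index("parcel_id")["atrophy_z"])

    def write_table(self, path) -> None:
        self.values.reset_index().to_csv(path, index=False)


@dataclass(frozen=True)
class ExposureVector:
    """Per-cortical-parcel disease exposure with provenance."""

    values: pd.Series        # indexed by cortical parcel_id
    modality: str
    reservoir: tuple         # parcel_ids summed over
    hemispheres: pd.Series   # parcel_id -> L/R, for scope restriction

    def in_scope(self, scope: str) -> pd.Series:
        return self.values.loc[scope_mask(self.hemispheres, scope)]


@dataclass(frozen=True)
class AssociationResult:
    """Spearman association with permutation p and bootstrap CI."""

    rho: float
    p_perm: float
    ci_low: float
    ci_high: float
    n_perm: int
    n_boot: int
    seed: int
    scope: str
    n: int
    modality: str = ""
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12):
            raise ValueError("rho outside [-1, 1]")
        if not (0.0 < self.p_perm <= 1.0):
            raise ValueError("permutation p must lie in (0, 1]")
        if self.ci_low > self.ci_high:
            raise ValueError("CI bounds out of order")


@dataclass(frozen=True)
class MultivariateFit:
    """OLS of parcel thinning on functional + structural exposure."""

    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    r_squared: float
    n: int
    scope: str


def scope_mask(hemispheres: pd.Series, scope: str) -> np.ndarray:
    """Boolean index of parcel_ids belonging to an analysis scope."""
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    h = hemispheres
    if scope == "whole":
        return h.index.to_numpy()
    want = "L" if scope == "left" else "R"
    return h.index[(h == want).to_numpy()].to_numpy()


# ---------------------------------------------------------------------------
# Exposure
# ---------------------------------------------------------------------------

def disease_exposure(
    conn: Connectome,
    atrophy: AtrophyMap,
    atlas: ParcelAtlas,
    reservoir: np.ndarray | None = None,
) -> ExposureVector:
    """Connectivity-weighted reservoir atrophy seen by each cortical parcel.

    ``reservoir`` restricts the sum to a subset of the nonzero-atrophy
    parcels (default: all of them).  The reservoir always spans both
    hemispheres regardless of the cortical scope later analysed.  Distance
    matrices are refused here; use :func:`associate_distance` for the
    geometric comparator.
    """
    if conn.modality == "distance":
        raise ValueError(
            "disease_exposure expects a functional or structural connectome; "
            "use associate_distance for the Euclidean comparator"
        )
    atrophy.validate_against(atlas)
    if reservoir is None:
        reservoir = atrophy.reservoir
    reservoir = np.asarray(reservoir, int)
    extra = sorted(set(reservoir) - set(atrophy.values.index))
    if extra:
        raise ValueError(f"reservoir parcel {extra[0]} has no atrophy entry")
    cort_ids = atlas.cortical["parcel_id"].to_numpy()
    block = conn.block(cort_ids, reservoir)
    z = atrophy.values.loc[reservoir].to_numpy()
    expo = pd.Series(block @ z, index=cort_ids, name="exposure")
    expo.index.name = "parcel_id"
    hemis = atlas.hemisphere_of().loc[cort_ids]
    return ExposureVector(expo, conn.modality, tuple(reservoir), hemis)


def distance_exposure(
    distance: Connectome,
    atrophy: AtrophyMap,
    atlas: ParcelAtlas,
    reservoir: np.ndarray | None = None,
) -> ExposureVector:
    """Distance-weighted analogue of exposure: sum_j dist_ij * Atrophy(j)."""
    if distance.modality != "distance":
        raise ValueError("distance_exposure requires a distance-modality matrix")
    atrophy.validate_against(atlas)
    if reservoir is None:
        reservoir = atrophy.reservoir
    reservoir = np.asarray(reservoir, int)
    cort_ids = atlas.cortical["parcel_id"].to_numpy()
    block = distance.block(cort_ids, reservoir)
    z = atrophy.values.loc[reservoir].to_numpy()
    expo = pd.Series(block @ z, index=cort_ids, name="exposure")
    expo.index.name = "parcel_id"
    hemis = atlas.hemisphere_of().loc[cort_ids]
    return ExposureVector(expo, "distance", tuple(reservoir), hemis)


def subset_reservoir(
    atrophy: AtrophyMap, atlas: ParcelAtlas, subset="all"
) -> AtrophyMap:
    """Restrict the reservoir to a named subset, zeroing atrophy elsewhere.

    ``subset`` is ``"all"`` (identity), ``"basal_ganglia"`` (caudate,
    putamen, pallidum and accumbens bilaterally, identified through the
    atlas ``name`` column) or an explicit list of parcel_ids.
    """
    if isinstance(subset, str) and subset == "all":
        return atrophy
    if isinstance(subset, str) and subset == "basal_ganglia":
        if "name" not in atlas.table.columns:
            raise ValueError("atlas has no 'name' column; cannot resolve basal ganglia")
        names = atlas.subcortical.set_index("parcel_id")["name"].astype(str)
        keep = names.index[
            names.str.split("_").str[0].isin(BASAL_GANGLIA_STRUCTURES)
        ].to_numpy()
    else:
        keep = np.asarray(list(subset), int)
        sub_ids = set(atlas.subcortical["parcel_id"])
        bad = sorted(set(keep) - sub_ids)
        if bad:
            raise ValueError(f"requested reservoir parcel {bad[0]} is not subcortical")
    v = atrophy.values.copy()
    v.loc[~v.index.isin(keep)] = 0.0
    out = AtrophyMap(v)
    if len(out.reservoir) == 0:
        raise ValueError("reservoir subset leaves no parcel with nonzero atrophy")
    return out


# ---------------------------------------------------------------------------
# Spearman association with permutation and bootstrap inference
# ---------------------------------------------------------------------------

def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation: Pearson on average ranks (ties averaged)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _perm_pvalue(rho_obs: float, rho_null: np.ndarray, alternative: str) -> float:
    n = len(rho_null)
    if alternative == "two-sided":
        k = int(np.sum(np.abs(rho_null) >= abs(rho_obs) - 1e-12))
    elif alternative == "greater":
        k = int(np.sum(rho_null >= rho_obs - 1e-12))
    elif alternative == "less":
        k = int(np.sum(rho_null <= rho_obs + 1e-12))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (k + 1) / (n + 1)


def associate(
    exposure: ExposureVector,
    thinning: pd.Series,
    scope: str = "whole",
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> AssociationResult:
    """Spearman association between exposure and per-parcel thinning.

    The permutation null shuffles the thinning values over the parcels in
    scope while connectivity and atrophy stay fixed; p uses the add-one
    estimator (k+1)/(n_perm+1).  The 95% CI is a percentile bootstrap
    resampling parcels with replacement.
    """
    if n_perm < 1 or n_boot < 1:
        raise ValueError("n_perm and n_boot must be >= 1")
    ids = scope_mask(exposure.hemispheres, scope)
    x = exposure.values.loc[ids].to_numpy(float)
    y = thinning.loc[ids].to_numpy(float)
    if len(x) < 5:
        raise ValueError("need at least 5 parcels in scope")
    if not np.all(np.isfinite(y)):
        raise ValueError("thinning values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    n = len(x)
    rng = np.random.default_rng(seed)

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    zx = (rx - rx.mean()) / rx.std()
    zy = (ry - ry.mean()) / ry.std()
    rho = float(zx @ zy / n)

    # permutation null: permuting y permutes its ranks
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    rho_null = (zy[perm] @ zx) / n

    # percentile bootstrap over parcels (re-rank every resample)
    bidx = rng.integers(0, n, size=(n_boot, n))
    bx = stats.rankdata(x[bidx], axis=1)
    by = stats.rankdata(y[bidx], axis=1)
    bx = bx - bx.mean(axis=1, keepdims=True)
    by = by - by.mean(axis=1, keepdims=True)
    denom = np.sqrt((bx**2).sum(axis=1) * (by**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_boot = (bx * by).sum(axis=1) / denom
    rho_boot = rho_boot[np.isfinite(rho_boot)]
    ci_low, ci_high = np.percentile(rho_boot, [2.5, 97.5])

    return AssociationResult(
        rho=rho,
        p_perm=_perm_pvalue(rho, rho_null, alternative),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
        scope=scope,
        n=n,
        modality=exposure.modality,
        alternative=alternative,
    )


def associate_distance(
    distance: Connectome,
    atrophy: AtrophyMap,
    thinning: pd.Series,
    atlas: ParcelAtlas,
    scope: str = "whole",
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> AssociationResult:
    """Geometric comparator: association of thinning with distance exposure.

    The hypothesised direction is negative (parcels nearer the reservoir
    accumulate a smaller distance-weighted sum yet more thinning); pass
    ``alternative="less"`` for the directional test.
    """
    expo = distance_exposure(distance, atrophy, atlas)
    if np.ptp(expo.values.to_numpy()) == 0:
        raise ValueError("zero-variance input")
    return associate(
        expo, thinning, scope=scope, n_perm=n_perm, n_boot=n_boot,
        seed=seed, alternative=alternative,
    )


# ---------------------------------------------------------------------------
# Multivariate functional + structural model
# ---------------------------------------------------------------------------

def multivariate_fit(
    thinning: pd.Series,
    exposure_func: ExposureVector,
    exposure_struct: ExposureVector,
    scope: str = "whole",
    standardize: bool = False,
    collinearity_r: float = 0.999,
) -> MultivariateFit:
    """OLS of parcel thinning on functional and structural exposure.

    Refuses near-collinear predictors (|r| above ``collinearity_r``) and
    suggests single-predictor runs instead.  ``standardize`` z-scores the
    predictors before fitting.
    """
    ids = scope_mask(exposure_func.hemispheres, scope)
    xf = exposure_func.values.loc[ids].to_numpy(float)
    xs = exposure_struct.values.loc[ids].to_numpy(float)
    y = thinning.loc[ids].to_numpy(float)
    if np.ptp(xf) == 0 or np.ptp(xs) == 0:
        raise ValueError("zero-variance predictor")
    r = float(np.corrcoef(xf, xs)[0, 1])
    if abs(r) > collinearity_r:
        raise ValueError(
            f"functional and structural exposures are collinear (r = {r:.4f}); "
            "run single-predictor models instead"
        )
    if standardize:
        xf = (xf - xf.mean()) / xf.std(ddof=1)
        xs = (xs - xs.mean()) / xs.std(ddof=1)
    X = sm.add_constant(
        pd.DataFrame({"functional": xf, "structural": xs}, index=ids)
    )
    fit = sm.OLS(y, X).fit()
    return MultivariateFit(
        params=fit.params,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        n=len(y),
        scope=scope,
    )
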