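"""Clinical and CSF statistics: group comparisons, partial correlations,
and the cognition (MoCA) regression.

Group comparisons reproduce the usual demographic-table conventions: a
two-sample t-test computed directly from printed summary statistics (pooled
or Welch variants) and a Pearson chi-square on 2x2 sex counts without
continuity correction.  Post-hoc analyses relate per-cluster cortical
thinning to CSF biomarkers via partial correlations controlling for age and
sex, and to cognitive change via an OLS regression of ΔMoCA on the four
cluster thinning values plus age and sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


@dataclass(frozen=True)
class SummaryRow:
    """Per-group mean/sd/n for one variable, as printed in a cohort table."""

    variable: str
    m1: float
    s1: float
    n1: int
    m2: float
    s2: float
    n2: int

    def __post_init__(self) -> None:
        if self.s1 <= 0 or self.s2 <= 0:
            raise ValueError("standard deviations must be positive")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")


@dataclass(frozen=True)
class RegressionResult:
    r_squared: float
    params: pd.Series
    pvalues: pd.Series
    covariates: tuple
    n: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r^2 outside [0, 1]")


def two_sample_t_from_summary(row: SummaryRow, variant: str = "pooled"):
    """Two-sample t-test from group means, sds and ns.

    pooled: sp^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2),
            t = (m1-m2) / (sp * sqrt(1/n1 + 1/n2)), df = n1+n2-2.
    welch:  t = (m1-m2) / sqrt(s1^2/n1 + s2^2/n2) with Satterthwaite df.

    Returns (t, df, two-tailed p).
    """
    m1, s1, n1, m2, s2, n2 = row.m1, row.s1, row.n1, row.m2, row.s2, row.n2
    if variant == "pooled":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    elif variant == "welch":
        v1, v2 = s1**2 / n1, s2**2 / n2
        t = (m1 - m2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}; use 'pooled' or 'welch'")
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi2_2x2(a: int, b: int, c: int, d: int):
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], no continuity correction.

    Returns (chi2, df=1, p).  Zero margins are an error.
    """
    table = np.array([[a, b], [c, d]], float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def partial_correlation(x, y, covariates=None):
    """Pearson correlation of x and y after removing covariates by OLS.

    Both variables are residualised on the covariates plus an intercept;
    df = n - n_covariates - 2 and the two-tailed p comes from the usual
    t transform.  With no covariates this reduces to the plain Pearson r.

    Returns (r, p, df).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        Z = np.ones((len(x), 1))
        k = 0
    else:
        Z = np.column_stack([np.ones(len(x)), np.asarray(covariates, float)])
        if Z.ndim == 1:
            Z = Z[:, None]
        k = Z.shape[1] - 1
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(Z))):
        raise ValueError("inputs must be finite")
    n = len(x)
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2 observations")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.allclose(rx.std(), 0) or np.allclose(ry.std(), 0):
        raise ValueError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    t = r * np.sqrt(df / max(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p), df


def delta_moca_regression(
    delta_moca, cluster_thinning, age, sex, bonferroni: bool = False
) -> RegressionResult:
    """OLS of MoCA change on four cluster-thinning values plus age and sex.

    ``cluster_thinning`` is (n, 4); terms are named cluster1..cluster4.
    With ``bonferroni``, the reported cluster p-values are multiplied by 4
    (capped at 1).  Requires n > 7 and a full-rank design.
    """
    y = np.asarray(delta_moca, float)
    C = np.asarray(cluster_thinning, float)
    if C.ndim != 2 or C.shape[1] != 4:
        raise ValueError("cluster_thinning must be an (n, 4) array")
    n = len(y)
    if n <= 7:
        raise ValueError("need more than 7 observations")
    X = pd.DataFrame(
        {f"cluster{j + 1}": C[:, j] for j in range(4)}
        | {"age": np.asarray(age, float), "sex": np.asarray(sex, float)}
    )
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("collinear regression design")
    fit = sm.OLS(y, Xc).fit()
    pvals = fit.pvalues.copy()
    if bonferroni:
        for j in range(4):
            pvals[f"cluster{j + 1}"] = min(1.0, pvals[f"cluster{j + 1}"] * 4)
    return RegressionResult(
        r_squared=float(fit.rsquared),
        params=fit.params,
        pvalues=pvals,
        covariates=("age", "sex"),
        n=n,
    )


def table1(clinical: pd.DataFrame, variant: str = "pooled") -> pd.DataFrame:
    """Cohort-table group comparisons from a raw clinical table.

    Continuous variables get a two-sample t-test (via summary statistics, so
    the result matches :func:`two_sample_t_from_summary` exactly); sex gets
    the uncorrected chi-square.
    """
    pd_rows = clinical[clinical["group"] == "PD"]
    hc_rows = clinical[clinical["group"] == "HC"]
    out = []
    for var in ("age", "moca_t1", "moca_t2", "asyn", "abeta42", "ttau", "ptau181"):
        if var not in clinical.columns:
            continue
        a, b = pd_rows[var].dropna(), hc_rows[var].dropna()
        row = SummaryRow(var, a.mean(), a.std(ddof=1), len(a),
                         b.mean(), b.std(ddof=1), len(b))
        t, df, p = two_sample_t_from_summary(row, variant)
        out.append(dict(variable=var, pd_mean=row.m1, pd_sd=row.s1,
                        hc_mean=row.m2, hc_sd=row.s2, stat=t, df=df, p=p))
    if "sex" in clinical.columns:
        a = int((pd_rows["sex"] == 1).sum())
        c = int((hc_rows["sex"] == 1).sum())
        chi2, df, p = chi2_2x2(a, len(pd_rows) - a, c, len(hc_rows) - c)
        out.append(dict(variable="sex", pd_mean=a, pd_sd=np.nan,
                        hc_mean=c, hc_sd=np.nan, stat=chi2, df=df, p=p))
    return pd.DataFrame(out)
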