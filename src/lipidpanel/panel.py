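"""Fixed-effects (within) panel regressions, FDR trend screening and
consecutive-visit paired t tests.

The within estimator demeans response and covariates inside each child and
runs OLS on the demeaned data, which is numerically identical to including
one dummy per child. Standard errors are clustered by child with the
``(G/(G-1)) * ((N-1)/(N-K))`` small-sample factor, K counting the slope
coefficients plus the absorbed child intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PanelFitResult:
    table: pd.DataFrame  # per regressor: coef, se, stat, pvalue
    n_obs: int
    n_children: int

    def coef(self, name: str) -> float:
        return float(self.table.loc[name, "coef"])

    def pvalue(self, name: str) -> float:
        return float(self.table.loc[name, "pvalue"])


@dataclass
class TrendClassification:
    table: pd.DataFrame  # per feature: slope, pvalue, fdr_pvalue, label
    alpha: float

    def counts(self) -> dict:
        return self.table["label"].value_counts().to_dict()


def within_fe_fit(
    panel: pd.DataFrame,
    response: str,
    covariates,
    child_col: str = "child_id",
    pvalue_dist: str = "normal",
) -> PanelFitResult:
    """Within (fixed-effects) fit of *response* on time-varying *covariates*.

    ``pvalue_dist='t'`` uses a t distribution with G-1 degrees of freedom
    instead of the default normal approximation for the cluster-robust z.
    """
    covariates = list(covariates)
    cols = [child_col, response, *covariates]
    df = panel[cols].dropna()
    groups = df.groupby(child_col)
    if df[child_col].nunique() < 2 or len(df) < 4:
        raise ValueError("need >=2 observations for >=2 children")
    for cov in covariates:
        within_dev = (df[cov] - groups[cov].transform("mean")).abs().max()
        if within_dev < 1e-12:
            raise ValueError(
                f"covariate '{cov}' is time-invariant within children and is "
                "absorbed by the fixed effects"
            )

    demeaned = df[[response, *covariates]] - groups[[response, *covariates]].transform("mean")
    y = demeaned[response].values
    x = demeaned[covariates].values
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta

    g_ids = df[child_col].values
    n, q = x.shape
    g = df[child_col].nunique()
    bread = np.linalg.inv(x.T @ x)
    scores = pd.DataFrame(x * resid[:, None]).groupby(g_ids).sum().values
    meat = scores.T @ scores
    k_abs = q + g  # slopes plus absorbed child intercepts
    factor = (g / (g - 1)) * ((n - 1) / max(n - k_abs, 1))
    cov = factor * bread @ meat @ bread
    se = np.sqrt(np.diag(cov))
    stat = beta / se
    if pvalue_dist == "t":
        pvals = 2 * stats.t.sf(np.abs(stat), df=g - 1)
    else:
        pvals = 2 * stats.norm.sf(np.abs(stat))
    table = pd.DataFrame(
        {"coef": beta, "se": se, "stat": stat, "pvalue": pvals}, index=covariates
    )
    return PanelFitResult(table=table, n_obs=n, n_children=g)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def trend_screen(
    panel: pd.DataFrame,
    features,
    alpha: float = 0.05,
    time_col: str = "visit_index",
    child_col: str = "child_id",
) -> TrendClassification:
    """Per-feature within-fit on the visit index, BH-FDR across features.

    Features are labeled ``up``/``down`` when the FDR-adjusted p-value falls
    below *alpha* (by slope sign) and ``flat`` otherwise.
    """
    rows, kept = [], []
    for feat in features:
        if panel[feat].dropna().empty:
            warnings.warn(f"feature '{feat}' is all-missing and was dropped")
            continue
        fit = within_fe_fit(panel, feat, [time_col], child_col=child_col)
        rows.append(
            {"slope": fit.coef(time_col), "pvalue": fit.pvalue(time_col)}
        )
        kept.append(feat)
    table = pd.DataFrame(rows, index=kept)
    table["fdr_pvalue"] = bh_fdr(table["pvalue"].values)
    sig = table["fdr_pvalue"] < alpha
    table["label"] = np.where(
        sig & (table["slope"] > 0), "up", np.where(sig, "down", "flat")
    )
    return TrendClassification(table=table, alpha=alpha)


SIGNIFICANCE_TIERS = ((1e-4, "***"), (1e-3, "**"), (1e-2, "*"))


def significance_tier(p: float) -> str:
    for cut, label in SIGNIFICANCE_TIERS:
        if p < cut:
            return label
    return ""


def consecutive_paired_ttests(
    panel: pd.DataFrame,
    value_cols,
    child_col: str = "child_id",
    time_col: str = "visit_index",
) -> pd.DataFrame:
    """Paired t tests between each visit and the preceding visit.

    Only children observed at both visits of a pair enter that comparison.
    Returns one row per (value column, visit pair) with t, df, p and the
    star tier (* p<0.01, ** p<0.001, *** p<0.0001).
    """
    visits = sorted(panel[time_col].dropna().unique())
    rows = []
    for col in value_cols:
        wide = panel.pivot(index=child_col, columns=time_col, values=col)
        for a, b in zip(visits[:-1], visits[1:]):
            pair = wide[[a, b]].dropna()
            if len(pair) < 2:
                warnings.warn(f"{col}: <2 complete pairs for visits {a}->{b}; skipped")
                continue
            diff = pair[b] - pair[a]
            if np.allclose(diff, 0.0):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_rel(pair[b], pair[a])
            rows.append(
                {
                    "variable": col,
                    "visit_from": a,
                    "visit_to": b,
                    "n_pairs": len(pair),
                    "t": float(t_stat),
                    "df": len(pair) - 1,
                    "pvalue": float(p),
                    "tier": significance_tier(float(p)),
                }
            )
    return pd.DataFrame(rows)


def prevalence_percent(n_cases: int, n_total: int) -> float:
    """Share of affected children as a percentage."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_cases <= n_total:
        raise ValueError("n_cases must lie in [0, n_total]")
    return 100.0 * n_cases / n_total


def stunting_rate(laz, cutoff: float = -2.0) -> float:
    """Percentage of values below the stunting cutoff (LAZ < -2)."""
    laz = np.asarray(laz, dtype=float)
    laz = laz[~np.isnan(laz)]
    if laz.size == 0:
        raise ValueError("no non-missing LAZ values")
    return prevalence_percent(int((laz < cutoff).sum()), laz.size)
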