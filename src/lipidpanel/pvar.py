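"""Panel vector autoregression estimated by difference and system GMM.

Estimates ``y_it = sum_l A_l y_{i,t-l} + v_i + e_it`` on (possibly
unbalanced) short panels. The child fixed effect ``v_i`` is removed by first
differencing (``fd``) or forward orthogonal deviations (``fod``); lagged
levels instrument the transformed equation and, in system GMM, lagged
differences instrument an additional levels equation. Estimation is
equation by equation with shared regressors and instruments, which for this
design coincides with joint estimation.

Downstream analytics: Hansen overidentification test, Andrews-Lu moment
selection criteria for the lag order, companion-matrix stability check, and
extraction of the signed directed temporal association network from the
significant lag-1 coefficients (a Granger-style predictive graph).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

RIDGE_COND_LIMIT = 1e12


@dataclass
class PVARSpec:
    endog: list
    lags: int = 1
    exog: list = field(default_factory=list)
    transform: str = "fod"  # 'fd' or 'fod'
    system: bool = True
    max_instr_lags: int | None = None  # instrument depth; None = full history
    collapse: bool = False
    steps: str = "twostep"  # 'onestep' or 'twostep'
    standardize: bool = True
    windmeijer: bool = False
    child_col: str = "child_id"
    time_col: str = "visit_index"

    def __post_init__(self):
        if self.lags < 1:
            raise ValueError("lags must be >= 1")
        if not self.endog:
            raise ValueError("at least one endogenous variable is required")
        if self.transform not in ("fd", "fod"):
            raise ValueError("transform must be 'fd' or 'fod'")
        if self.steps not in ("onestep", "twostep"):
            raise ValueError("steps must be 'onestep' or 'twostep'")


@dataclass
class MomentSystem:
    x: np.ndarray  # n_rows x q shared regressors
    z: np.ndarray  # n_rows x c shared instruments
    y: np.ndarray  # n_rows x k outcomes (one column per equation)
    child: np.ndarray  # child code per row
    time: np.ndarray
    is_level: np.ndarray  # bool per row
    regressor_names: list
    instrument_names: list
    n_children: int

    @property
    def n_instruments(self) -> int:
        return self.z.shape[1]


@dataclass
class PVARModel:
    spec: PVARSpec
    a_mats: list  # p matrices, each k x k (row = equation, col = source var)
    exog_coefs: pd.DataFrame | None
    coef_table: pd.DataFrame  # long: equation, regressor, coef, se, stat, pvalue
    hansen_j: float
    hansen_df: int
    hansen_p: float
    n_instruments: int
    n_children: int
    n_obs: int
    companion: np.ndarray
    eigenvalues: np.ndarray
    stable: bool
    mmsc: pd.DataFrame | None = None
    _moments: MomentSystem | None = None
    _residuals: np.ndarray | None = None

    def coef(self, equation: str, regressor: str) -> float:
        t = self.coef_table
        row = t[(t.equation == equation) & (t.regressor == regressor)]
        return float(row["coef"].iloc[0])

    def pvalue(self, equation: str, regressor: str) -> float:
        t = self.coef_table
        row = t[(t.equation == equation) & (t.regressor == regressor)]
        return float(row["pvalue"].iloc[0])


@dataclass
class TemporalNetwork:
    nodes: list
    edges: pd.DataFrame  # source, target, weight, sign, pvalue
    alpha: float

    def to_node_link(self) -> dict:
        return {
            "nodes": [{"id": n} for n in self.nodes],
            "links": self.edges.to_dict(orient="records"),
        }


def fod_transform(values) -> np.ndarray:
    """Forward orthogonal deviations of one child's ordered series.

    ``x*_t = sqrt(m_t / (m_t + 1)) * (x_t - mean of the m_t available future
    values)``. The last available observation (and any gap) maps to NaN.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    avail = np.flatnonzero(~np.isnan(x))
    for pos, idx in enumerate(avail[:-1]):
        future = x[avail[pos + 1 :]]
        m = len(future)
        out[idx] = np.sqrt(m / (m + 1.0)) * (x[idx] - future.mean())
    return out


def _panel_to_array(panel, spec):
    """(children, Y[N,T,k], exog[N,x]) wide arrays sorted by child/time."""
    children = np.sort(panel[spec.child_col].unique())
    times = np.sort(panel[spec.time_col].unique())
    t_max = int(times.max())
    if times.min() < 1:
        raise ValueError("time indices must be 1-based positive integers")
    n, k = len(children), len(spec.endog)
    y = np.full((n, t_max, k), np.nan)
    cidx = {c: i for i, c in enumerate(children)}
    rows = panel[spec.child_col].map(cidx).values
    cols = panel[spec.time_col].astype(int).values - 1
    for j, var in enumerate(spec.endog):
        y[rows, cols, j] = panel[var].values
    ex = np.zeros((n, len(spec.exog)))
    if spec.exog:
        first = panel.sort_values(spec.time_col).groupby(spec.child_col).first()
        for j, var in enumerate(spec.exog):
            ex[:, j] = first.loc[children, var].values
    return children, y, ex


def build_gmm_system(panel: pd.DataFrame, spec: PVARSpec) -> MomentSystem:
    """Stack the transformed (and, if system, levels) moment system.

    Transformed-equation instruments are per-period blocks of lagged levels
    ``y_{i,t-2}, ..., y_{i,max(1,t-1-depth)}`` of every endogenous variable,
    zero-filled where missing; the levels equation is instrumented by
    per-period blocks of ``dy_{i,t-1}`` plus the constant and exogenous
    columns. ``collapse`` sums instrument blocks across periods.
    """
    children, y, ex = _panel_to_array(panel, spec)
    n, t_max, k = y.shape
    p = spec.lags
    if t_max < p + 2:
        raise ValueError(
            f"need at least {p + 2} periods for a lag-{p} model (have {t_max})"
        )
    depth = spec.max_instr_lags if spec.max_instr_lags is not None else t_max
    obs = ~np.isnan(y).any(axis=2)  # child x time

    # equation rows: y_t and all p lags observed (1-based time t)
    eqrow = np.zeros((n, t_max + 1), dtype=bool)
    for t in range(p + 1, t_max + 1):
        eqrow[:, t] = obs[:, t - p - 1 : t].all(axis=1)

    def eq_vector(i, t):
        """[y_t, y_{t-1}, ..., y_{t-p}] for child i at 1-based time t."""
        return np.concatenate([y[i, t - 1 - l, :] for l in range(p + 1)])

    rows = []  # (child, time, is_level, eqvec or transformed eqvec)
    for i in range(n):
        times_i = [t for t in range(p + 1, t_max + 1) if eqrow[i, t]]
        vecs = {t: eq_vector(i, t) for t in times_i}
        if spec.transform == "fd":
            for t in times_i:
                if t - 1 in vecs:
                    rows.append((i, t, False, vecs[t] - vecs[t - 1]))
        else:  # fod
            for pos, t in enumerate(times_i):
                future = times_i[pos + 1 :]
                if not future:
                    continue
                m = len(future)
                fmean = np.mean([vecs[s] for s in future], axis=0)
                rows.append((i, t, False, np.sqrt(m / (m + 1.0)) * (vecs[t] - fmean)))
        if spec.system:
            for t in times_i:
                rows.append((i, t, True, vecs[t]))
    if not rows:
        raise ValueError("no usable equation rows (panel too short or sparse)")

    n_rows = len(rows)
    q = k * p + (1 + len(spec.exog) if spec.system else 0)
    regressor_names = [
        f"{v}_lag{l}" for l in range(1, p + 1) for v in spec.endog
    ] + (["const"] + list(spec.exog) if spec.system else [])

    x = np.zeros((n_rows, q))
    y_out = np.zeros((n_rows, k))
    child_arr = np.zeros(n_rows, dtype=int)
    time_arr = np.zeros(n_rows, dtype=int)
    level_arr = np.zeros(n_rows, dtype=bool)
    for r, (i, t, is_level, vec) in enumerate(rows):
        child_arr[r], time_arr[r], level_arr[r] = i, t, is_level
        y_out[r] = vec[:k]
        x[r, : k * p] = vec[k:]
        if spec.system and is_level:
            x[r, k * p] = 1.0
            x[r, k * p + 1 :] = ex[i]

    # ---- instruments ----
    dy = np.full_like(y, np.nan)
    dy[:, 1:, :] = y[:, 1:, :] - y[:, :-1, :]

    z_cols: dict[tuple, np.ndarray] = {}

    def col(key):
        if key not in z_cols:
            z_cols[key] = np.zeros(n_rows)
        return z_cols[key]

    for r, (i, t, is_level, _vec) in enumerate(rows):
        if not is_level:
            lo = max(1, t - 1 - depth)
            for s in range(t - 2, lo - 1, -1):
                if s < 1 or not obs[i, s - 1]:
                    continue
                for v in range(k):
                    key = (
                        ("trans", "lag", t - s, v)
                        if spec.collapse
                        else ("trans", t, s, v)
                    )
                    col(key)[r] = y[i, s - 1, v]
        else:
            if t >= 3 and obs[i, t - 2] and obs[i, t - 3]:
                for v in range(k):
                    key = ("level", "dy", v) if spec.collapse else ("level", t, v)
                    col(key)[r] = dy[i, t - 2, v]

    keys = sorted(z_cols.keys(), key=lambda kk: tuple(str(e) for e in kk))
    z_list = [z_cols[kk] for kk in keys]
    instrument_names = ["_".join(str(e) for e in kk) for kk in keys]
    if spec.system:
        z_list.append(level_arr.astype(float))
        instrument_names.append("level_const")
        for j, var in enumerate(spec.exog):
            zc = np.zeros(n_rows)
            zc[level_arr] = ex[child_arr[level_arr], j]
            z_list.append(zc)
            instrument_names.append(f"level_exog_{var}")
    z = np.column_stack(z_list) if z_list else np.zeros((n_rows, 0))

    nonzero = np.abs(z).sum(axis=0) > 0
    z = z[:, nonzero]
    instrument_names = [nm for nm, keep in zip(instrument_names, nonzero) if keep]
    if z.shape[1] == 0:
        raise ValueError("no valid instruments (insufficient periods)")

    return MomentSystem(
        x=x,
        z=z,
        y=y_out,
        child=child_arr,
        time=time_arr,
        is_level=level_arr,
        regressor_names=regressor_names,
        instrument_names=instrument_names,
        n_children=n,
    )


def _weight_inverse(a: np.ndarray, what: str) -> np.ndarray:
    a = (a + a.T) / 2.0
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > RIDGE_COND_LIMIT:
        warnings.warn(
            f"WARNING: singular {what} weighting matrix; ridge-regularized. "
            "Estimates may be unreliable.",
            stacklevel=3,
        )
        scale = max(float(np.abs(np.diag(a)).mean()), 1e-12)
        a = a + 1e-8 * scale * np.eye(a.shape[0])
    return np.linalg.inv(a)


def _per_child_moments(ms: MomentSystem, u: np.ndarray) -> np.ndarray:
    """Sum of z_row * u_row within child -> [n_children x c]."""
    zu = np.zeros((ms.n_children, ms.z.shape[1]))
    np.add.at(zu, ms.child, ms.z * u[:, None])
    return zu


def _onestep_weight(ms: MomentSystem, transform: str) -> np.ndarray:
    """Z' H Z with the fd tridiagonal H (identity for fod and levels rows)."""
    z, lvl = ms.z, ms.is_level
    if transform != "fd":
        return z.T @ z
    zt = z[~lvl]
    a = 2.0 * zt.T @ zt + z[lvl].T @ z[lvl]
    # -1 off-diagonals between consecutive transformed rows of one child
    order = np.lexsort((ms.time, ms.child))
    for r1, r2 in zip(order[:-1], order[1:]):
        if (
            ms.child[r1] == ms.child[r2]
            and not lvl[r1]
            and not lvl[r2]
            and ms.time[r2] == ms.time[r1] + 1
        ):
            off = np.outer(z[r1], z[r2])
            a -= off + off.T
    return a


def fit_pvar(panel: pd.DataFrame, spec: PVARSpec) -> PVARModel:
    """Fit the PVAR by one- or two-step GMM and assemble all diagnostics."""
    panel = panel.sort_values([spec.child_col, spec.time_col])
    if spec.standardize:
        panel = panel.copy()
        for var in spec.endog:
            v = panel[var]
            sd = v.std(ddof=1)
            panel[var] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    ms = build_gmm_system(panel, spec)
    x, z, yy = ms.x, ms.z, ms.y
    k, q, c = yy.shape[1], x.shape[1], z.shape[1]
    if c > ms.n_children:
        warnings.warn(
            f"{c} instruments exceed {ms.n_children} children: Hansen test weak"
        )

    g_mat = z.T @ x  # c x q
    w1 = _weight_inverse(_onestep_weight(ms, spec.transform), "one-step")

    def gmm_solve(w, gy):
        m = g_mat.T @ w @ g_mat
        return np.linalg.solve(m, g_mat.T @ w @ gy), m

    betas = np.zeros((k, q))
    ses = np.zeros((k, q))
    resid = np.zeros_like(yy)
    s_list = []
    for m_eq in range(k):
        gy = z.T @ yy[:, m_eq]
        b1, _ = gmm_solve(w1, gy)
        u1 = yy[:, m_eq] - x @ b1
        zu1 = _per_child_moments(ms, u1)
        s1 = zu1.T @ zu1
        if spec.steps == "twostep":
            w2 = _weight_inverse(s1, "two-step")
            b2, m2 = gmm_solve(w2, gy)
            u2 = yy[:, m_eq] - x @ b2
            v_cov = np.linalg.inv(m2)
            if spec.windmeijer:
                v_cov = _windmeijer(ms, g_mat, w2, v_cov, w1, s1, u1, u2, x)
            beta, u_fin = b2, u2
        else:
            beta, u_fin = b1, u1
            bread = np.linalg.inv(g_mat.T @ w1 @ g_mat)
            v_cov = bread @ (g_mat.T @ w1 @ s1 @ w1 @ g_mat) @ bread
        betas[m_eq] = beta
        ses[m_eq] = np.sqrt(np.clip(np.diag(v_cov), 0.0, None))
        resid[:, m_eq] = u_fin
        s_list.append(s1)

    stat = np.divide(betas, ses, out=np.zeros_like(betas), where=ses > 0)
    pvals = 2 * stats.norm.sf(np.abs(stat))
    records = []
    for m_eq, eq in enumerate(spec.endog):
        for j, rn in enumerate(ms.regressor_names):
            records.append(
                {
                    "equation": eq,
                    "regressor": rn,
                    "coef": betas[m_eq, j],
                    "se": ses[m_eq, j],
                    "stat": stat[m_eq, j],
                    "pvalue": pvals[m_eq, j],
                }
            )
    coef_table = pd.DataFrame(records)

    a_mats = [
        betas[:, (l - 1) * k : l * k].copy() for l in range(1, spec.lags + 1)
    ]
    exog_coefs = None
    if spec.system:
        extra = ms.regressor_names[k * spec.lags :]
        exog_coefs = pd.DataFrame(
            betas[:, k * spec.lags :], index=spec.endog, columns=extra
        )

    j_stat, j_df, j_p = _hansen_from_moments(ms, resid, q)
    companion = companion_matrix(a_mats)
    eig = np.linalg.eigvals(companion)
    model = PVARModel(
        spec=spec,
        a_mats=a_mats,
        exog_coefs=exog_coefs,
        coef_table=coef_table,
        hansen_j=j_stat,
        hansen_df=j_df,
        hansen_p=j_p,
        n_instruments=c,
        n_children=ms.n_children,
        n_obs=len(yy),
        companion=companion,
        eigenvalues=eig,
        stable=bool(np.max(np.abs(eig)) < 1.0),
        _moments=ms,
        _residuals=resid,
    )
    return model


def _windmeijer(ms, g_mat, w2, v2, w1, s1, u1, u2, x):
    """Finite-sample correction of the two-step covariance (approximate)."""
    c, q = g_mat.shape
    zu2 = _per_child_moments(ms, u2).sum(axis=0)  # c
    bread1 = np.linalg.inv(g_mat.T @ w1 @ g_mat)
    v1 = bread1 @ (g_mat.T @ w1 @ s1 @ w1 @ g_mat) @ bread1
    d = np.zeros((q, q))
    zu1 = _per_child_moments(ms, u1)
    zx_by_child = np.zeros((ms.n_children, c, q))
    np.add.at(zx_by_child, ms.child, ms.z[:, :, None] * x[:, None, :])
    for j in range(q):
        ds = -(
            zx_by_child[:, :, j].T @ zu1 + zu1.T @ zx_by_child[:, :, j]
        )  # dS/dbeta_j
        d[:, j] = -(v2 @ g_mat.T @ w2 @ ds @ w2 @ zu2)
    return v2 + d @ v2 + v2 @ d.T + d @ v1 @ d.T


def _hansen_from_moments(ms: MomentSystem, resid: np.ndarray, q: int):
    """Joint Hansen J over all equations (chi^2, df = moments - parameters)."""
    k = resid.shape[1]
    per_eq = [_per_child_moments(ms, resid[:, m]) for m in range(k)]
    g_i = np.hstack(per_eq)  # n_children x (k*c)
    g_tot = g_i.sum(axis=0)
    s = g_i.T @ g_i
    df = k * ms.z.shape[1] - k * q
    if df <= 0:
        return 0.0, 0, float("nan")
    j_stat = float(g_tot @ np.linalg.pinv(s) @ g_tot)
    return j_stat, df, float(stats.chi2.sf(j_stat, df))


def hansen_j(model: PVARModel) -> tuple[float, int, float]:
    """Hansen J test of the overidentifying restrictions (two-step fit).

    Returns ``(J, df, p)``; a just-identified model reports ``J=0`` with
    ``p`` flagged as NaN.
    """
    if model.spec.steps != "twostep":
        raise ValueError("Hansen test requires a two-step fit")
    return model.hansen_j, model.hansen_df, model.hansen_p


def companion_matrix(a_mats) -> np.ndarray:
    """[[A_1 ... A_p], [I, 0]] block companion form."""
    p = len(a_mats)
    k = a_mats[0].shape[0]
    comp = np.zeros((k * p, k * p))
    comp[:k] = np.hstack(a_mats)
    if p > 1:
        comp[k:, : k * (p - 1)] = np.eye(k * (p - 1))
    return comp


def stability_check(model: PVARModel):
    """Eigenvalue moduli, stability flag and unit-circle coordinates."""
    eig = model.eigenvalues
    moduli = np.abs(eig)
    coords = np.column_stack([eig.real, eig.imag])
    return moduli, bool(np.max(moduli) < 1.0), coords


def mmsc_lag_select(
    panel: pd.DataFrame,
    spec: PVARSpec,
    p_candidates=(1, 2),
    criterion: str = "bic",
) -> tuple[pd.DataFrame, int, dict]:
    """Andrews-Lu moment selection over candidate lag orders.

    ``MMSC_BIC = J - (c - b) ln N``, ``MMSC_AIC = J - 2 (c - b)`` and
    ``MMSC_HQIC = J - 2.1 (c - b) ln ln N`` with c = moment count and
    b = parameter count; the chosen p minimizes the configured criterion,
    ties broken toward the smaller p.
    """
    rows, models = [], {}
    for p in sorted(p_candidates):
        cand = replace(spec, lags=p, steps="twostep")
        try:
            model = fit_pvar(panel, cand)
        except ValueError as err:
            rows.append({"p": p, "feasible": False, "note": str(err)})
            continue
        k = len(spec.endog)
        c = k * model.n_instruments
        b = k * len(model._moments.regressor_names)
        n = model.n_children
        j = model.hansen_j
        rows.append(
            {
                "p": p,
                "feasible": True,
                "j": j,
                "n_moments": c,
                "n_params": b,
                "mmsc_bic": j - (c - b) * np.log(n),
                "mmsc_aic": j - 2.0 * (c - b),
                "mmsc_hqic": j - 2.1 * (c - b) * np.log(np.log(n)),
            }
        )
        models[p] = model
    table = pd.DataFrame(rows)
    feasible = table[table["feasible"]]
    if feasible.empty:
        raise ValueError("no feasible lag candidate")
    key = f"mmsc_{criterion}"
    best_val = feasible[key].min()
    chosen = int(feasible.loc[feasible[key] <= best_val + 1e-12, "p"].min())
    return table, chosen, models


def extract_temporal_network(model: PVARModel, alpha: float = 0.05) -> TemporalNetwork:
    """Signed directed edges from significant lag-1 coefficients.

    Edge ``source -> target`` means the current value of *source* predicts
    the next-period value of *target*; self-loops come from the diagonal.
    """
    endog = model.spec.endog
    k = len(endog)
    a1 = model.a_mats[0]
    edges = []
    for m_eq, target in enumerate(endog):
        for j, source in enumerate(endog):
            p = model.pvalue(target, f"{source}_lag1")
            if p < alpha:
                w = float(a1[m_eq, j])
                edges.append(
                    {
                        "source": source,
                        "target": target,
                        "weight": w,
                        "sign": "positive" if w > 0 else "negative",
                        "pvalue": p,
                    }
                )
    edges_df = pd.DataFrame(
        edges, columns=["source", "target", "weight", "sign", "pvalue"]
    )
    return TemporalNetwork(nodes=list(endog), edges=edges_df, alpha=alpha)
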