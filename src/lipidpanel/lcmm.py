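"""Latent-class linear mixed models for growth trajectories.

A finite mixture of mixed-effects models: each class k has a mean trajectory
over a natural cubic spline basis in age, children carry a random intercept
and random age slope (covariance shared across classes), and residuals are
iid Gaussian. Children with missing visits contribute the marginal
likelihood of their observed rows only. Fitting is by (multicycle) ECM, so
the observed-data log-likelihood is non-decreasing across iterations; the
best of several restarts is kept and classes are relabeled by ascending
trajectory value at the earliest age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

DEFAULT_N_KNOTS = 5


@dataclass
class SplineBasis:
    """Natural cubic spline design with knots at age quantiles."""

    knots: np.ndarray  # on the internal (standardized) scale
    age_mean: float
    age_sd: float

    @property
    def dim(self) -> int:
        return len(self.knots)

    def design(self, age) -> np.ndarray:
        x = (np.asarray(age, dtype=float) - self.age_mean) / self.age_sd
        kn = self.knots
        k = len(kn)
        cols = [np.ones_like(x), x]

        def d(j):
            num = np.clip(x - kn[j], 0, None) ** 3 - np.clip(x - kn[-1], 0, None) ** 3
            return num / (kn[-1] - kn[j])

        d_last = d(k - 2)
        for j in range(k - 2):
            cols.append(d(j) - d_last)
        return np.column_stack(cols)


def quantile_spline_basis(age, n_knots: int = DEFAULT_N_KNOTS) -> SplineBasis:
    """Natural cubic spline basis with interior knots at age quantiles."""
    age = np.asarray(age, dtype=float)
    age = age[~np.isnan(age)]
    if np.ptp(age) < 1e-12:
        raise ValueError("age is constant; spline basis would be rank deficient")
    mean, sd = float(age.mean()), float(age.std())
    x = (age - mean) / sd
    knots = np.quantile(x, np.linspace(0, 1, n_knots))
    uniq = np.unique(knots)
    if len(uniq) < len(knots):
        warnings.warn(
            f"{len(knots) - len(uniq)} tied knots collapsed "
            f"({len(uniq)} distinct remain)"
        )
    if len(uniq) < 2:
        raise ValueError("fewer than 2 distinct knots")
    return SplineBasis(knots=uniq, age_mean=mean, age_sd=sd)


@dataclass
class EMConfig:
    n_restarts: int = 10
    tol: float = 1e-6
    max_iter: int = 200
    seed: int = 0


@dataclass
class LatentClassModel:
    k: int
    mixing: np.ndarray  # pi, sums to 1
    trajectories: np.ndarray  # [K x basis dim]
    sex_effect: float | None
    re_cov: np.ndarray  # 2x2 random intercept+slope covariance
    resid_sd: float
    posterior: pd.DataFrame  # children x K, rows sum to 1
    loglik: float
    loglik_trace: np.ndarray
    aic: float
    bic: float
    n_params: int
    converged: bool
    n_restarts: int
    basis: SplineBasis

    def modal_labels(self) -> pd.Series:
        return self.posterior.idxmax(axis=1)

    def class_means(self, age) -> np.ndarray:
        """Predicted class trajectories at the given ages, [K x len(age)]."""
        b = self.basis.design(age)
        return self.trajectories @ b.T


class _Pattern:
    """All children sharing one visit-observation pattern."""

    def __init__(self, basis: SplineBasis, ages, y_rows, sex_vals, child_ids):
        self.ages = np.asarray(ages, dtype=float)
        self.b = basis.design(self.ages)  # n_obs x d
        zage = (self.ages - basis.age_mean) / basis.age_sd
        self.z = np.column_stack([np.ones_like(zage), zage])  # n_obs x 2
        self.y = np.asarray(y_rows, dtype=float)  # n_child x n_obs
        self.sex = np.asarray(sex_vals, dtype=float)
        self.child_ids = list(child_ids)
        self.n_obs = self.b.shape[0]
        self.n_child = self.y.shape[0]


def _build_patterns(panel, response, basis, child_col, age_col, sex_col):
    groups: dict[tuple, list] = {}
    df = panel[[child_col, age_col, response] + ([sex_col] if sex_col else [])].dropna(
        subset=[response, age_col]
    )
    for cid, sub in df.groupby(child_col):
        sub = sub.sort_values(age_col)
        key = tuple(sub[age_col].values)
        sex = float(sub[sex_col].iloc[0]) if sex_col else 0.0
        groups.setdefault(key, []).append((cid, sub[response].values, sex))
    patterns = []
    for ages, entries in groups.items():
        cids = [e[0] for e in entries]
        rows = np.vstack([e[1] for e in entries])
        sexes = [e[2] for e in entries]
        patterns.append(_Pattern(basis, ages, rows, sexes, cids))
    return patterns


def _class_logliks(patterns, gamma, delta, g_cov, sigma2):
    """Per-pattern list of [n_child x K] Gaussian log-densities."""
    out = []
    for pt in patterns:
        v = pt.z @ g_cov @ pt.z.T + sigma2 * np.eye(pt.n_obs)
        l_chol = np.linalg.cholesky(v)
        logdet = 2.0 * np.sum(np.log(np.diag(l_chol)))
        const = -0.5 * (pt.n_obs * np.log(2 * np.pi) + logdet)
        ll = np.empty((pt.n_child, gamma.shape[0]))
        base = pt.y - delta * pt.sex[:, None]
        for k in range(gamma.shape[0]):
            r = base - (pt.b @ gamma[k])[None, :]
            a = solve_triangular(l_chol, r.T, lower=True)
            ll[:, k] = const - 0.5 * np.sum(a**2, axis=0)
        out.append(ll)
    return out


def _posteriors(class_ll, pi):
    """Responsibilities and total log-likelihood from class log-densities."""
    total = 0.0
    ws = []
    logpi = np.log(np.clip(pi, 1e-300, None))
    for ll in class_ll:
        a = ll + logpi[None, :]
        m = a.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(a - m).sum(axis=1))
        total += lse.sum()
        ws.append(np.exp(a - lse[:, None]))
    return ws, float(total)


def _update_mean(patterns, ws, g_cov, sigma2, n_classes, dim, with_sex):
    """Joint weighted-GLS update of class trajectories (and sex effect)."""
    p_tot = n_classes * dim + (1 if with_sex else 0)
    a_mat = np.zeros((p_tot, p_tot))
    rhs = np.zeros(p_tot)
    for pt, w in zip(patterns, ws):
        v = pt.z @ g_cov @ pt.z.T + sigma2 * np.eye(pt.n_obs)
        vc = cho_factor(v, lower=True)
        vinv_b = cho_solve(vc, pt.b)  # n_obs x d
        bvb = pt.b.T @ vinv_b
        vinv_yt = cho_solve(vc, pt.y.T)  # n_obs x n_child
        bvy = pt.b.T @ vinv_yt  # d x n_child
        for k in range(n_classes):
            sl = slice(k * dim, (k + 1) * dim)
            wk = w[:, k]
            a_mat[sl, sl] += wk.sum() * bvb
            rhs[sl] += bvy @ wk
        if with_sex:
            one = np.ones(pt.n_obs)
            vinv_1 = cho_solve(vc, one)
            bv1 = pt.b.T @ vinv_1
            yv1 = pt.y @ vinv_1  # per child: 1' V^-1 y_i
            for k in range(n_classes):
                sl = slice(k * dim, (k + 1) * dim)
                swk = float(np.sum(w[:, k] * pt.sex))
                a_mat[sl, -1] += swk * bv1
                a_mat[-1, sl] += swk * bv1
            a_mat[-1, -1] += float(np.sum(pt.sex**2)) * (one @ vinv_1)
            rhs[-1] += float(np.sum(pt.sex * yv1))
    theta = np.linalg.solve(a_mat, rhs)
    delta = float(theta[-1]) if with_sex else 0.0
    gamma = theta[: n_classes * dim].reshape(n_classes, dim)
    return gamma, delta


def _update_variance(patterns, ws, gamma, delta, g_cov, sigma2):
    """EM update of the random-effect covariance and residual variance."""
    n_child = sum(pt.n_child for pt in patterns)
    n_obs_tot = sum(pt.n_child * pt.n_obs for pt in patterns)
    g_acc = np.zeros((2, 2))
    s_acc = 0.0
    for pt, w in zip(patterns, ws):
        v = pt.z @ g_cov @ pt.z.T + sigma2 * np.eye(pt.n_obs)
        vc = cho_factor(v, lower=True)
        vinv_z = cho_solve(vc, pt.z)  # n_obs x 2
        c_post = g_cov - g_cov @ (pt.z.T @ vinv_z) @ g_cov  # 2x2
        tr_zcz = float(np.trace(pt.z @ c_post @ pt.z.T))
        base = pt.y - delta * pt.sex[:, None]
        for k in range(gamma.shape[0]):
            r = base - (pt.b @ gamma[k])[None, :]  # n_child x n_obs
            bhat = (g_cov @ (pt.z.T @ cho_solve(vc, r.T))).T  # n_child x 2
            wk = w[:, k]
            g_acc += (bhat * wk[:, None]).T @ bhat + wk.sum() * c_post
            eps = r - bhat @ pt.z.T
            s_acc += float(np.sum(wk * np.sum(eps**2, axis=1))) + wk.sum() * tr_zcz
    g_new = g_acc / n_child
    g_new = (g_new + g_new.T) / 2.0
    sigma2_new = max(s_acc / n_obs_tot, 1e-10)
    return g_new, sigma2_new


def _init_responsibilities(patterns, k, rng, restart_idx):
    """Hard-assignment initialization from per-child mean response.

    The first restart bins children into K quantile groups of their mean;
    later restarts assign children to the nearest of K randomly chosen
    child means (one k-means step), which keeps starting trajectories
    well separated instead of collapsing onto the grand mean.
    """
    means = np.concatenate([pt.y.mean(axis=1) for pt in patterns])
    n = len(means)
    if restart_idx == 0:
        order = np.argsort(means, kind="stable")
        labels = np.empty(n, dtype=int)
        for j, chunk in enumerate(np.array_split(order, k)):
            labels[chunk] = j
    else:
        centers = means[rng.choice(n, size=k, replace=False)]
        labels = np.argmin(np.abs(means[:, None] - centers[None, :]), axis=1)
        # guard against empty initial classes
        for j in range(k):
            if not (labels == j).any():
                labels[rng.integers(n)] = j
    onehot = np.eye(k)[labels]
    # soften slightly so no responsibility is exactly zero
    onehot = 0.9 * onehot + 0.1 / k
    ws, pos = [], 0
    for pt in patterns:
        ws.append(onehot[pos : pos + pt.n_child])
        pos += pt.n_child
    return ws


def fit_latent_class_mixed(
    panel: pd.DataFrame,
    response: str,
    k: int,
    config: EMConfig | None = None,
    child_col: str = "child_id",
    age_col: str = "week",
    sex_col: str | None = None,
    n_knots: int = DEFAULT_N_KNOTS,
    basis: SplineBasis | None = None,
) -> LatentClassModel:
    """Fit a K-class latent-class linear mixed model by multi-restart ECM."""
    if k < 1:
        raise ValueError("k must be >= 1")
    config = config or EMConfig()
    if basis is None:
        basis = quantile_spline_basis(panel[age_col].dropna().values, n_knots)
    patterns = _build_patterns(panel, response, basis, child_col, age_col, sex_col)
    n_child = sum(pt.n_child for pt in patterns)
    if n_child < k:
        raise ValueError("fewer children than classes")
    dim = basis.dim
    with_sex = sex_col is not None
    y_all = np.concatenate([pt.y.ravel() for pt in patterns])
    y_var = float(np.var(y_all))

    rng = np.random.default_rng(config.seed)
    best = None
    restarts_used = 0
    attempts = 0
    max_attempts = config.n_restarts * 3  # empty-class restarts count extra
    while restarts_used < config.n_restarts and attempts < max_attempts:
        attempts += 1
        ws = _init_responsibilities(patterns, k, rng, restarts_used)
        g_cov = np.diag([y_var / 2.0, y_var / 8.0])
        sigma2 = y_var / 2.0
        gamma, delta = _update_mean(patterns, ws, g_cov, sigma2, k, dim, with_sex)
        pi = np.full(k, 1.0 / k)
        trace = []
        converged = False
        degenerate = False
        for _ in range(config.max_iter):
            class_ll = _class_logliks(patterns, gamma, delta, g_cov, sigma2)
            ws, ll = _posteriors(class_ll, pi)
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < config.tol * (
                1.0 + abs(trace[-2])
            ):
                converged = True
                break
            pi = np.concatenate([w for w in ws]).mean(axis=0)
            if (pi < 1.0 / (10.0 * n_child)).any():
                degenerate = True
                break
            gamma, delta = _update_mean(patterns, ws, g_cov, sigma2, k, dim, with_sex)
            # fresh E-step with the updated means keeps ECM monotone
            class_ll = _class_logliks(patterns, gamma, delta, g_cov, sigma2)
            ws, _ = _posteriors(class_ll, pi)
            g_cov, sigma2 = _update_variance(patterns, ws, gamma, delta, g_cov, sigma2)
        if degenerate:
            continue
        restarts_used += 1
        if best is None or trace[-1] > best["loglik"]:
            best = {
                "loglik": trace[-1],
                "trace": np.array(trace),
                "pi": pi,
                "gamma": gamma,
                "delta": delta,
                "g": g_cov,
                "sigma2": sigma2,
                "ws": ws,
                "converged": converged,
            }
    if best is None:
        raise RuntimeError(
            "all EM restarts collapsed to an empty class; reduce k or add restarts"
        )

    # relabel by ascending trajectory value at the earliest age
    min_age = min(pt.ages.min() for pt in patterns)
    first_vals = (best["gamma"] @ basis.design([min_age]).T)[:, 0]
    order = np.argsort(first_vals, kind="stable")
    gamma = best["gamma"][order]
    pi = best["pi"][order]
    post_rows = np.vstack([w[:, order] for w in best["ws"]])
    child_ids = [cid for pt in patterns for cid in pt.child_ids]
    posterior = pd.DataFrame(
        post_rows, index=child_ids, columns=list(range(1, k + 1))
    ).sort_index()

    n_params = (k - 1) + k * dim + (1 if with_sex else 0) + 3 + 1
    ll = best["loglik"]
    aic = -2.0 * ll + 2.0 * n_params
    bic = -2.0 * ll + np.log(n_child) * n_params
    if not best["converged"]:
        warnings.warn(f"EM did not converge in {config.max_iter} iterations")
    return LatentClassModel(
        k=k,
        mixing=pi,
        trajectories=gamma,
        sex_effect=best["delta"] if with_sex else None,
        re_cov=best["g"],
        resid_sd=float(np.sqrt(best["sigma2"])),
        posterior=posterior,
        loglik=float(ll),
        loglik_trace=best["trace"],
        aic=float(aic),
        bic=float(bic),
        n_params=n_params,
        converged=best["converged"],
        n_restarts=restarts_used,
        basis=basis,
    )


def select_num_classes(
    panel: pd.DataFrame,
    response: str,
    k_range=(2, 3, 4),
    config: EMConfig | None = None,
    **fit_kwargs,
) -> tuple[LatentClassModel, pd.DataFrame]:
    """Fit each K in *k_range* (shared seed/restarts) and pick the lowest AIC."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    config = config or EMConfig()
    models, rows = {}, []
    for k in k_range:
        model = fit_latent_class_mixed(panel, response, k, config=config, **fit_kwargs)
        models[k] = model
        rows.append(
            {
                "k": k,
                "loglik": model.loglik,
                "n_params": model.n_params,
                "aic": model.aic,
                "bic": model.bic,
                "converged": model.converged,
            }
        )
    table = pd.DataFrame(rows).set_index("k")
    best_k = int(table["aic"].idxmin())
    return models[best_k], table
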