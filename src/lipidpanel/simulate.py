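"""Synthetic cohort generator with known ground truth.

Generates the three layers the analysis pipeline consumes:

* a long-format cohort panel in which growth z-scores follow latent-class
  mean trajectories plus a stationary VAR(1) deviation process with
  child-level fixed effects;
* lipid features built from latent module signals so that the module
  partition, within-module correlation and cross-lagged dynamics are all
  known exactly;
* raw feature tables with engineered QC-filter violations.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import DEFAULT_VISIT_WEEKS
from .qc import RawFeatureTable, FILTER_ORDER

#: growth outcomes occupy the first three coordinates of the latent state
N_GROWTH = 3


def spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(a, dtype=float)))))


@dataclass
class SimConfig:
    """Configuration of the cohort simulator.

    ``class_spec`` is a list of ``(proportion, coefficients)`` pairs; the
    coefficients are an ascending polynomial in the 1-based visit index and
    define the class mean trajectory shared by the three growth scores.
    ``var_matrix`` is the true lag-1 coefficient matrix of the latent state
    ``(waz, laz, wlz, module_1..module_m)``.
    """

    n_children: int = 200
    visit_weeks: tuple = DEFAULT_VISIT_WEEKS
    dropout_prob: float = 0.0
    seed: int = 0
    n_modules: int = 3
    lipids_per_module: int = 10
    within_module_cor: float = 0.8
    noise_sd: float = 1.0
    var_matrix: np.ndarray | None = None
    fixed_effect_sd: float = 0.5
    class_spec: tuple = ((0.5, (0.0, -0.2)), (0.5, (1.0, -0.4)))
    sex_effect: float = 0.0
    require_stable: bool = True
    burn_in: int = 50

    @property
    def state_dim(self) -> int:
        return N_GROWTH + self.n_modules

    def resolved_var_matrix(self) -> np.ndarray:
        if self.var_matrix is None:
            return 0.3 * np.eye(self.state_dim)
        return np.asarray(self.var_matrix, dtype=float)

    def validate(self) -> None:
        props = np.array([p for p, _ in self.class_spec], dtype=float)
        if abs(props.sum() - 1.0) > 1e-8:
            raise ValueError(
                f"class proportions must sum to 1 (got {props.sum():.6f})"
            )
        weeks = np.asarray(self.visit_weeks)
        if not (np.diff(weeks) > 0).all():
            raise ValueError("visit_weeks must be strictly increasing")
        a = self.resolved_var_matrix()
        if a.shape != (self.state_dim, self.state_dim):
            raise ValueError(
                f"var_matrix must be {self.state_dim}x{self.state_dim}, got {a.shape}"
            )
        if self.require_stable and spectral_radius(a) >= 1.0:
            raise ValueError(
                f"var_matrix is unstable (spectral radius "
                f"{spectral_radius(a):.3f} >= 1); pass require_stable=False to override"
            )
        if not 0 < self.within_module_cor < 1:
            raise ValueError("within_module_cor must be in (0, 1)")
        if self.noise_sd < 0 or self.fixed_effect_sd < 0:
            raise ValueError("noise_sd and fixed_effect_sd must be nonnegative")


@dataclass
class GroundTruth:
    """Recovery targets for the downstream stages."""

    class_labels: np.ndarray | None = None
    class_trajectories: np.ndarray | None = None  # [K x T] mean per visit
    var_matrix: np.ndarray | None = None
    module_assignment: dict = field(default_factory=dict)  # lipid -> module (1-based)
    fixed_effects: np.ndarray | None = None
    qc_violations: dict = field(default_factory=dict)  # feature -> [filter names]

    def to_json(self, path) -> None:
        def _convert(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        with open(path, "w") as fh:
            json.dump({k: _convert(v) for k, v in asdict(self).items()}, fh, indent=1)


def _simulate_var_states(
    rng: np.random.Generator,
    n: int,
    t: int,
    a: np.ndarray,
    fe_sd: float,
    noise_sd: float,
    burn_in: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent VAR(1) deviations with child fixed effects, post burn-in.

    The fixed effect enters as a level shift: y = alpha_i + u with
    u_t = A u_{t-1} + eps, so that first differences and forward orthogonal
    deviations are unaffected by alpha_i.
    """
    k = a.shape[0]
    alpha = rng.normal(0.0, fe_sd, size=(n, k)) if fe_sd > 0 else np.zeros((n, k))
    u = np.zeros((n, k))
    states = np.empty((n, t, k))
    for step in range(burn_in + t):
        eps = rng.normal(0.0, noise_sd, size=(n, k)) if noise_sd > 0 else 0.0
        u = u @ a.T + eps
        if step >= burn_in:
            states[:, step - burn_in, :] = u
    return states + alpha[:, None, :], alpha


def class_mean_trajectories(config: SimConfig) -> np.ndarray:
    """Class mean growth per visit index, shape [n_classes x n_visits]."""
    t_idx = np.arange(1, len(config.visit_weeks) + 1, dtype=float)
    return np.array(
        [np.polynomial.polynomial.polyval(t_idx, np.asarray(c, float)) for _, c in config.class_spec]
    )


def simulate_study(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a full cohort panel: growth scores, lipids and latent modules.

    Returns the long-format panel (one row per retained child-visit) and the
    :class:`GroundTruth` with class labels, the true lag matrix, the module
    assignment and the fixed effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, t = config.n_children, len(config.visit_weeks)
    a = config.resolved_var_matrix()
    props = np.array([p for p, _ in config.class_spec], dtype=float)

    labels = rng.choice(len(props), size=n, p=props)
    sex = rng.integers(0, 2, size=n)
    states, alpha = _simulate_var_states(
        rng, n, t, a, config.fixed_effect_sd, config.noise_sd, config.burn_in
    )

    traj = class_mean_trajectories(config)  # [K x T]
    growth = traj[labels][:, :, None] + states[:, :, :N_GROWTH]
    growth += config.sex_effect * sex[:, None, None]

    # latent module signals, standardized over the full panel
    z = states[:, :, N_GROWTH:]  # [n x t x m]
    sd = z.std(axis=(0, 1), ddof=0)
    mean = z.mean(axis=(0, 1))
    zs = np.where(sd > 0, (z - mean) / np.where(sd > 0, sd, 1.0), 0.0)

    w = config.within_module_cor
    n_lip = config.n_modules * config.lipids_per_module
    eta = rng.normal(0.0, 1.0, size=(n, t, n_lip))
    lipids = np.empty((n, t, n_lip))
    module_assignment = {}
    for m in range(config.n_modules):
        for j in range(config.lipids_per_module):
            idx = m * config.lipids_per_module + j
            lipids[:, :, idx] = np.sqrt(w) * zs[:, :, m] + np.sqrt(1 - w) * eta[:, :, idx]
            module_assignment[f"lipid_{idx + 1:03d}"] = m + 1

    keep = np.ones((n, t), dtype=bool)
    if config.dropout_prob > 0:
        keep[:, 1:] = rng.random((n, t - 1)) >= config.dropout_prob

    rows = []
    weeks = list(config.visit_weeks)
    for i in range(n):
        for v in range(t):
            if not keep[i, v]:
                continue
            row = {
                "child_id": i + 1,
                "sex": int(sex[i]),
                "week": weeks[v],
                "visit_index": v + 1,
                "waz": growth[i, v, 0],
                "laz": growth[i, v, 1],
                "wlz": growth[i, v, 2],
            }
            for m in range(config.n_modules):
                row[f"me_{m + 1}"] = zs[i, v, m]
            for idx in range(n_lip):
                row[f"lipid_{idx + 1:03d}"] = lipids[i, v, idx]
            rows.append(row)
    panel = pd.DataFrame(rows)

    truth = GroundTruth(
        class_labels=labels,
        class_trajectories=traj,
        var_matrix=a,
        module_assignment=module_assignment,
        fixed_effects=alpha,
    )
    return panel, truth


def simulate_var_panel(
    n: int,
    t: int,
    a: np.ndarray,
    fe_sd: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    require_stable: bool = True,
    burn_in: int = 50,
) -> pd.DataFrame:
    """Pure VAR(1)-with-fixed-effects panel for estimator testing.

    Columns ``y1..yk`` plus ``child_id`` and ``visit_index``; a burn-in of
    *burn_in* periods precedes the *t* retained periods so the process is at
    its stationary distribution.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if a.shape[0] != a.shape[1]:
        raise ValueError("a must be square")
    if t < 3:
        raise ValueError("t must be at least 3")
    if require_stable and spectral_radius(a) >= 1.0:
        raise ValueError(
            f"unstable VAR matrix (spectral radius {spectral_radius(a):.3f} >= 1)"
        )
    rng = np.random.default_rng(seed)
    states, _ = _simulate_var_states(rng, n, t, a, fe_sd, noise_sd, burn_in)
    k = a.shape[0]
    child = np.repeat(np.arange(1, n + 1), t)
    visit = np.tile(np.arange(1, t + 1), n)
    data = {"child_id": child, "visit_index": visit}
    flat = states.reshape(n * t, k)
    for j in range(k):
        data[f"y{j + 1}"] = flat[:, j]
    return pd.DataFrame(data)


def simulate_raw_features(
    n_features: int,
    n_samples: int,
    violation_spec: dict | None = None,
    seed: int = 0,
    n_blanks: int = 3,
    n_dilution: int = 5,
) -> tuple[RawFeatureTable, GroundTruth]:
    """Raw feature table with engineered per-filter violations.

    ``violation_spec`` maps a filter name (``ppm``, ``blank_ratio``,
    ``zero_fraction``, ``dilution_r``) to an iterable of 0-based feature
    indices constructed to fail exactly that filter; all other features are
    constructed to pass all four.
    """
    violation_spec = violation_spec or {}
    unknown = set(violation_spec) - set(FILTER_ORDER)
    if unknown:
        raise ValueError(f"unknown filters in violation_spec: {sorted(unknown)}")
    if n_dilution < 4 or n_samples < n_blanks + n_dilution + 1:
        raise ValueError(
            f"n_samples={n_samples} cannot host {n_blanks} blanks, a >=4-point "
            "dilution series and at least one study sample"
        )
    rng = np.random.default_rng(seed)
    n_study = n_samples - n_blanks - n_dilution

    features = [f"feat_{i + 1:03d}" for i in range(n_features)]
    study_ids = [f"study_{i + 1:03d}" for i in range(n_study)]
    blank_ids = [f"blank_{i + 1}" for i in range(n_blanks)]
    qc_ids = [f"qc_{i + 1}" for i in range(n_dilution)]
    factors = np.linspace(0.2, 1.0, n_dilution)

    base = rng.uniform(500.0, 5000.0, size=n_features)
    study = base[:, None] * (1 + 0.05 * rng.normal(size=(n_features, n_study)))
    blanks = base[:, None] / 50.0 * np.abs(1 + 0.05 * rng.normal(size=(n_features, n_blanks)))
    qc = base[:, None] * factors[None, :] * (1 + 0.02 * rng.normal(size=(n_features, n_dilution)))

    expected = 400.0 + 1.2345 * np.arange(n_features)
    observed = expected * (1 + rng.uniform(-2e-6, 2e-6, size=n_features))

    violations: dict[str, list[str]] = {}

    def _flag(i, name):
        violations.setdefault(features[i], []).append(name)

    for i in violation_spec.get("ppm", ()):
        observed[i] = expected[i] * (1 + 1e-5)  # 10 ppm off
        _flag(i, "ppm")
    for i in violation_spec.get("blank_ratio", ()):
        blanks[i] = base[i] / 2.0  # ratio ~2 < 5
        _flag(i, "blank_ratio")
    for i in violation_spec.get("zero_fraction", ()):
        n_zero = max(1, int(np.ceil(0.2 * n_study)))
        study[i, :n_zero] = 0.0
        _flag(i, "zero_fraction")
    for i in violation_spec.get("dilution_r", ()):
        qc[i] = base[i] * (1.5 - factors) * (1 + 0.02 * rng.normal(size=n_dilution))
        _flag(i, "dilution_r")

    intensities = pd.DataFrame(
        np.clip(np.hstack([study, blanks, qc]), 0.0, None),
        index=features,
        columns=study_ids + blank_ids + qc_ids,
    )
    feature_meta = pd.DataFrame(
        {"expected_mass": expected, "observed_mass": observed}, index=features
    )
    sample_meta = pd.DataFrame(
        {
            "role": ["study"] * n_study + ["blank"] * n_blanks + ["qc_dilution"] * n_dilution,
            "dilution_factor": [np.nan] * (n_study + n_blanks) + list(factors),
        },
        index=study_ids + blank_ids + qc_ids,
    )
    raw = RawFeatureTable(intensities, feature_meta, sample_meta)
    truth = GroundTruth(qc_violations=violations)
    return raw, truth
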