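import numpy as np
import pandas as pd
import pytest

from lipidpanel import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """20-child, 5-visit panel with noise, no dropout."""
    cfg = simulate.SimConfig(
        n_children=20,
        seed=7,
        n_modules=2,
        lipids_per_module=4,
        noise_sd=0.5,
        fixed_effect_sd=0.5,
    )
    panel, truth = simulate.simulate_study(cfg)
    return panel, truth


@pytest.fixture
def var_panel_ar05():
    """Univariate AR(1) panel with rho = 0.5 and fixed effects."""
    return simulate.simulate_var_panel(
        300, 5, [[0.5]], fe_sd=1.0, noise_sd=1.0, seed=11
    )


def make_exact_var_panel(a, n=50, t=5, seed=0, fixed_effects=True):
    """Panel following y_t = A y_{t-1} + c_i exactly (zero innovation)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    k = a.shape[0]
    rng = np.random.default_rng(seed)
    y = np.empty((n, t, k))
    y[:, 0] = rng.normal(size=(n, k))
    c = rng.normal(size=(n, k)) if fixed_effects else np.zeros((n, k))
    for step in range(1, t):
        y[:, step] = y[:, step - 1] @ a.T + c
    rows = []
    for i in range(n):
        for step in range(t):
            row = {"child_id": i + 1, "visit_index": step + 1}
            for j in range(k):
                row[f"y{j + 1}"] = y[i, step, j]
            rows.append(row)
    return pd.DataFrame(rows)
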