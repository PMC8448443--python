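"""Signed weighted lipid correlation network, module detection, eigenlipids.

The network is built from pairwise Pearson correlations ``s_ij`` soft
thresholded into a signed adjacency ``a_ij = ((1 + s_ij) / 2) ** beta``
(default ``beta = 18``), which suppresses weak and negative correlations
while amplifying strong positive ones. Modules come from average-linkage
hierarchical clustering of the topological-overlap dissimilarity; each
module is summarised by its eigenlipid (leading left singular vector).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

DEFAULT_BETA = 18.0
DEFAULT_MIN_MODULE_SIZE = 10
DEFAULT_CUT_FRACTION = 0.99


@dataclass
class AdjacencyMatrix:
    values: pd.DataFrame  # symmetric, entries in [0, 1], unit diagonal
    beta: float
    signed: bool = True

    @property
    def nodes(self) -> list:
        return list(self.values.index)


@dataclass
class ModulePartition:
    """Lipid -> module label; 0 means unassigned."""

    assignment: pd.Series
    min_size: int
    linkage: np.ndarray | None = None
    cut_height: float | None = None

    def members(self, label: int) -> list:
        return list(self.assignment.index[self.assignment == label])

    @property
    def module_labels(self) -> list[int]:
        return sorted(set(self.assignment) - {0})


@dataclass
class EigenlipidMatrix:
    values: pd.DataFrame  # samples x modules, columns me_<q>
    variance_explained: dict
    sign_flipped: dict = field(default_factory=dict)


def standardize(x: pd.DataFrame) -> pd.DataFrame:
    """Per-column z-score (ddof=1); constant columns become all-zero."""
    sd = x.std(ddof=1)
    sd = sd.where(sd > 0, 1.0)
    return (x - x.mean()) / sd


def signed_adjacency(x: pd.DataFrame, beta: float = DEFAULT_BETA) -> AdjacencyMatrix:
    """Signed soft-threshold adjacency from a samples x lipids matrix.

    Correlations are pairwise-complete; a constant column has undefined
    correlations which are treated as 0 with a warning.
    """
    x = pd.DataFrame(x)
    n_obs = x.notna().sum()
    if (n_obs < 3).any():
        raise ValueError("each lipid needs at least 3 non-missing values")
    s = x.corr(min_periods=3)
    if s.isna().any().any():
        warnings.warn("undefined correlations (constant column?) set to 0")
        s = s.fillna(0.0)
    a = ((1.0 + s.clip(-1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(a.values, 1.0)
    return AdjacencyMatrix(values=a, beta=float(beta))


def connectivity(adj: AdjacencyMatrix) -> pd.Series:
    """Node connectivity k_i = sum_{j != i} a_ij."""
    return adj.values.sum(axis=1) - np.diag(adj.values.values)


def scale_free_fit(adj: AdjacencyMatrix, n_bins: int = 10) -> float:
    """R^2 of the log-log connectivity-frequency fit (scale-free check).

    Returns 0 with a warning when the connectivity distribution is
    degenerate (all nodes equal) or too few populated bins remain.
    """
    k = connectivity(adj).values
    if len(k) < 20:
        raise ValueError("scale-free fit needs at least 20 nodes")
    if np.ptp(k) < 1e-12:
        warnings.warn("degenerate connectivity (all equal); r^2 reported as 0")
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float)
    centers = np.array([k[which == b].mean() if freq[b] else np.nan for b in range(n_bins)])
    ok = (freq > 0) & (centers > 0)
    if ok.sum() < 3:
        warnings.warn("fewer than 3 populated bins; r^2 reported as 0")
        return 0.0
    lx, ly = np.log10(centers[ok]), np.log10(freq[ok])
    r = np.corrcoef(lx, ly)[0, 1]
    return float(r**2)


def topological_overlap(adj: AdjacencyMatrix) -> pd.DataFrame:
    """Topological-overlap dissimilarity 1 - TOM with zero diagonal.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``.
    """
    a = adj.values.values.astype(float)
    k = a.sum(axis=1) - np.diag(a)
    shared = a @ a - 2.0 * a  # excludes u = i and u = j (unit diagonal)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    return pd.DataFrame(dissim, index=adj.values.index, columns=adj.values.columns)


def detect_modules(
    dissim: pd.DataFrame,
    min_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float | None = None,
) -> ModulePartition:
    """Average-linkage clustering of *dissim*, fixed-height cut, size pruning.

    The tree is cut at ``cut_height`` (default ``0.99 * max merge height``);
    clusters smaller than *min_size* are dissolved into module 0 and the
    surviving modules are relabeled 1, 2, ... by decreasing size.
    """
    nodes = list(dissim.index)
    if len(nodes) < min_size:
        warnings.warn(
            f"{len(nodes)} lipids < min module size {min_size}: all unassigned"
        )
        return ModulePartition(
            assignment=pd.Series(0, index=nodes), min_size=min_size
        )
    d = squareform(dissim.values, checks=False)
    link = hierarchy.linkage(d, method="average")
    if cut_height is None:
        cut_height = DEFAULT_CUT_FRACTION * link[:, 2].max()
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_size]
    order = keep.sort_values(ascending=False).index  # decreasing size
    relabel = {old: new + 1 for new, old in enumerate(order)}
    assignment = pd.Series(
        [relabel.get(c, 0) for c in raw], index=nodes, dtype=int
    )
    return ModulePartition(
        assignment=assignment, min_size=min_size, linkage=link, cut_height=cut_height
    )


def module_eigenlipids(
    x: pd.DataFrame, partition: ModulePartition, include_unassigned: bool = False
) -> EigenlipidMatrix:
    """Leading-singular-vector summary of each module, unit variance.

    Missing values are imputed with the per-lipid mean (zero after
    standardization). The eigenlipid sign is fixed so its correlation with
    the module mean profile is nonnegative; ``variance_explained`` is the
    leading share of squared singular values.
    """
    xs = standardize(pd.DataFrame(x))
    labels = partition.module_labels
    if include_unassigned and (partition.assignment == 0).any():
        labels = labels + [0]
    cols, var_exp, flips = {}, {}, {}
    for q in labels:
        members = partition.members(q)
        if len(members) < 2:
            raise ValueError(f"module {q} has fewer than 2 members")
        sub = xs[members]
        if sub.isna().any().any():
            warnings.warn(f"module {q}: missing values mean-imputed before SVD")
            sub = sub.fillna(0.0)
        u, s, _ = np.linalg.svd(sub.values, full_matrices=False)
        me = u[:, 0]
        sd = me.std(ddof=1)
        me = me / sd if sd > 0 else me
        mean_profile = sub.mean(axis=1).values
        flip = float(np.dot(me, mean_profile - mean_profile.mean())) < 0
        if flip:
            me = -me
        name = f"me_{q}" if q else "me_grey"
        cols[name] = me
        var_exp[name] = float(s[0] ** 2 / np.sum(s**2))
        flips[name] = bool(flip)
    values = pd.DataFrame(cols, index=xs.index)
    return EigenlipidMatrix(values=values, variance_explained=var_exp, sign_flipped=flips)


def module_network(me: EigenlipidMatrix) -> tuple[pd.DataFrame, list]:
    """Pairwise eigenlipid correlations as a weighted edge list.

    Returns the edge list (source, target, weight) and an average-linkage
    leaf ordering of the modules for heatmap export.
    """
    cols = list(me.values.columns)
    if len(cols) < 2:
        raise ValueError("module network needs at least 2 modules")
    corr = me.values.corr()
    edges = [
        {"source": cols[i], "target": cols[j], "weight": float(corr.iloc[i, j])}
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
    ]
    link = hierarchy.linkage(
        squareform(np.clip(1.0 - corr.values, 0.0, None), checks=False),
        method="average",
    )
    order = [cols[i] for i in hierarchy.leaves_list(link)]
    return pd.DataFrame(edges), order
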