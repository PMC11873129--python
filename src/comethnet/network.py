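"""Unsigned weighted co-methylation networks and module detection.

The network is built per brain region on residualised beta values:
adjacency a_ij = |cor(i,j)|^beta (unsigned, soft-thresholded), topological
overlap TOM_ij as similarity, average-linkage clustering of 1-TOM, a
simplified dynamic tree cut, and first-principal-component module
eigengenes. Module labels follow the conventional colour sequence with
"grey" reserved for unassigned probes.

The tree cut used here is a deliberately reproducible surrogate for the
usual dynamic cut: a static cut at the 0.99 quantile of merge heights,
re-applied recursively to any cluster larger than three times the minimum
module size, with undersized clusters sent to grey.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "MODULE_COLORS",
    "SoftThresholdReport",
    "ModuleAssignment",
    "Eigengene",
    "soft_threshold_scan",
    "adjacency_matrix",
    "tom_from_adjacency",
    "detect_modules",
    "module_eigengenes",
]

#: conventional module colour sequence (size-ordered); overflow -> moduleN
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]

GREY = "grey"


@dataclass
class SoftThresholdReport:
    table: pd.DataFrame  # power, scale_free_r2, mean_k, median_k, max_k
    selected_power: int


@dataclass
class ModuleAssignment:
    """probe -> module label; 'grey' is unassigned."""

    labels: pd.Series  # index: probe, value: module label

    @property
    def modules(self) -> list[str]:
        return [m for m in self.labels.unique() if m != GREY]

    def probes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


@dataclass
class Eigengene:
    """Per-module first-PC sample scores (unit variance, sign-oriented)."""

    scores: pd.DataFrame  # samples x modules
    variance_explained: pd.Series  # module -> share of variance


def _check_no_constant(X: np.ndarray) -> None:
    if np.any(X.std(axis=1) == 0):
        raise ValueError("constant probes present; correlation undefined")


def _abs_cor(beta: pd.DataFrame) -> np.ndarray:
    X = beta.to_numpy(float)
    _check_no_constant(X)
    return np.abs(np.corrcoef(X))


def adjacency_matrix(beta: pd.DataFrame, power: float) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency a_ij = |cor|^power, diagonal 1."""
    if beta.shape[0] < 2:
        raise ValueError("need at least 2 probes")
    A = _abs_cor(beta) ** power
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=beta.index, columns=beta.index)


def tom_from_adjacency(A: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap similarity.

    TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    is_df = isinstance(A, pd.DataFrame)
    M = A.to_numpy(float) if is_df else np.asarray(A, float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    Ad = M.copy()
    np.fill_diagonal(Ad, 0.0)
    k = Ad.sum(axis=1)
    L = Ad @ Ad  # l_ij for i != j (diagonal terms excluded below)
    # L currently includes u=i and u=j? Ad_ii=0 so u=i,j contribute 0 already
    num = L + Ad
    den = np.minimum.outer(k, k) + 1.0 - Ad
    with np.errstate(invalid="ignore", divide="ignore"):
        T = num / den
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    if is_df:
        return pd.DataFrame(T, index=A.index, columns=A.columns)
    return T


def soft_threshold_scan(
    beta: pd.DataFrame,
    powers: range | list[int] = range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Scale-free topology fit across candidate soft powers.

    For each power the connectivity distribution is binned into
    equal-occupancy bins and R^2 of log10 p(k) on log10 mean(k) measures
    scale-free fit. The selected power is the smallest one reaching
    ``r2_target``, falling back to the argmax.
    """
    if beta.shape[0] < 30:
        raise ValueError("need >= 30 probes for a degree-distribution fit")
    C = _abs_cor(beta)
    rows = []
    for p in powers:
        A = C**p
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        rows.append(
            {
                "power": int(p),
                "scale_free_r2": _scale_free_r2(k, n_bins),
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["scale_free_r2"] >= r2_target]
    if len(ok):
        selected = int(ok["power"].iloc[0])
    elif table["scale_free_r2"].notna().any():
        selected = int(table.loc[table["scale_free_r2"].idxmax(skipna=True), "power"])
    else:
        selected = int(table["power"].iloc[0])
    return SoftThresholdReport(table, selected)


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    """R² of log10 density against log10 connectivity over equal-occupancy
    bins (the density accounts for the varying bin widths)."""
    k = k[k > 0]
    if k.size < n_bins:
        return float("nan")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 4:
        return float("nan")
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    xs, ys = [], []
    for b in range(edges.size - 1):
        mask = idx == b
        width = edges[b + 1] - edges[b]
        if mask.sum() == 0 or width <= 0:
            continue
        density = mask.mean() / width
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(density))
    if len(xs) < 3 or np.std(xs) == 0 or np.std(ys) == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r**2)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def _recursive_cut(
    D: np.ndarray, idx: np.ndarray, min_size: int, quantile: float = 0.99
) -> list[np.ndarray]:
    """Static cut at the ``quantile`` of merge heights, recursing into any
    cluster larger than 3x min_size. Returns index groups."""
    if idx.size <= max(2, 3 * min_size):
        return [idx]
    sub = D[np.ix_(idx, idx)]
    Z = average(squareform(sub, checks=False))
    h = float(np.quantile(Z[:, 2], quantile))
    labels = fcluster(Z, t=h, criterion="distance")
    groups = [idx[labels == g] for g in np.unique(labels)]
    if len(groups) == 1:
        return groups
    out: list[np.ndarray] = []
    for g in groups:
        if g.size > 3 * min_size:
            out.extend(_recursive_cut(D, g, min_size, quantile))
        else:
            out.append(g)
    return out


def _partition_blocks(
    beta: pd.DataFrame, max_block: int, seed: int = 0
) -> list[np.ndarray]:
    """Pre-partition probes into blocks <= max_block by k-means on the top-8
    principal-component loadings of the probe correlation structure."""
    from sklearn.cluster import KMeans

    n = beta.shape[0]
    if n <= max_block:
        return [np.arange(n)]
    X = beta.to_numpy(float)
    Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    r = min(8, U.shape[1])
    load = U[:, :r] * s[:r]
    k = int(np.ceil(n / max_block))
    km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(load)
    blocks = [np.flatnonzero(km.labels_ == c) for c in range(k)]
    # rebalance oversized blocks deterministically
    out: list[np.ndarray] = []
    for b in blocks:
        for start in range(0, b.size, max_block):
            out.append(b[start : start + max_block])
    return [b for b in out if b.size]


def detect_modules(
    beta: pd.DataFrame,
    power: float,
    min_size: int = 100,
    max_block: int = 10_000,
    merge_cut: float = 0.15,
    kme_min: float = 0.3,
) -> ModuleAssignment:
    """Blockwise unsigned module detection.

    Probes are pre-partitioned into blocks of at most ``max_block``; within
    each block 1-TOM is clustered by average linkage and cut by the
    simplified dynamic rule; clusters below ``min_size`` go to grey;
    probes whose absolute correlation with their cluster's eigengene falls
    below ``kme_min`` are scattered leaves and also go to grey (the analogue
    of the dynamic cut's core criterion); modules whose eigengenes correlate
    above 1-``merge_cut`` are merged; final labels are colour names in
    decreasing size order.
    """
    n = beta.shape[0]
    if min_size > n:
        raise ValueError("min_size exceeds number of probes")
    labels = pd.Series(GREY, index=beta.index, dtype=object)
    next_id = 0
    for block in _partition_blocks(beta, max_block):
        if block.size < max(2, min_size):
            continue  # block too small to host a module; stays grey
        sub = beta.iloc[block]
        A = adjacency_matrix(sub, power).to_numpy()
        D = 1.0 - np.asarray(tom_from_adjacency(A))
        np.fill_diagonal(D, 0.0)
        groups = _recursive_cut(D, np.arange(sub.shape[0]), min_size)
        for g in groups:
            if g.size >= min_size:
                labels.iloc[block[g]] = f"tmp{next_id}"
                next_id += 1
    labels = _kme_cleanup(beta, labels, kme_min, min_size)
    labels = _merge_close_modules(beta, labels, merge_cut, min_size)
    return ModuleAssignment(_relabel_by_size(labels))


def _kme_cleanup(
    beta: pd.DataFrame, labels: pd.Series, kme_min: float, min_size: int
) -> pd.Series:
    """Send probes weakly correlated with their module eigengene to grey;
    modules dropping below min_size dissolve entirely."""
    if kme_min <= 0:
        return labels
    labels = labels.copy()
    mods = [m for m in labels.unique() if m != GREY]
    if not mods:
        return labels
    me = module_eigengenes(beta, ModuleAssignment(labels)).scores
    for m in mods:
        probes = labels.index[labels == m]
        X = beta.loc[probes].to_numpy(float)
        e = me[m].to_numpy()
        Xc = X - X.mean(axis=1, keepdims=True)
        ec = e - e.mean()
        denom = np.sqrt((Xc**2).sum(axis=1) * (ec**2).sum())
        denom[denom == 0] = np.inf
        kme = np.abs(Xc @ ec) / denom
        weak = probes[kme < kme_min]
        labels[weak] = GREY
        if (labels == m).sum() < min_size:
            labels[labels == m] = GREY
    return labels


def _merge_close_modules(
    beta: pd.DataFrame, labels: pd.Series, merge_cut: float, min_size: int
) -> pd.Series:
    threshold = 1.0 - merge_cut
    labels = labels.copy()
    for _ in range(100):
        mods = [m for m in labels.unique() if m != GREY]
        if len(mods) < 2:
            break
        me = module_eigengenes(beta, ModuleAssignment(labels)).scores
        C = np.corrcoef(me.to_numpy().T)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] <= threshold:
            break
        a, b = me.columns[i], me.columns[j]
        labels[labels == b] = a
    return labels


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != GREY].value_counts()
    mapping = {}
    for rank, (old, _) in enumerate(sizes.items()):
        mapping[old] = (
            MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        )
    return labels.map(lambda m: mapping.get(m, GREY))


def module_eigengenes(
    beta: pd.DataFrame, assignment: ModuleAssignment
) -> Eigengene:
    """First-PC sample scores per module.

    Probes are standardised, the first right singular vector gives the
    sample scores (scaled to unit variance) and the sign is oriented so the
    eigengene correlates non-negatively with the module's mean standardised
    profile. variance_explained is the share of the first eigenvalue.
    """
    scores: dict[str, np.ndarray] = {}
    varexp: dict[str, float] = {}
    for module in assignment.modules:
        probes = assignment.probes_in(module)
        X = beta.loc[probes].to_numpy(float)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Xs = (X - X.mean(axis=1, keepdims=True)) / sd
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        v = Vt[0]
        mean_profile = Xs.mean(axis=0)
        if mean_profile.std() > 0:
            c = np.corrcoef(v, mean_profile)[0, 1]
            if np.isfinite(c) and c < 0:
                v = -v
        v_sd = v.std(ddof=1)
        scores[module] = v / v_sd if v_sd > 0 else v
        total = float((s**2).sum())
        varexp[module] = float(s[0] ** 2 / total) if total > 0 else 0.0
    score_df = pd.DataFrame(scores, index=beta.columns)
    return Eigengene(score_df, pd.Series(varexp, dtype=float))
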