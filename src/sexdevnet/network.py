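"""Weighted co-expression network construction and topology.

Links are unsigned power-transformed correlations a_ij = |cor(x_i, x_j)|^beta
with beta chosen by the scale-free topology criterion (smallest power whose
degree distribution fits a power law with R^2 above a target).  Clusters come
from average-linkage hierarchical clustering of topological-overlap
dissimilarity with a fixed-height cut, or are supplied externally.  Node
statistics (connection density Kd, weighted clustering coefficient CC, hub
score Kd*(1-CC)) are computed within each node's cluster, so they describe
local regulatory structure rather than whole-network position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import squareform

UNASSIGNED = "grey"

# colour-style cluster labels, assigned by decreasing cluster size
_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


def _color_name(i: int) -> str:
    return _COLORS[i] if i < len(_COLORS) else f"module{i}"


def biweight_midcorrelation(x: np.ndarray) -> np.ndarray:
    """Row-wise biweight midcorrelation matrix (robust correlation).

    Rows with zero median absolute deviation fall back to ordinary
    standardisation; zero-variance rows get correlation 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    bad_mad = (mad == 0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (x - med) / (9.0 * mad)
    w = (1 - u**2) ** 2 * (np.abs(u) < 1)
    xt = (x - med) * w
    if bad_mad.any():
        # fall back to mean/SD standardisation for those rows
        mu = x[bad_mad].mean(axis=1, keepdims=True)
        xt[bad_mad] = x[bad_mad] - mu
    norm = np.sqrt((xt**2).sum(axis=1, keepdims=True))
    zero_var = (norm == 0).ravel()
    if zero_var.any():
        warnings.warn(f"{zero_var.sum()} zero-variance node(s); correlations set to 0")
        norm[zero_var] = 1.0
    z = xt / norm
    r = z @ z.T
    r[zero_var, :] = 0.0
    r[:, zero_var] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0, out=r)


def pearson_correlation(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x)
    if zero_var.any():
        warnings.warn(f"{zero_var.sum()} zero-variance node(s); correlations set to 0")
        r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0, out=r)


@dataclass
class Adjacency:
    """Symmetric node x node weights |r|^beta with zero diagonal."""

    weights: np.ndarray
    node_ids: list[str]
    beta: int
    method: str = "bicor"


def _abs_power(r: np.ndarray, beta: int) -> np.ndarray:
    """|r|^beta via binary exponentiation (fast for large integer beta)."""
    b = int(beta)
    if b % 2 == 0:
        a = r * r  # even powers never need the absolute value
        b //= 2
    else:
        a = np.abs(r)
    out = None
    while b > 0:
        if b & 1:
            if out is None:
                out = a.copy()
            else:
                out *= a
        b >>= 1
        if b:
            a *= a
    return out


def correlation_adjacency(
    values,
    beta: int,
    sample_subset: list[str] | None = None,
    method: str = "bicor",
    node_ids: list[str] | None = None,
) -> Adjacency:
    """Unsigned weighted adjacency a_ij = |cor|^beta (diagonal zeroed).

    ``values`` is a node x sample DataFrame (or array with ``node_ids``);
    ``sample_subset`` restricts the correlation to those sample columns.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if isinstance(values, pd.DataFrame):
        ids = values.index.to_list()
        mat = values[sample_subset].to_numpy() if sample_subset else values.to_numpy()
    else:
        ids = node_ids or [str(i) for i in range(len(values))]
        mat = np.asarray(values)
        if sample_subset is not None:
            mat = mat[:, sample_subset]
    if mat.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    corr = biweight_midcorrelation(mat) if method == "bicor" else pearson_correlation(mat)
    a = _abs_power(corr, beta)
    np.fill_diagonal(a, 0.0)
    return Adjacency(weights=a, node_ids=ids, beta=int(beta), method=method)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """(R^2, slope) of log10 frequency vs log10 mean-degree over degree bins."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq, mean_k = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() > 0 and k[sel].mean() > 0:
            freq.append(sel.mean())
            mean_k.append(k[sel].mean())
    if len(freq) < 3:
        return 0.0, 0.0
    lx, ly = np.log10(mean_k), np.log10(freq)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    return float(r2), float(slope)


def select_soft_power(
    values,
    candidate_betas=tuple(range(1, 31)),
    r2_target: float = 0.8,
    method: str = "bicor",
) -> int:
    """Smallest power whose degree distribution is scale-free (R^2 >= target).

    Falls back to the candidate maximising R^2 (with a warning) when no
    candidate meets the criterion with a negative slope.
    """
    candidate_betas = list(candidate_betas)
    if len(candidate_betas) < 2:
        raise ValueError("need >= 2 candidate powers")
    mat = values.to_numpy() if isinstance(values, pd.DataFrame) else np.asarray(values)
    corr = biweight_midcorrelation(mat) if method == "bicor" else pearson_correlation(mat)
    np.fill_diagonal(corr, 0.0)
    absr = np.abs(corr)
    best, best_r2 = None, -np.inf
    for beta in candidate_betas:
        k = _abs_power(absr, int(beta)).sum(axis=1)
        r2, slope = scale_free_fit(k)
        if slope < 0 and r2 >= r2_target:
            return int(beta)
        if r2 > best_r2:
            best, best_r2 = int(beta), r2
    warnings.warn(
        f"no candidate power reached scale-free R^2 {r2_target}; "
        f"returning argmax R^2 ({best}, R^2={best_r2:.3f})"
    )
    return best


def topological_overlap(adj: Adjacency) -> np.ndarray:
    """Topological overlap matrix of an adjacency with zero diagonal."""
    a = adj.weights
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_clusters(
    adj: Adjacency,
    method: str = "tom-hierarchical",
    labels: pd.Series | None = None,
    cut_height: float | None = None,
    min_size: int = 10,
) -> pd.Series:
    """Assign every node to a cluster label.

    ``tom-hierarchical`` clusters 1 - TOM with average linkage and a fixed
    height cut (default 0.99 of the maximum merge height); branches below
    ``min_size`` go to the unassigned label.  ``provided`` passes supplied
    labels through after checking full coverage.  Labels are colour-style
    names ordered by decreasing cluster size.
    """
    if method == "provided":
        if labels is None:
            raise ValueError("method='provided' requires labels")
        missing = set(adj.node_ids) - set(labels.index)
        if missing:
            raise ValueError(f"labels missing for {len(missing)} node(s)")
        return labels.loc[adj.node_ids]
    tom = topological_overlap(adj)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2
    z = linkage(squareform(dissim, checks=False), method="average")
    h = cut_height if cut_height is not None else 0.99 * z[:, 2].max()
    raw = fcluster(z, t=h, criterion="distance")
    out = pd.Series(UNASSIGNED, index=pd.Index(adj.node_ids, name="node_id"))
    sizes = pd.Series(raw).value_counts()
    big = [c for c in sizes.index if sizes[c] >= min_size]
    big.sort(key=lambda c: -sizes[c])
    for rank, c in enumerate(big):
        out.iloc[np.flatnonzero(raw == c)] = _color_name(rank)
    return out


def node_topology(adj: Adjacency, clusters: pd.Series) -> pd.DataFrame:
    """Within-cluster Kd, clustering coefficient and hub score per node.

    Kd_i = k_i / (N - 1) with k_i the node's summed within-cluster weight;
    CC_i is the Zhang-Horvath weighted clustering coefficient
    sum_{j!=l} a_ij a_jl a_li / ((sum_j a_ij)^2 - sum_j a_ij^2);
    Hub_i = Kd_i * (1 - CC_i), so a hub score never exceeds Kd.
    Nodes in clusters of size < 2 (and unassigned nodes) are flagged with
    NaN statistics.
    """
    ids = np.array(adj.node_ids)
    lab = clusters.loc[ids].to_numpy()
    out = pd.DataFrame(
        {"cluster": lab, "k": np.nan, "Kd": np.nan, "CC": np.nan, "Hub": np.nan},
        index=pd.Index(ids, name="node_id"),
    )
    for c in pd.unique(lab):
        if c == UNASSIGNED:
            continue
        idx = np.flatnonzero(lab == c)
        n = len(idx)
        if n < 2:
            continue
        a = adj.weights[np.ix_(idx, idx)]
        k = a.sum(axis=1)
        kd = k / (n - 1)
        num = np.einsum("ij,jl,li->i", a, a, a)
        denom = k**2 - (a**2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cc = np.where(denom > 0, num / denom, 0.0)
        if n < 3:
            cc = np.zeros(n)
        out.iloc[idx, out.columns.get_loc("k")] = k
        out.iloc[idx, out.columns.get_loc("Kd")] = kd
        out.iloc[idx, out.columns.get_loc("CC")] = cc
        out.iloc[idx, out.columns.get_loc("Hub")] = kd * (1 - cc)
    return out


def cluster_topology(
    adj: Adjacency,
    clusters: pd.Series,
    node_meta: pd.DataFrame | None = None,
    duplicated_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-cluster topology statistics.

    density = mean off-diagonal within-cluster weight; centralization =
    (N/(N-2)) * (max Kd - density); heterogeneity = coefficient of variation
    of within-cluster degree; median CC; diameter = longest shortest path
    under edge length 1 - a.  Splicing and duplicated-gene node proportions
    are normalised by their network-wide shares (``node_meta`` provides node
    kinds and gene ids).  Clusters of size < 3 get NaN diameter and
    centralization, flagged via the ``small`` column.
    """
    ids = np.array(adj.node_ids)
    lab = clusters.loc[ids].to_numpy()
    ntop = node_topology(adj, clusters)

    if node_meta is not None:
        meta = node_meta.set_index("node_id").loc[ids]
        is_splice = (meta["kind"] == "splicing").to_numpy()
        if duplicated_genes is None:
            duplicated_genes = set()
        is_dup = np.array(
            [
                any(g in duplicated_genes for g in str(gs).split(","))
                for gs in meta["gene_id"]
            ]
        )
        net_splice = is_splice.mean()
        net_dup = is_dup.mean()
    rows = []
    for c in pd.unique(lab):
        if c == UNASSIGNED:
            continue
        idx = np.flatnonzero(lab == c)
        n = len(idx)
        a = adj.weights[np.ix_(idx, idx)]
        k = a.sum(axis=1)
        density = a.sum() / (n * (n - 1)) if n > 1 else np.nan
        kd = ntop.iloc[idx]["Kd"].to_numpy()
        cc = ntop.iloc[idx]["CC"].to_numpy()
        small = n < 3
        if small:
            central, diam = np.nan, np.nan
        else:
            central = (n / (n - 2)) * (np.nanmax(kd) - density)
            d = np.clip(1.0 - a, 0.0, None)
            np.fill_diagonal(d, 0.0)
            sp = shortest_path(d, method="D", directed=False)
            diam = float(np.max(sp[np.isfinite(sp)]))
        het = k.std() / k.mean() if k.mean() > 0 else np.nan
        row = {
            "cluster": c,
            "size": n,
            "density": density,
            "centralization": central,
            "heterogeneity": het,
            "median_cc": float(np.nanmedian(cc)),
            "diameter": diam,
            "small": small,
        }
        if node_meta is not None:
            row["prop_splicing"] = (
                is_splice[idx].mean() / net_splice if net_splice > 0 else np.nan
            )
            row["prop_duplicated"] = (
                is_dup[idx].mean() / net_dup if net_dup > 0 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")
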