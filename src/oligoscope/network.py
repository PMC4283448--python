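"""Co-occurrence networks from Whittaker's index of association (IA).

Oligotype abundance profiles are percentage-scaled per oligotype; for a
pair, IA = 100 − ½ Σ_s |p_s − q_s|, so proportional profiles score 100 and
profiles with disjoint site support score 0.  Edges join oligotype pairs
with IA > 85 whose permutation p-value (independent shuffling of the site
order within every profile, 200 permutations, BH-corrected over all pairs)
stays below 0.05.  The graph is summarised with standard topology
statistics and partitioned by Markov clustering (inflation 2.5) after the
IA edge weights are rescaled from [85, 100] down to [0.001, 0.15].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from oligoscope.ordination import fdr_bh


class UndefinedIAError(ValueError):
    """Raised when a profile has zero total abundance."""


def _percent_profiles(table: np.ndarray) -> np.ndarray:
    totals = table.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise UndefinedIAError("zero-total abundance vector")
    return 100.0 * table / totals


def index_of_association(x, y) -> float:
    """Whittaker's IA between two abundance profiles (0–100 scale)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must share a site set")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("profiles must be non-negative")
    p, q = _percent_profiles(np.vstack([x, y]))
    return float(100.0 - 0.5 * np.abs(p - q).sum())


def ia_matrix(table: np.ndarray) -> np.ndarray:
    """All pairwise IA values of a rows-by-sites count table."""
    p = _percent_profiles(np.asarray(table, dtype=float))
    return 100.0 - 0.5 * squareform(pdist(p, metric="cityblock"))


def ia_null(
    table, n_perm: int = 200, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permutation null for all pairwise IA values.

    Each permutation independently shuffles the site order within every
    row and recomputes all pairwise IA values.  Per pair,
    p = #{IA_perm ≥ IA_obs} / n_perm, so a profile pair that beats every
    permutation scores p = 0 — with only 200 permutations and a
    Benjamini–Hochberg family spanning every unordered pair, a strictly
    positive floor (the add-one rule) would leave no pair able to clear
    an FDR threshold of 0.05 in tables beyond a few dozen rows.  BH
    adjustment is applied over all unordered pairs.  Returns
    (ia_obs, p, p_adjusted) as square symmetric matrices (diagonal p set
    to 1).
    """
    table = np.asarray(table, dtype=float)
    n = table.shape[0]
    if n < 2:
        raise ValueError("need at least 2 oligotype rows")
    rng = np.random.default_rng(seed)
    obs = ia_matrix(table)
    iu = np.triu_indices(n, k=1)
    obs_pairs = obs[iu]
    count = np.zeros_like(obs_pairs)
    p_profiles = _percent_profiles(table)
    for _ in range(n_perm):
        perm = np.array([rng.permutation(table.shape[1]) for _ in range(n)])
        shuffled = np.take_along_axis(p_profiles, perm, axis=1)
        ia_p = 100.0 - 0.5 * squareform(pdist(shuffled, metric="cityblock"))
        count += ia_p[iu] >= obs_pairs
    p_pairs = count / n_perm
    padj_pairs = fdr_bh(p_pairs)
    p = np.ones((n, n))
    padj = np.ones((n, n))
    p[iu] = p_pairs
    padj[iu] = padj_pairs
    p.T[iu] = p_pairs
    padj.T[iu] = padj_pairs
    return obs, p, padj


def build_graph(
    counts: pd.DataFrame,
    ia: np.ndarray,
    p_adjusted: np.ndarray,
    ia_min: float = 85.0,
    alpha: float = 0.05,
    min_abundance: int = 2,
    node_meta: pd.DataFrame | None = None,
) -> nx.Graph:
    """Assemble the IA association graph.

    Nodes are oligotypes (rows of ``counts``) with total read count at
    least ``min_abundance``; an undirected edge joins a pair when
    IA > ``ia_min`` and adjusted p < ``alpha``, weighted by the IA value.
    ``node_meta`` (same index) may carry taxonomy columns copied onto
    nodes.
    """
    totals = counts.sum(axis=1)
    eligible = totals[totals >= min_abundance].index
    pos = {name: i for i, name in enumerate(counts.index)}
    g = nx.Graph()
    for name in eligible:
        attrs = {"abundance": int(totals[name])}
        if node_meta is not None and name in node_meta.index:
            attrs.update(
                {k: v for k, v in node_meta.loc[name].items() if pd.notna(v)}
            )
        g.add_node(name, **attrs)
    names = list(eligible)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            i, j = pos[names[a]], pos[names[b]]
            if ia[i, j] > ia_min and p_adjusted[i, j] < alpha:
                g.add_edge(
                    names[a],
                    names[b],
                    weight=float(ia[i, j]),
                    ia=float(ia[i, j]),
                    p_adjusted=float(p_adjusted[i, j]),
                )
    return g


# ---------------------------------------------------------------------------
# topology statistics


@dataclass
class NetworkStats:
    """Summary topology of an association graph."""

    n_nodes: int
    n_edges: int
    density: float
    clustering_coefficient: float
    heterogeneity: float
    centralization: float | None
    mean_neighbors: float
    n_components: int
    component_sizes: list[int]
    powerlaw_coefficient: float | None
    powerlaw_exponent: float | None

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "clustering_coefficient": self.clustering_coefficient,
            "heterogeneity": self.heterogeneity,
            "centralization": self.centralization,
            "mean_neighbors": self.mean_neighbors,
            "n_components": self.n_components,
            "component_sizes": self.component_sizes,
            "powerlaw_coefficient": self.powerlaw_coefficient,
            "powerlaw_exponent": self.powerlaw_exponent,
        }


def fit_degree_powerlaw(degrees) -> tuple[float, float] | None:
    """Least-squares fit y = a·x^b of the raw degree histogram (log–log).

    Returns (a, b) or None when fewer than two distinct positive degrees
    exist.  This mirrors the NetworkAnalyzer-style fit on unbinned degree
    counts and is approximate by nature.
    """
    degrees = np.asarray(degrees)
    degrees = degrees[degrees > 0]
    if degrees.size == 0:
        return None
    vals, counts = np.unique(degrees, return_counts=True)
    if vals.size < 2:
        return None
    slope, intercept = np.polyfit(np.log10(vals), np.log10(counts), 1)
    return float(10**intercept), float(slope)


def network_stats(g: nx.Graph) -> NetworkStats:
    """Topology summary: density, clustering, heterogeneity, centralization.

    density = 2E/(N(N−1)); clustering is the mean local clustering
    coefficient (degree-<2 nodes contribute 0); heterogeneity is the
    coefficient of variation of the degrees; centralization is
    [N/(N−2)]·[k_max/(N−1) − density] (undefined for N < 3).
    """
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("need at least one node")
    e = g.number_of_edges()
    degrees = np.array([d for _, d in g.degree()])
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    clustering = float(np.mean(list(nx.clustering(g).values())))
    mean_deg = degrees.mean()
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0
    centralization = (
        float((n / (n - 2)) * (degrees.max() / (n - 1) - density)) if n >= 3 else None
    )
    comps = [len(c) for c in nx.connected_components(g)]
    fit = fit_degree_powerlaw(degrees)
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        density=float(density),
        clustering_coefficient=clustering,
        heterogeneity=heterogeneity,
        centralization=centralization,
        mean_neighbors=float(2 * e / n),
        n_components=len(comps),
        component_sizes=sorted(comps, reverse=True),
        powerlaw_coefficient=None if fit is None else fit[0],
        powerlaw_exponent=None if fit is None else fit[1],
    )


# ---------------------------------------------------------------------------
# Markov clustering


@dataclass(frozen=True)
class MCLParams:
    """Markov-cluster parameters.

    ``inflation`` is the granularity parameter; IA edge weights are
    linearly rescaled from ``ia_interval`` to ``weight_rescale_interval``
    before clustering, which keeps the stochastic matrix well conditioned.
    """

    inflation: float = 2.5
    ia_interval: tuple[float, float] = (85.0, 100.0)
    weight_rescale_interval: tuple[float, float] = (0.001, 0.15)
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if not self.weight_rescale_interval[0] < self.weight_rescale_interval[1]:
            raise ValueError("rescale interval must be increasing")


class ConvergenceError(RuntimeError):
    pass


def rescale_edge_weights(ia_values, params: MCLParams | None = None) -> np.ndarray:
    """Map IA values linearly from [85, 100] onto [0.001, 0.15]."""
    if params is None:
        params = MCLParams()
    ia = np.asarray(ia_values, dtype=float)
    lo, hi = params.ia_interval
    w_lo, w_hi = params.weight_rescale_interval
    if (ia < lo).any() or (ia > hi).any():
        raise ValueError(f"IA values must lie within [{lo}, {hi}]")
    return w_lo + (ia - lo) / (hi - lo) * (w_hi - w_lo)


def _mcl_matrix(m: np.ndarray, params: MCLParams) -> np.ndarray:
    """Run the expansion/inflation iteration on a weight matrix."""
    n = m.shape[0]
    m = m.astype(float).copy()
    np.fill_diagonal(m, 0.0)
    # self-loop = node's maximum incident weight (regularisation)
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(m, loops)
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(params.max_iterations):
        expanded = m @ m
        inflated = expanded**params.inflation
        inflated[inflated < params.prune_threshold] = 0.0
        colsums = inflated.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        inflated /= colsums
        if np.abs(inflated - m).max() < params.tolerance:
            return inflated
        m = inflated
    raise ConvergenceError(
        f"MCL did not converge in {params.max_iterations} iterations"
    )


def _clusters_from_matrix(m: np.ndarray) -> list[set[int]]:
    """Read clusters off the attractors of a converged MCL matrix."""
    n = m.shape[0]
    attractors = [i for i in range(n) if m[i, i] > 1e-9]
    raw: list[set[int]] = []
    for a in attractors:
        members = set(np.flatnonzero(m[a] > 1e-9).tolist()) | {a}
        raw.append(members)
    # merge attractor rows that share members (one attractor system)
    merged: list[set[int]] = []
    for cl in raw:
        hit = [i for i, m2 in enumerate(merged) if m2 & cl]
        for i in reversed(hit):
            cl |= merged.pop(i)
        merged.append(cl)
    assigned = set().union(*merged) if merged else set()
    # orphaned nodes (pruned everywhere): attach to heaviest attractor column
    for node in range(n):
        if node not in assigned:
            col = m[:, node]
            if col.max() > 0:
                best = int(np.argmax(col))
                for cl in merged:
                    if best in cl:
                        cl.add(node)
                        break
                else:
                    merged.append({node})
            else:
                merged.append({node})
    # resolve any overlap to the heaviest attractor column value
    seen: dict[int, int] = {}
    for ci, cl in enumerate(merged):
        for node in list(cl):
            if node in seen and seen[node] != ci:
                prev = merged[seen[node]]
                w_prev = max(m[a, node] for a in prev)
                w_cur = max(m[a, node] for a in cl)
                if w_cur > w_prev:
                    prev.discard(node)
                    seen[node] = ci
                else:
                    cl.discard(node)
            else:
                seen[node] = ci
    return [cl for cl in merged if cl]


def mcl(
    g: nx.Graph, params: MCLParams | None = None, rescale: bool = True
) -> list[set]:
    """Markov clustering of a weighted association graph.

    Edge weights (IA values when ``rescale`` is true) feed a
    column-stochastic matrix with max-incident-weight self-loops; the
    expansion (matrix square) / inflation (entrywise power, renormalise)
    iteration runs with pruning until idempotence.  Returns a partition of
    the node set as a list of node-label sets, largest first.
    """
    if params is None:
        params = MCLParams()
    nodes = list(g.nodes())
    n = len(nodes)
    if n == 0:
        return []
    if n == 1:
        return [set(nodes)]
    w = np.zeros((n, n))
    index = {v: i for i, v in enumerate(nodes)}
    for a, b, data in g.edges(data=True):
        val = data.get("weight", 1.0)
        if rescale:
            val = float(rescale_edge_weights([val], params)[0])
        w[index[a], index[b]] = w[index[b], index[a]] = val
    converged = _mcl_matrix(w, params)
    clusters = _clusters_from_matrix(converged)
    out = [set(nodes[i] for i in cl) for cl in clusters]
    return sorted(out, key=len, reverse=True)


def cluster_summary(
    clusters: list[set], node_meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster size, abundance and taxonomic breadth, largest first.

    ``node_meta`` is indexed by node label with columns ``abundance`` and
    (optionally) ``phylum`` and ``class``.
    """
    rows = []
    for ci, cl in enumerate(sorted(clusters, key=len, reverse=True), start=1):
        sub = node_meta.loc[sorted(cl)]
        ab = sub["abundance"].astype(float)
        rows.append(
            {
                "cluster": ci,
                "n_oligotypes": len(cl),
                "mean_abundance": round(float(ab.mean()), 2),
                "max_abundance": int(ab.max()),
                "n_phyla": int(sub["phylum"].nunique()) if "phylum" in sub else 0,
                "n_classes": int(sub["class"].nunique()) if "class" in sub else 0,
            }
        )
    cols = [
        "cluster",
        "n_oligotypes",
        "mean_abundance",
        "max_abundance",
        "n_phyla",
        "n_classes",
    ]
    return (
        pd.DataFrame(rows, columns=cols).set_index("cluster")
        if rows
        else pd.DataFrame(columns=cols[1:], index=pd.Index([], name="cluster"))
    )
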