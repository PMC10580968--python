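"""SparCC compositional correlation networks, topology, and node roles.

SparCC estimates linear ("basis") correlations between taxa from
compositional counts.  For taxa i, j the log-ratio variance
t_ij = var(log(x_i / x_j)) decomposes as
t_ij = w_i^2 + w_j^2 - 2 rho_ij w_i w_j.  Under the sparsity assumption
(most rho = 0) the basis variances w^2 solve the linear system
[(D - 2) I + 1 1'] w^2 = row-sums(T); correlations follow by inversion and
are refined by iteratively excluding the strongest-correlated pairs from
the system.  Fractions are resampled from a Dirichlet posterior
(counts + 1) and the final r is the median over draws.

The network keeps edges with |r| > 0.6 and permutation P < 0.05 (the
absolute-value rule retains negative associations; ``positive_only``
restores the literal one-sided reading).  Hubs are nodes in the top 30% of
both degree and betweenness; keystones combine top-30% degree and closeness
with bottom-30% betweenness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .tables import OTUTable, relative_abundance

logger = logging.getLogger(__name__)


def prevalence_filter(table: OTUTable, min_relab: float = 0.001) -> OTUTable:
    """Keep OTUs whose max per-sample relative abundance exceeds min_relab
    (strict >)."""
    relab = relative_abundance(table)
    keep = relab.max(axis=0) > min_relab
    return OTUTable(table.counts.loc[:, keep].copy())


# ---------------------------------------------------------------------------
# SparCC core
# ---------------------------------------------------------------------------

def log_ratio_variance_matrix(fractions: np.ndarray) -> np.ndarray:
    """T with t_ij = var(log(x_i / x_j)) across samples (n x D fractions)."""
    logs = np.log(fractions)
    cov = np.cov(logs, rowvar=False)
    var = np.diag(cov)
    return var[:, None] + var[None, :] - 2.0 * cov


def basis_variances(t: np.ndarray,
                    excluded: set[tuple[int, int]] | None = None) -> np.ndarray:
    """Solve the sparsity-approximation linear system for basis variances.

    ``excluded`` pairs are removed from the row sums and from the
    coefficient matrix (each exclusion of (i, j) decrements M[i,i], M[j,j],
    M[i,j] and M[j,i]).
    """
    d = t.shape[0]
    M = np.ones((d, d)) + (d - 2) * np.eye(d)
    t_row = t.sum(axis=1).astype(float)
    if excluded:
        for i, j in excluded:
            t_row[i] -= t[i, j]
            t_row[j] -= t[i, j]
            M[i, i] -= 1
            M[j, j] -= 1
            M[i, j] -= 1
            M[j, i] -= 1
    omega2 = np.linalg.solve(M, t_row)
    return np.clip(omega2, 1e-12, None)


def correlations_from_basis(t: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    omega = np.sqrt(omega2)
    rho = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(omega, omega))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _sparcc_single(fractions: np.ndarray, n_exclusion_iters: int,
                   exclusion_threshold: float) -> np.ndarray:
    """One SparCC pass on a fractions matrix (samples x taxa)."""
    t = log_ratio_variance_matrix(fractions)
    excluded: set[tuple[int, int]] = set()
    omega2 = basis_variances(t)
    rho = correlations_from_basis(t, omega2)
    for _ in range(n_exclusion_iters):
        mask = np.abs(rho.copy())
        np.fill_diagonal(mask, 0.0)
        for i, j in excluded:
            mask[i, j] = mask[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(mask), mask.shape)
        if mask[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        omega2 = basis_variances(t, excluded)
        rho = correlations_from_basis(t, omega2)
    return rho


def sparcc_correlations(table: OTUTable, n_dirichlet: int = 20,
                        n_exclusion_iters: int = 10,
                        exclusion_threshold: float = 0.1,
                        seed: int = 0) -> pd.DataFrame:
    """Median SparCC correlation matrix over Dirichlet fraction draws."""
    counts = table.counts.to_numpy(dtype=float)
    n, d = counts.shape
    if d < 4:
        raise ValueError("SparCC needs at least 4 OTUs")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("all-zero OTU present; apply prevalence_filter first")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_dirichlet, d, d))
    alpha = counts + 1.0
    for k in range(n_dirichlet):
        fractions = np.vstack([rng.dirichlet(alpha[i]) for i in range(n)])
        draws[k] = _sparcc_single(fractions, n_exclusion_iters,
                                  exclusion_threshold)
    r = np.median(draws, axis=0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=table.otu_ids, columns=table.otu_ids)


def sparcc_pvalues(table: OTUTable, r_obs: pd.DataFrame, n_perm: int = 100,
                   seed: int = 0, n_dirichlet: int = 5,
                   n_exclusion_iters: int = 10,
                   exclusion_threshold: float = 0.1) -> pd.DataFrame:
    """Two-sided permutation pseudo-p per pair.

    Each OTU's counts are permuted across samples independently, r is
    recomputed, and p = (#{|r_perm| >= |r_obs|} + 1) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    n, d = counts.shape
    r_obs_v = np.abs(r_obs.to_numpy())
    exceed = np.zeros((d, d))
    for _ in range(n_perm):
        shuffled = np.empty_like(counts)
        for j in range(d):
            shuffled[:, j] = counts[rng.permutation(n), j]
        perm_table = OTUTable(pd.DataFrame(
            shuffled, index=table.counts.index, columns=table.counts.columns))
        r_perm = sparcc_correlations(
            perm_table, n_dirichlet=n_dirichlet,
            n_exclusion_iters=n_exclusion_iters,
            exclusion_threshold=exclusion_threshold,
            seed=int(rng.integers(2 ** 31))).to_numpy()
        exceed += (np.abs(r_perm) >= r_obs_v)
    p = (exceed + 1.0) / (n_perm + 1.0)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=r_obs.index, columns=r_obs.columns)


# ---------------------------------------------------------------------------
# network construction and topology
# ---------------------------------------------------------------------------

def build_network(r: pd.DataFrame, p: pd.DataFrame, r_min: float = 0.6,
                  p_max: float = 0.05,
                  positive_only: bool = False,
                  node_abundance: pd.Series | None = None) -> nx.Graph:
    """Filtered undirected graph: edge iff |r| > r_min and p < p_max.

    Isolated nodes (no retained edge) are dropped from the graph and logged.
    """
    g = nx.Graph()
    ids = list(r.index)
    rv, pv = r.to_numpy(), p.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            strength = rv[i, j] if positive_only else abs(rv[i, j])
            if strength > r_min and pv[i, j] < p_max:
                g.add_edge(ids[i], ids[j], r=float(rv[i, j]),
                           p=float(pv[i, j]),
                           sign="+" if rv[i, j] > 0 else "-")
    isolated = set(ids) - set(g.nodes)
    if isolated:
        logger.info("%d nodes isolated after filtering", len(isolated))
    if node_abundance is not None:
        for node in g.nodes:
            g.nodes[node]["relative_abundance"] = float(node_abundance[node])
    return g


def node_metrics(g: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness, harmonic closeness, clustering, component id."""
    nodes = list(g.nodes)
    if not nodes:
        return pd.DataFrame(columns=["degree", "betweenness", "closeness",
                                     "clustering", "component"])
    degree = dict(g.degree)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    n = len(nodes)
    harmonic = nx.harmonic_centrality(g)
    closeness = {v: harmonic[v] / (n - 1) if n > 1 else 0.0 for v in nodes}
    clustering = nx.clustering(g)
    component = {}
    for cid, comp in enumerate(nx.connected_components(g)):
        for v in comp:
            component[v] = cid
    return pd.DataFrame({
        "degree": pd.Series(degree, dtype=float),
        "betweenness": pd.Series(betweenness),
        "closeness": pd.Series(closeness),
        "clustering": pd.Series(clustering, dtype=float),
        "component": pd.Series(component),
    }).loc[nodes]


def network_summary(g: nx.Graph) -> dict:
    """Node/edge counts, largest-component diameter, mean degree, clustering."""
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return {"n_nodes": 0, "n_edges": 0, "diameter": 0,
                "mean_degree": 0.0, "clustering_coefficient": 0.0}
    components = list(nx.connected_components(g))
    giant = g.subgraph(max(components, key=len))
    diameter = nx.diameter(giant) if giant.number_of_nodes() > 1 else 0
    return {
        "n_nodes": n,
        "n_edges": e,
        "diameter": diameter,
        "mean_degree": 2.0 * e / n,
        "clustering_coefficient": float(np.mean(list(nx.clustering(g).values()))),
    }


def mean_degree(n_nodes: int, n_edges: int) -> float:
    """Mean degree 2E/N of an undirected graph."""
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    return 2.0 * n_edges / n_nodes


# ---------------------------------------------------------------------------
# hubs and keystones
# ---------------------------------------------------------------------------

def _bottom_cut(values: np.ndarray, fraction: float) -> float:
    """Threshold of the ceil(fraction*n) smallest values (nearest rank)."""
    v = np.sort(values)
    k = max(1, math.ceil(fraction * len(v)))
    return v[min(k, len(v)) - 1]


def _top_cut(values: np.ndarray, fraction: float) -> float:
    """Threshold of the ceil(fraction*n) largest values (nearest rank)."""
    v = np.sort(values)
    k = max(1, math.ceil(fraction * len(v)))
    return v[max(len(v) - k, 0)]


def classify_roles(metrics: pd.DataFrame,
                   top_fraction: float = 0.30) -> pd.DataFrame:
    """Label nodes hub / keystone / other by percentile rules.

    hub: degree >= P70 and betweenness >= P70.
    keystone: degree >= P70, closeness >= P70, betweenness <= P30, not hub.
    Cuts are nearest-rank and inclusive; the not-hub clause keeps the two
    roles mutually exclusive when ties collapse the P30/P70 cuts.
    """
    if metrics.empty:
        return metrics.assign(role=pd.Series(dtype=str))
    deg = metrics["degree"].to_numpy(dtype=float)
    btw = metrics["betweenness"].to_numpy(dtype=float)
    clo = metrics["closeness"].to_numpy(dtype=float)
    p70_deg = _top_cut(deg, top_fraction)
    p70_btw = _top_cut(btw, top_fraction)
    p70_clo = _top_cut(clo, top_fraction)
    p30_btw = _bottom_cut(btw, top_fraction)

    def _ge(a, cut):  # tolerate float summation noise in tied metrics
        return (a >= cut) | np.isclose(a, cut, rtol=1e-9, atol=1e-12)

    def _le(a, cut):
        return (a <= cut) | np.isclose(a, cut, rtol=1e-9, atol=1e-12)

    hub = _ge(deg, p70_deg) & _ge(btw, p70_btw)
    keystone = (_ge(deg, p70_deg) & _ge(clo, p70_clo)
                & _le(btw, p30_btw) & ~hub)
    out = metrics.copy()
    out["role"] = np.select([hub, keystone], ["hub", "keystone"],
                            default="other")
    for name, cut in (("degree_p70", p70_deg), ("betweenness_p70", p70_btw),
                      ("closeness_p70", p70_clo), ("betweenness_p30", p30_btw)):
        out.attrs[name] = cut
    return out


def overlay_functions(g: nx.Graph, fn: pd.DataFrame) -> dict[str, float]:
    """Annotate nodes with pathway booleans; return per-pathway fractions."""
    if fn.empty:
        logger.warning("empty function table; all pathway fractions are 0")
        return {}
    present = fn[fn["present"]]
    pathways = sorted(present["pathway"].unique())
    lookup = {pw: set(present.loc[present["pathway"] == pw, "otu_id"])
              for pw in pathways}
    n = g.number_of_nodes()
    fractions = {}
    for pw in pathways:
        annotated = 0
        for node in g.nodes:
            has = node in lookup[pw]
            g.nodes[node][pw] = has
            annotated += has
        fractions[pw] = annotated / n if n else 0.0
    return fractions


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_edge_list(g: nx.Graph, path) -> None:
    rows = [{"source": u, "target": v, **data}
            for u, v, data in g.edges(data=True)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_node_table(metrics: pd.DataFrame, path) -> None:
    out = metrics.copy()
    out.insert(0, "otu_id", out.index)
    out.to_csv(path, sep="\t", index=False)
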