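"""Mapper topological networks of samples and SAFE enrichment scores.

Samples are projected to a 2-D lens by classical metric MDS on the
Bray-Curtis distance matrix.  The lens plane is covered by
``resolution`` x ``resolution`` rectangular bins, each widened by the
``overlap`` fraction; within every cover cell, samples are grouped by
DBSCAN-style density clustering (eps = a global percentile of the pairwise
distances, minimum cluster size = ``min_samples``).  Each cluster becomes a
node; nodes sharing at least one sample are linked.

SAFE (spatial analysis of functional enrichment) scores how strongly a
per-sample variable concentrates in a node's 1-hop neighborhood: observed
neighborhood sums are compared against shuffles of the sample-to-value
assignment, p = (exceedances + 1)/(n_perm + 1), and the score is
-log10(p) normalized by the minimum attainable p, so it lies in [0, 1]
(1 exactly when p attains its minimum, 0 when p = 1).
A node is called enriched when its BH-adjusted p is below 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class TDAConfig:
    resolution: int = 40
    overlap: float = 0.75
    min_samples: int = 2
    eps_percentile: float = 98.0
    lens_dims: int = 2
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if not (0 < self.eps_percentile <= 100):
            raise ValueError("eps_percentile must be in (0, 100]")


@dataclass
class TDANetwork:
    graph: nx.Graph = field(repr=False)
    members: dict[int, list[str]] = field(repr=False)
    sample_ids: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.members)

    def membership_matrix(self) -> np.ndarray:
        """Binary nodes x samples matrix."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        m = np.zeros((len(self.members), len(self.sample_ids)))
        for k, node in enumerate(sorted(self.members)):
            for s in self.members[node]:
                m[k, pos[s]] = 1.0
        return m


def mds_lens(dist: pd.DataFrame, k: int = 2) -> np.ndarray:
    """Classical metric MDS coordinates (n x k), deterministic up to sign.

    Signs are fixed so the entry with the largest |loading| on each axis is
    positive.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1][:k]
    lam = np.clip(eigvals[order], 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(lam)
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords


def _cover_cells(lens: np.ndarray, cfg: TDAConfig):
    """Yield sample-index arrays for each nonempty widened cover cell."""
    n, k = lens.shape
    axes_bins = []
    for a in range(k):
        lo, hi = lens[:, a].min(), lens[:, a].max()
        if hi == lo:
            hi = lo + 1e-9
        edges = np.linspace(lo, hi, cfg.resolution + 1)
        w = edges[1] - edges[0]
        pad = cfg.overlap * w / 2.0
        axes_bins.append([(edges[b] - pad, edges[b + 1] + pad)
                          for b in range(cfg.resolution)])
    # iterate over the k-dim product of bins, but only visit bins that
    # contain samples along each axis to keep the sweep sparse
    per_axis_hits = []
    for a in range(k):
        hits = []
        for b, (lo, hi) in enumerate(axes_bins[a]):
            mask = (lens[:, a] >= lo) & (lens[:, a] <= hi)
            if mask.any():
                hits.append((b, mask))
        per_axis_hits.append(hits)

    def recurse(axis: int, mask: np.ndarray):
        if axis == k:
            idx = np.nonzero(mask)[0]
            if len(idx) >= cfg.min_samples:
                yield idx
            return
        for _, amask in per_axis_hits[axis]:
            combined = mask & amask
            if combined.any():
                yield from recurse(axis + 1, combined)

    yield from recurse(0, np.ones(n, dtype=bool))


def mapper_network(lens: np.ndarray, dist: pd.DataFrame,
                   cfg: TDAConfig) -> TDANetwork:
    """Build the Mapper graph of sample clusters."""
    sample_ids = list(dist.index)
    d = np.asarray(dist, dtype=float)
    if lens.shape[0] != len(sample_ids):
        raise ValueError("lens and distance matrix cover different samples")
    iu = np.triu_indices(len(sample_ids), k=1)
    eps = float(np.percentile(d[iu], cfg.eps_percentile)) if len(iu[0]) else 1.0
    eps = max(eps, 1e-12)

    members: dict[int, list[str]] = {}
    seen: set[frozenset] = set()
    node_id = 0
    for idx in _cover_cells(lens, cfg):
        sub = d[np.ix_(idx, idx)]
        labels = DBSCAN(eps=eps, min_samples=cfg.min_samples,
                        metric="precomputed").fit_predict(sub)
        for lab in set(labels) - {-1}:
            cluster = frozenset(idx[labels == lab])
            if len(cluster) < cfg.min_samples or cluster in seen:
                continue
            seen.add(cluster)
            members[node_id] = sorted(sample_ids[i] for i in cluster)
            node_id += 1
    g = nx.Graph()
    g.add_nodes_from(members)
    keys = sorted(members)
    sets = {k: set(members[k]) for k in keys}
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            if sets[a] & sets[b]:
                g.add_edge(a, b)
    if not members:
        logger.warning("mapper produced an empty network")
    return TDANetwork(graph=g, members=members, sample_ids=sample_ids)


def safe_scores(net: TDANetwork, variable: pd.Series,
                cfg: TDAConfig) -> pd.DataFrame:
    """Per-node SAFE enrichment of a per-sample variable.

    Returns a DataFrame indexed by node with columns value (node mean),
    neighborhood (1-hop sum), p, p_adj, safe, enriched.
    """
    v = variable.reindex(net.sample_ids)
    if v.isna().any():
        raise ValueError("variable undefined for some samples")
    v = v.to_numpy(dtype=float)
    if net.n_nodes == 0:
        return pd.DataFrame(columns=["value", "neighborhood", "p", "p_adj",
                                     "safe", "enriched"])
    m = net.membership_matrix()
    sizes = m.sum(axis=1)
    m_norm = m / sizes[:, None]
    keys = sorted(net.members)
    adj = nx.to_numpy_array(net.graph, nodelist=keys) + np.eye(len(keys))

    node_vals = m_norm @ v
    neigh_obs = adj @ node_vals

    rng = np.random.default_rng(cfg.seed)
    exceed = np.zeros(len(keys))
    if np.ptp(v) == 0:
        p = np.ones(len(keys))
    else:
        for _ in range(cfg.n_perm):
            v_perm = v[rng.permutation(len(v))]
            neigh_perm = adj @ (m_norm @ v_perm)
            exceed += neigh_perm >= neigh_obs
        p = (exceed + 1.0) / (cfg.n_perm + 1.0)
    p_min = 1.0 / (cfg.n_perm + 1.0)
    safe = np.where(p >= 1.0, 0.0, np.log10(p) / np.log10(p_min))
    _, p_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
    return pd.DataFrame({
        "value": node_vals,
        "neighborhood": neigh_obs,
        "p": p,
        "p_adj": p_adj,
        "safe": safe,
        "enriched": p_adj < 0.05,
    }, index=pd.Index(keys, name="node"))


def safe_table(net: TDANetwork, variables: pd.DataFrame,
               cfg: TDAConfig) -> dict[str, pd.DataFrame]:
    """SAFE scores for every column of ``variables`` (one table each)."""
    return {name: safe_scores(net, variables[name], cfg)
            for name in variables.columns}


def dominant_variable_map(safe_tables: dict[str, pd.DataFrame]) -> pd.Series:
    """Per node, the enriched variable with the highest SAFE score.

    Nodes with no enriched variable are labeled ``none``; ties break
    lexicographically (logged).
    """
    if not safe_tables:
        return pd.Series(dtype=str)
    names = sorted(safe_tables)
    nodes = safe_tables[names[0]].index
    out = pd.Series("none", index=nodes, name="dominant_variable")
    for node in nodes:
        best_name, best_safe = None, -np.inf
        tied = []
        for name in names:
            row = safe_tables[name].loc[node]
            if not row["enriched"]:
                continue
            if row["safe"] > best_safe:
                best_name, best_safe = name, row["safe"]
                tied = [name]
            elif row["safe"] == best_safe:
                tied.append(name)
        if len(tied) > 1:
            logger.info("node %s: SAFE tie among %s; taking %s",
                        node, tied, min(tied))
            best_name = min(tied)
        if best_name is not None:
            out[node] = best_name
    return out
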