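"""Canonical correspondence analysis, permutation tests, and variation
partitioning.

CCA relates a chi-square-standardized community matrix to environmental or
spatial constraints by weighted least squares: with relative frequency
matrix P, row masses r and column masses c, the standardized residual matrix
is Qbar = (P - r c') / sqrt(r c').  The constraints (weighted-centered and
scaled) are projected in the sqrt(r) metric; the SVD of the fitted part
gives the constrained eigenvalues, and the residual the unconstrained ones.
Constrained + unconstrained inertia always equals the total inertia
(sum of squares of Qbar).

Significance per factor is a marginal permutation test (permute the tested
factor's rows, holding the others fixed; statistic = partial constrained
inertia), and variation partitioning reports the partial-CCA fraction of
each constraint group with the remainder as the shared component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class CollinearityWarning(UserWarning):
    pass


@dataclass
class CCAResult:
    eigenvalues_constrained: np.ndarray
    eigenvalues_unconstrained: np.ndarray
    total_inertia: float
    constrained_proportion: float
    site_scores: pd.DataFrame = field(repr=False)
    biplot_scores: pd.DataFrame = field(repr=False)
    rank: int = 0
    dropped_constraints: list[str] = field(default_factory=list)


def _as_counts(Y) -> pd.DataFrame:
    counts = Y.counts if hasattr(Y, "counts") else pd.DataFrame(Y)
    return counts.astype(float)


def chi_square_residuals(counts: pd.DataFrame):
    """Standardized residual matrix Qbar plus row/column masses."""
    M = counts.to_numpy(dtype=float)
    if M.sum() <= 0:
        raise ValueError("empty community matrix")
    P = M / M.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any():
        raise ValueError("zero-sum sample in community matrix")
    expected = np.outer(r, c)
    Qbar = (P - expected) / np.sqrt(expected)
    return Qbar, r, c


def _weighted_standardize(X: pd.DataFrame, r: np.ndarray):
    """Center and scale constraints by the row-mass-weighted moments."""
    Xv = X.to_numpy(dtype=float)
    mean = r @ Xv
    Xc = Xv - mean
    var = r @ (Xc ** 2)
    keep = var > 1e-12
    dropped = list(X.columns[~keep])
    if dropped:
        logger.warning("dropping constant constraints: %s", dropped)
    Xs = Xc[:, keep] / np.sqrt(var[keep])
    return Xs, list(X.columns[keep]), dropped


def _drop_collinear(Z: np.ndarray, names: list[str], tol: float = 1e-9):
    """QR with column pivoting; drop columns beyond the numerical rank."""
    if Z.shape[1] == 0:
        return Z, names, []
    # greedy rank-revealing pruning keeps the earliest independent columns
    keep: list[int] = []
    for j in range(Z.shape[1]):
        trial = Z[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=tol * max(Z.shape)) > len(keep):
            keep.append(j)
    dropped = [names[j] for j in range(Z.shape[1]) if j not in keep]
    if dropped:
        logger.warning("dropping collinear constraints: %s", dropped)
    return Z[:, keep], [names[j] for j in keep], dropped


def _fit_core(Qbar: np.ndarray, Z: np.ndarray):
    """Project Qbar onto the (already sqrt(r)-scaled) constraint columns."""
    if Z.shape[1] == 0:
        return np.zeros_like(Qbar)
    coef, *_ = np.linalg.lstsq(Z, Qbar, rcond=None)
    return Z @ coef


def cca_fit(Y, X: pd.DataFrame) -> CCAResult:
    """CCA of community table Y on constraint matrix X."""
    counts = _as_counts(Y)
    zero_otus = counts.columns[counts.sum(axis=0) == 0]
    if len(zero_otus):
        logger.warning("dropping %d all-zero OTU columns", len(zero_otus))
        counts = counts.loc[:, counts.sum(axis=0) > 0]
    X = X.loc[counts.index]
    Qbar, r, c = chi_square_residuals(counts)
    total_inertia = float((Qbar ** 2).sum())

    Xs, names, dropped_const = _weighted_standardize(X, r)
    Z = np.sqrt(r)[:, None] * Xs
    Z, names, dropped_coll = _drop_collinear(Z, names)
    fitted = _fit_core(Qbar, Z)

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    rank = min(Z.shape[1], *Qbar.shape)
    eig_c = (s ** 2)[:rank]
    eig_c = eig_c[eig_c > 1e-12]
    resid = Qbar - fitted
    _, s_u, _ = np.linalg.svd(resid, full_matrices=False)
    eig_u = s_u ** 2
    eig_u = eig_u[eig_u > 1e-12]

    k = len(eig_c)
    site = pd.DataFrame(
        (Qbar @ vt[:k].T) / np.sqrt(r)[:, None],
        index=counts.index, columns=[f"CCA{i+1}" for i in range(k)])
    # biplot scores: weighted correlation of constraints with the site axes
    lc = (fitted @ vt[:k].T) / np.sqrt(r)[:, None]
    bip = np.zeros((len(names), k))
    for j in range(len(names)):
        for a in range(k):
            xa, ya = Xs[:, j], lc[:, a]
            cov = r @ (xa * ya) - (r @ xa) * (r @ ya)
            sx = np.sqrt(r @ xa ** 2 - (r @ xa) ** 2)
            sy = np.sqrt(r @ ya ** 2 - (r @ ya) ** 2)
            bip[j, a] = cov / (sx * sy) if sx > 0 and sy > 0 else 0.0
    biplot = pd.DataFrame(bip, index=names,
                          columns=[f"CCA{i+1}" for i in range(k)])

    return CCAResult(
        eigenvalues_constrained=eig_c,
        eigenvalues_unconstrained=eig_u,
        total_inertia=total_inertia,
        constrained_proportion=float(eig_c.sum() / total_inertia),
        site_scores=site,
        biplot_scores=biplot,
        rank=len(eig_c),
        dropped_constraints=dropped_const + dropped_coll,
    )


def _partial_constrained_inertia(Qbar: np.ndarray, r: np.ndarray,
                                 X_test: np.ndarray,
                                 X_cond: np.ndarray | None) -> float:
    """Constrained inertia of X_test after partialling out X_cond."""
    sqrt_r = np.sqrt(r)[:, None]
    Zt = sqrt_r * X_test
    Q = Qbar
    if X_cond is not None and X_cond.shape[1] > 0:
        Zc = sqrt_r * X_cond
        Q = Q - _fit_core(Q, Zc)
        coef, *_ = np.linalg.lstsq(Zc, Zt, rcond=None)
        Zt = Zt - Zc @ coef
    fitted = _fit_core(Q, Zt)
    return float((fitted ** 2).sum())


def cca_permutation_test(Y, X: pd.DataFrame, factor: str,
                         n_perm: int = 999, seed: int = 0) -> float:
    """Marginal permutation p for one constraint column.

    The tested column is permuted across samples while the other constraints
    stay fixed; the statistic is the partial constrained inertia of the
    factor given the others.  p = (exceedances + 1) / (n_perm + 1).
    """
    counts = _as_counts(Y)
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    X = X.loc[counts.index]
    if factor not in X.columns:
        raise KeyError(f"factor {factor!r} not in constraints")
    Qbar, r, _ = chi_square_residuals(counts)
    others = [cname for cname in X.columns if cname != factor]
    Xs_all, names, _ = _weighted_standardize(X, r)
    name_pos = {nm: i for i, nm in enumerate(names)}
    if factor not in name_pos:
        return 1.0  # constant factor carries no signal
    xt = Xs_all[:, [name_pos[factor]]]
    xc = (Xs_all[:, [name_pos[nm] for nm in others if nm in name_pos]]
          if others else None)
    stat_obs = _partial_constrained_inertia(Qbar, r, xt, xc)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(xt))
        stat = _partial_constrained_inertia(Qbar, r, xt[perm], xc)
        if stat >= stat_obs:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def vpa(Y, X_groups: dict[str, list[str]], X: pd.DataFrame) -> dict[str, float]:
    """CCA-based variation partitioning over groups of constraints.

    Returns the partial (conditional) proportion for each group, the shared
    remainder, and the total constrained proportion.  Components may be
    slightly negative and are reported as-is.
    """
    counts = _as_counts(Y)
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    X = X.loc[counts.index]
    Qbar, r, _ = chi_square_residuals(counts)
    total_inertia = float((Qbar ** 2).sum())
    Xs, names, _ = _weighted_standardize(X, r)
    name_pos = {nm: i for i, nm in enumerate(names)}

    def cols(group_cols: list[str]) -> np.ndarray:
        idx = [name_pos[cname] for cname in group_cols if cname in name_pos]
        return Xs[:, idx]

    all_cols = [cname for group in X_groups.values() for cname in group]
    total_constrained = _partial_constrained_inertia(
        Qbar, r, cols(all_cols), None) / total_inertia
    out: dict[str, float] = {}
    for gname, gcols in X_groups.items():
        other_cols = [cname for og, oc in X_groups.items() if og != gname
                      for cname in oc]
        out[gname] = _partial_constrained_inertia(
            Qbar, r, cols(gcols), cols(other_cols) if other_cols else None
        ) / total_inertia
    out["shared"] = total_constrained - sum(out.values())
    out["total_constrained"] = total_constrained
    return out
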