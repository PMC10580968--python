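"""Stochastic-assembly signals: distance decay and the Sloan neutral model.

Distance decay regresses pairwise Bray-Curtis community similarity on
(log10) geographic distance; a negative slope indicates spatial turnover.
The Sloan neutral community model (NCM) predicts a taxon's occurrence
frequency across local communities from its mean relative abundance ``p``
under dispersal and drift alone:

    F(p) = 1 - BetaCDF(d; Nm * p, Nm * (1 - p))

where ``Nm`` is the product of local community size and immigration rate and
``d`` is the detection limit (the smallest observable proportion, taken as
1/rarefaction depth).  ``Nm`` is estimated by bounded non-linear least
squares on the occupancy-abundance cloud; goodness of fit is
R^2 = 1 - SSres/SStot and may be negative when the cloud is anti-neutral
(e.g. habitat specialists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.proportion import proportion_confint

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# geographic distance
# ---------------------------------------------------------------------------

def haversine_km(a, b) -> float:
    """Great-circle distance in km between (lat, lon) points in degrees."""
    lat1, lon1 = a
    lat2, lon2 = b
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90 <= lat <= 90) or not (-180 <= lon <= 180):
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1))))


def geographic_distance_matrix(meta: pd.DataFrame) -> pd.DataFrame:
    """Pairwise haversine distances (km) from metadata latitude/longitude."""
    coords = meta[["latitude", "longitude"]].to_numpy(dtype=float)
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(coords[i], coords[j])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=meta.index, columns=meta.index)


# ---------------------------------------------------------------------------
# community similarity
# ---------------------------------------------------------------------------

def community_similarity(table, metric: str = "bray_curtis") -> pd.DataFrame:
    """Pairwise similarity = 1 - dissimilarity; diagonal 1, symmetric."""
    if metric != "bray_curtis":
        raise ValueError(f"unsupported metric: {metric!r}")
    counts = table.counts.to_numpy(dtype=float)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("zero-sum sample")
    dis = squareform(pdist(counts, metric="braycurtis"))
    sim = 1.0 - dis
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=table.counts.index,
                        columns=table.counts.index)


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

@dataclass
class DistanceDecayFit:
    slope: float
    intercept: float
    r: float
    p_ols: float
    p_mantel: float
    n_pairs: int
    transform: str
    degenerate: bool = False


def _upper_triangle(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def distance_decay_fit(sim: pd.DataFrame, dist: pd.DataFrame,
                       transform: str = "log10_distance",
                       n_perm: int = 999, seed: int = 0) -> DistanceDecayFit:
    """OLS of pairwise similarity on (transformed) distance.

    Zero-distance pairs are offset to half the minimum nonzero distance
    before the log transform.  A Mantel-style permutation p (sample labels
    permuted, Pearson r recomputed) accompanies the OLS p because pairs are
    not independent.
    """
    if list(sim.index) != list(dist.index):
        dist = dist.loc[sim.index, sim.index]
    s = np.asarray(sim, dtype=float)
    d = np.asarray(dist, dtype=float)
    n = s.shape[0]
    y = _upper_triangle(s)
    x_raw = _upper_triangle(d)
    if len(y) < 3:
        raise ValueError("need at least 3 sample pairs")
    if transform == "log10_distance":
        positive = x_raw[x_raw > 0]
        if len(positive) == 0:
            raise ValueError("all pairwise distances are zero")
        floor = positive.min() * 0.5
        x = np.log10(np.where(x_raw > 0, x_raw, floor))
    elif transform == "linear":
        x = x_raw
    else:
        raise ValueError(f"unknown transform: {transform!r}")

    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return DistanceDecayFit(0.0, float(y.mean()), 0.0, 1.0, 1.0,
                                len(y), transform, degenerate=True)

    res = stats.linregress(x, y)
    r_obs = res.rvalue

    # Mantel permutation: permute sample labels of the similarity matrix
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = _upper_triangle(s[np.ix_(perm, perm)])
        r_perm = np.corrcoef(x, y_perm)[0, 1]
        if abs(r_perm) >= abs(r_obs):
            exceed += 1
    p_mantel = (exceed + 1) / (n_perm + 1)

    return DistanceDecayFit(float(res.slope), float(res.intercept),
                            float(r_obs), float(res.pvalue), p_mantel,
                            len(y), transform)


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------

def ncm_predicted_freq(p, Nm: float, d: float):
    """Neutral occurrence frequency F = 1 - BetaCDF(d; Nm*p, Nm*(1-p)).

    Vectorized over ``p``; extremes are clamped (p <= 0 -> 0, p >= 1 -> 1).
    """
    p = np.asarray(p, dtype=float)
    a = np.clip(Nm * p, 1e-12, None)
    b = np.clip(Nm * (1.0 - p), 1e-12, None)
    f = 1.0 - special.betainc(a, b, np.clip(d, 0.0, 1.0))
    f = np.where(p <= 0, 0.0, np.where(p >= 1, 1.0, f))
    return f if f.ndim else float(f)


@dataclass
class NCMFit:
    Nm: float
    m: float
    d: float
    R2: float
    n_samples: int
    per_otu: pd.DataFrame = field(repr=False)
    n_above: int = 0
    n_within: int = 0
    n_below: int = 0


def fit_ncm(table, d: float | None = None, ci_alpha: float = 0.05,
            log10_nm_bounds: tuple[float, float] = (0.0, 9.0),
            n_starts: int = 5) -> NCMFit:
    """Fit the Sloan NCM to an OTU table's occupancy-abundance cloud.

    ``p_mean`` is each OTU's mean relative abundance, ``F_obs`` the fraction
    of samples where it is detected.  ``Nm`` is optimized over log10(Nm) in
    ``log10_nm_bounds`` with ``n_starts`` multi-starts.

    ``d`` defaults to ln(2)/depth, the sharp detection threshold equivalent
    to detection by count sampling at the rarefaction depth (a taxon at
    proportion q is seen with probability ~ 1 - exp(-q * depth), which
    crosses 1/2 at q = ln(2)/depth); pass ``d = 1/depth`` for the common
    smallest-detectable-proportion convention.  The 95% envelope per OTU is
    the Wilson score interval on the predicted binomial proportion at
    n = n_samples.
    """
    detected = table.counts.sum(axis=0) > 0
    if int(detected.sum()) < 20:
        raise ValueError("need >= 20 detected OTUs to fit the NCM")
    counts = table.counts.loc[:, detected]
    n_samples = counts.shape[0]
    depth = float(np.median(table.sample_totals()))
    # pooled proportion: on a rarefied table this equals the mean relative
    # abundance, and it is invariant to shuffling counts within an OTU
    p_mean = counts.sum(axis=0).to_numpy() / counts.to_numpy().sum()
    f_obs = (counts > 0).mean(axis=0).to_numpy()
    if d is None:
        d = np.log(2.0) / depth

    def sse(log_nm: float) -> float:
        f_pred = ncm_predicted_freq(p_mean, 10.0 ** log_nm, d)
        return float(np.sum((f_obs - f_pred) ** 2))

    lo, hi = log10_nm_bounds
    best = None
    candidates = [optimize.minimize_scalar(
        sse, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10}).x]
    for x0 in np.linspace(lo, hi, n_starts + 2)[1:-1]:
        local = optimize.minimize(lambda v: sse(v[0]), x0=[x0],
                                  bounds=[(lo, hi)], method="L-BFGS-B",
                                  options={"ftol": 1e-14})
        candidates.append(local.x[0])
    for cand in candidates:
        val = sse(float(cand))
        if best is None or val < best[1]:
            best = (float(cand), val)
    if best is None or not np.isfinite(best[1]):
        raise RuntimeError("NCM non-linear least squares did not converge")
    log_nm, ss_res = best
    nm = 10.0 ** log_nm

    f_pred = ncm_predicted_freq(p_mean, nm, d)
    ss_tot = float(np.sum((f_obs - f_obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    ci_lo, ci_hi = proportion_confint(
        np.round(f_pred * n_samples), n_samples, alpha=ci_alpha,
        method="wilson")
    ci_lo = np.minimum(ci_lo, f_pred)
    ci_hi = np.maximum(ci_hi, f_pred)
    per_otu = pd.DataFrame({
        "p_mean": p_mean, "F_obs": f_obs, "F_pred": f_pred,
        "CI_lo": ci_lo, "CI_hi": ci_hi,
    }, index=counts.columns)
    per_otu["partition"] = np.select(
        [per_otu.F_obs > per_otu.CI_hi, per_otu.F_obs < per_otu.CI_lo],
        ["above", "below"], default="within")

    counts = per_otu["partition"].value_counts()
    return NCMFit(
        Nm=nm, m=nm / depth, d=d, R2=float(r2), n_samples=n_samples,
        per_otu=per_otu,
        n_above=int(counts.get("above", 0)),
        n_within=int(counts.get("within", 0)),
        n_below=int(counts.get("below", 0)),
    )
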