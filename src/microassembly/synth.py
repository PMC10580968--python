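"""Synthetic OTU tables with known, planted structure.

Every downstream stage has a parameter-recovery test against tables built
here: neutrally assembled communities with known Nm, a spatial gradient with
a known per-km turnover rate, habitat-restricted specialists, and taxon
blocks with a known log-abundance correlation matrix.

The neutral generator mirrors the distributional assumption the Sloan model
curve encodes: for a taxon at metacommunity proportion ``p``, each local
community's latent proportion is Beta(Nm*p, Nm*(1-p)); latent proportions
are renormalized per sample and reads drawn multinomially at fixed depth, so
per-sample totals always equal the depth (as in a rarefied table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import OTUTable


@dataclass
class NeutralSimSpec:
    """Parameters of a neutral community simulation.

    ``Nm`` is the product of local community size and immigration rate; large
    Nm means local communities track the metacommunity closely.
    ``metacommunity_shape`` is ``logseries`` (parameter = the log-series
    ``theta`` in (0,1)) or ``lognormal`` (parameter = sigma of log
    abundances).
    """

    n_taxa: int = 500
    n_samples: int = 200
    depth: int = 10_000
    Nm: float = 1000.0
    metacommunity_shape: str = "lognormal"
    shape_param: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Nm <= 0:
            raise ValueError("Nm must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def metacommunity_proportions(spec: NeutralSimSpec,
                              rng: np.random.Generator) -> np.ndarray:
    """Metacommunity relative abundances summing to 1."""
    if spec.metacommunity_shape == "logseries":
        theta = spec.shape_param if 0 < spec.shape_param < 1 else 0.999
        abund = rng.logseries(theta, spec.n_taxa).astype(float)
    elif spec.metacommunity_shape == "lognormal":
        abund = np.exp(rng.normal(0.0, spec.shape_param, spec.n_taxa))
    else:
        raise ValueError(
            f"unknown metacommunity shape: {spec.metacommunity_shape!r}")
    return abund / abund.sum()


def _beta_latents(p: np.ndarray, nm: float, n_samples: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-sample latent proportions, Beta(Nm*p, Nm*(1-p)) per taxon.

    Shape parameters that underflow to zero fall back to Bernoulli presence
    at probability p (the beta degenerates to a point mass mixture).
    """
    a = nm * p
    b = nm * (1.0 - p)
    latent = np.empty((n_samples, len(p)))
    ok = (a > 0) & (b > 0)
    latent[:, ok] = rng.beta(a[ok], b[ok], size=(n_samples, ok.sum()))
    if (~ok).any():
        latent[:, ~ok] = (rng.random((n_samples, (~ok).sum())) < p[~ok]) * p[~ok]
    return latent


def simulate_neutral_table(spec: NeutralSimSpec) -> OTUTable:
    """Sample an OTU table under Sloan neutrality at known Nm."""
    rng = np.random.default_rng(spec.seed)
    p = metacommunity_proportions(spec, rng)
    latent = _beta_latents(p, spec.Nm, spec.n_samples, rng)
    row_sums = latent.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    local = latent / row_sums
    counts = np.vstack([rng.multinomial(spec.depth, local[i])
                        for i in range(spec.n_samples)])
    return OTUTable(pd.DataFrame(
        counts,
        index=[f"S{i:04d}" for i in range(spec.n_samples)],
        columns=[f"OTU{j:05d}" for j in range(spec.n_taxa)]))


def coastline_metadata(n_samples: int, length_km: float = 2000.0,
                       n_locations: int = 5, seed: int = 0,
                       region: str = "China") -> pd.DataFrame:
    """Sample metadata along a 1-D coastline of ``length_km``.

    Samples are ordered by arc position; latitude/longitude trace a great
    circle northward, and climate covariates (MAT, MAP, MDTR) vary smoothly
    with latitude plus noise.
    """
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.uniform(0.0, length_km, n_samples))
    lat0 = 20.0
    lat = lat0 + pos / 111.0  # ~111 km per degree latitude
    # coastlines are not meridians: slight eastward drift plus site jitter
    lon = 110.0 + 0.3 * pos / 111.0 + rng.normal(0, 0.02, n_samples)
    loc_edges = np.linspace(0, length_km, n_locations + 1)
    loc = np.digitize(pos, loc_edges[1:-1])
    meta = pd.DataFrame({
        "latitude": lat,
        "longitude": lon,
        "location": [f"L{k}" for k in loc],
        "MAT": 28.0 - 0.5 * (lat - lat0) + rng.normal(0, 0.3, n_samples),
        "MAP": 1800.0 - 40.0 * (lat - lat0) + rng.normal(0, 50, n_samples),
        "MDTR": 6.0 + 0.1 * (lat - lat0) + rng.normal(0, 0.2, n_samples),
        "region": region,
        "arc_km": pos,
    }, index=[f"S{i:04d}" for i in range(n_samples)])
    meta.index.name = "sample_id"
    return meta


def plant_gradient(table: OTUTable, coords: pd.DataFrame, strength: float,
                   seed: int = 0, tilt_sigma: float = 1.5) -> OTUTable:
    """Impose spatial turnover: expected similarity declines with distance.

    Two endpoint metacommunities (log-normal tilts of the table's overall
    composition, sd ``tilt_sigma`` on the log scale) are mixed exponentially
    along the coastline arc-length: sample at position s draws from
    w(s)*A + (1-w(s))*B with w(s) = exp(-strength * s).  Counts are re-drawn
    multinomially at each sample's original depth, so strength = 0 leaves no
    planted signal.  Large tilts make some taxa effectively endemic to one
    end of the gradient; use a milder ``tilt_sigma`` when the niche breadth
    of other planted structure must stay interpretable.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    missing = [s for s in table.sample_ids if s not in coords.index]
    if missing:
        raise ValueError(f"coordinates missing for samples: {missing[:5]}")
    rng = np.random.default_rng(seed)
    base = table.counts.sum(axis=0).to_numpy(dtype=float)
    base = base / base.sum()
    k = len(base)
    pool_a = base * np.exp(rng.normal(0, tilt_sigma, k))
    pool_b = base * np.exp(rng.normal(0, tilt_sigma, k))
    pool_a /= pool_a.sum()
    pool_b /= pool_b.sum()
    if "arc_km" in coords.columns:
        pos = coords.loc[table.sample_ids, "arc_km"].to_numpy(dtype=float)
    else:  # arc position from latitude/longitude via 1-D projection
        from .assembly import haversine_km
        xy = coords.loc[table.sample_ids, ["latitude", "longitude"]]
        origin = xy.iloc[0].to_numpy()
        pos = np.array([haversine_km(origin, row.to_numpy())
                        for _, row in xy.iterrows()])
    depths = table.sample_totals().to_numpy()
    w = np.exp(-strength * pos)
    counts = np.empty_like(table.counts.to_numpy())
    for i in range(table.n_samples):
        mix = w[i] * pool_a + (1.0 - w[i]) * pool_b
        counts[i] = rng.multinomial(depths[i], mix / mix.sum())
    return OTUTable(pd.DataFrame(counts, index=table.counts.index,
                                 columns=table.counts.columns))


def plant_specialists(table: OTUTable, habitat_labels: pd.Series, k: int,
                      seed: int = 0,
                      boost: float = 0.01) -> tuple[OTUTable, list[str]]:
    """Restrict k designated taxa to a single habitat each.

    The chosen taxa get zero counts outside their habitat and a boosted
    share inside it; counts are re-drawn per sample so totals stay at the
    original depth.  Returns the modified table and the planted taxa ids.
    """
    rng = np.random.default_rng(seed)
    habitats = habitat_labels.loc[table.sample_ids]
    levels = sorted(habitats.unique())
    chosen = list(rng.choice(table.otu_ids, size=k, replace=False))
    assigned = {otu: levels[i % len(levels)] for i, otu in enumerate(chosen)}

    relab = table.counts.div(table.sample_totals(), axis=0)
    for otu, hab in assigned.items():
        inside = (habitats == hab).to_numpy()
        relab.loc[~inside, otu] = 0.0
        relab.loc[inside, otu] = boost * (1 + rng.random(inside.sum()))
    relab = relab.div(relab.sum(axis=1), axis=0)
    depths = table.sample_totals().to_numpy()
    counts = np.vstack([rng.multinomial(depths[i], relab.iloc[i].to_numpy())
                        for i in range(table.n_samples)])
    # guarantee presence of each specialist inside its habitat
    out = pd.DataFrame(counts, index=table.counts.index,
                       columns=table.counts.columns)
    for otu, hab in assigned.items():
        inside = habitats[habitats == hab].index
        if out.loc[inside, otu].sum() == 0:
            donor = out.loc[inside[0]].idxmax()
            out.loc[inside[0], donor] -= 1
            out.loc[inside[0], otu] += 1
    return OTUTable(out), chosen


def plant_correlated_block(table: OTUTable, taxa: list[str],
                           rho_matrix: np.ndarray,
                           seed: int = 0,
                           sigma: float = 1.0) -> OTUTable:
    """Give designated taxa a target correlation on log abundances.

    A Gaussian copula with covariance ``rho_matrix`` drives log-normal
    abundances for the block; the composition is then closed and counts
    re-drawn multinomially, so the planted correlation survives the
    constant-sum constraint only approximately.
    """
    rho = np.asarray(rho_matrix, dtype=float)
    if rho.shape != (len(taxa), len(taxa)):
        raise ValueError("rho_matrix shape does not match taxa list")
    if not np.allclose(np.diag(rho), 1.0):
        raise ValueError("rho_matrix must have unit diagonal")
    eigvals = np.linalg.eigvalsh(rho)
    if eigvals.min() <= -1e-10:
        raise ValueError("rho_matrix must be positive (semi)definite")
    rng = np.random.default_rng(seed)
    relab = table.counts.div(table.sample_totals(), axis=0)
    base_mean = relab[taxa].mean(axis=0).to_numpy()
    base_mean = np.clip(base_mean, 1e-4, None)
    chol = np.linalg.cholesky(rho + 1e-10 * np.eye(len(taxa)))
    z = rng.standard_normal((table.n_samples, len(taxa))) @ chol.T
    block = base_mean * np.exp(sigma * z - sigma ** 2 / 2)
    relab.loc[:, taxa] = block
    relab = relab.div(relab.sum(axis=1), axis=0)
    depths = table.sample_totals().to_numpy()
    counts = np.vstack([rng.multinomial(depths[i], relab.iloc[i].to_numpy())
                        for i in range(table.n_samples)])
    return OTUTable(pd.DataFrame(counts, index=table.counts.index,
                                 columns=table.counts.columns))
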