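"""End-to-end pipeline driver with a single config and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assembly, network, ordination, synth, tables, tda, traits

logger = logging.getLogger(__name__)

CONSTRAINT_COLUMNS = ["longitude", "latitude", "MAT", "MAP", "MDTR"]


@dataclass
class RunConfig:
    """All pipeline knobs; defaults are the study's stated thresholds."""

    otu_table: str | None = None
    metadata: str | None = None
    function_table: str | None = None
    simulate: bool = False
    n_taxa: int = 300
    n_samples: int = 80
    rarefaction_depth: int = 10_000
    abundance_threshold: float = 0.01
    niche_fraction: float = 0.10
    network_min_relab: float = 0.001
    network_r_min: float = 0.6
    network_p_max: float = 0.05
    role_top_fraction: float = 0.30
    sparcc_n_dirichlet: int = 20
    sparcc_n_perm: int = 100
    decay_n_perm: int = 999
    cca_n_perm: int = 999
    tda: tda.TDAConfig = field(default_factory=tda.TDAConfig)
    seed: int = 0

    def validate(self) -> None:
        for name, value, lo, hi in [
            ("abundance_threshold", self.abundance_threshold, 0, 1),
            ("niche_fraction", self.niche_fraction, 0, 0.5),
            ("network_min_relab", self.network_min_relab, 0, 1),
            ("network_r_min", self.network_r_min, 0, 1),
            ("network_p_max", self.network_p_max, 0, 1),
            ("role_top_fraction", self.role_top_fraction, 0, 1),
        ]:
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if not self.simulate and self.otu_table is None:
            raise ValueError("either simulate=True or an otu_table path")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        if "tda" in doc and isinstance(doc["tda"], dict):
            doc["tda"] = tda.TDAConfig(**doc["tda"])
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages in dependency order; write artifacts + manifest."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "config_hash": _config_hash(cfg),
                      "version": __version__, "stages": {}}

    # stage: input ------------------------------------------------------
    if cfg.simulate:
        depth = min(cfg.rarefaction_depth, 2000)
        spec = synth.NeutralSimSpec(n_taxa=cfg.n_taxa,
                                    n_samples=cfg.n_samples,
                                    depth=depth, Nm=1000.0, seed=cfg.seed)
        table = synth.simulate_neutral_table(spec)
        meta = synth.coastline_metadata(cfg.n_samples, seed=cfg.seed)
        table = synth.plant_gradient(table, meta, strength=2e-3,
                                     seed=cfg.seed + 1)
        tables.write_otu_table(table, outdir / "otu_table.tsv")
        tables.write_metadata(meta, outdir / "metadata.tsv")
        fn = None
    else:
        table = tables.read_otu_table(cfg.otu_table)
        meta = tables.read_metadata(cfg.metadata)
        fn = (tables.read_function_table(cfg.function_table)
              if cfg.function_table else None)
    manifest["stages"]["input"] = {"n_samples": table.n_samples,
                                   "n_otus": table.n_otus}

    # stage: rarefy -----------------------------------------------------
    depth = int(min(cfg.rarefaction_depth, table.sample_totals().max()))
    rare, dropped = tables.rarefy(table, depth, seed=cfg.seed,
                                  return_dropped=True)
    meta = meta.loc[rare.sample_ids]
    manifest["stages"]["rarefy"] = {"depth": depth, "dropped": dropped}

    # stage: traits -----------------------------------------------------
    relab = tables.relative_abundance(rare)
    part = traits.partition_traits(relab, cfg.abundance_threshold,
                                   cfg.niche_fraction)
    part.rename_axis("otu_id").to_csv(outdir / "traits.tsv", sep="\t")
    manifest["stages"]["traits"] = {
        "n_abundant": int((part.abundance_class == "abundant").sum()),
        "n_generalist": int((part.niche_class == "generalist").sum()),
        "n_specialist": int((part.niche_class == "specialist").sum()),
    }

    # stage: distance decay --------------------------------------------
    sim = assembly.community_similarity(rare)
    dist = assembly.geographic_distance_matrix(meta)
    decay = assembly.distance_decay_fit(sim, dist, n_perm=cfg.decay_n_perm,
                                        seed=cfg.seed)
    manifest["stages"]["decay"] = {
        "slope": decay.slope, "r": decay.r, "p_ols": decay.p_ols,
        "p_mantel": decay.p_mantel, "n_pairs": decay.n_pairs}

    # stage: NCM --------------------------------------------------------
    ncm = assembly.fit_ncm(rare)
    ncm.per_otu.rename_axis("otu_id").to_csv(outdir / "ncm_per_otu.tsv",
                                             sep="\t")
    manifest["stages"]["ncm"] = {"Nm": ncm.Nm, "m": ncm.m, "R2": ncm.R2,
                                 "d": ncm.d}

    # stage: CCA --------------------------------------------------------
    constraints = meta[CONSTRAINT_COLUMNS]
    cca = ordination.cca_fit(rare, constraints)
    pvals = {c: ordination.cca_permutation_test(
        rare, constraints, c, n_perm=cfg.cca_n_perm, seed=cfg.seed)
        for c in constraints.columns}
    cca.biplot_scores.to_csv(outdir / "cca_biplot.tsv", sep="\t")
    manifest["stages"]["cca"] = {
        "constrained_proportion": cca.constrained_proportion,
        "p_values": pvals}

    # stage: network ----------------------------------------------------
    filtered = network.prevalence_filter(rare, cfg.network_min_relab)
    r = network.sparcc_correlations(filtered,
                                    n_dirichlet=cfg.sparcc_n_dirichlet,
                                    seed=cfg.seed)
    p = network.sparcc_pvalues(filtered, r, n_perm=cfg.sparcc_n_perm,
                               seed=cfg.seed)
    mean_relab = tables.relative_abundance(filtered).mean(axis=0)
    g = network.build_network(r, p, cfg.network_r_min, cfg.network_p_max,
                              node_abundance=mean_relab)
    metrics = network.node_metrics(g)
    roles = network.classify_roles(metrics, cfg.role_top_fraction)
    if fn is not None:
        manifest["stages"]["functions"] = network.overlay_functions(g, fn)
    network.write_edge_list(g, outdir / "network_edges.tsv")
    network.write_node_table(roles, outdir / "network_nodes.tsv")
    manifest["stages"]["network"] = network.network_summary(g) | {
        "n_hubs": int((roles.get("role", pd.Series(dtype=str)) == "hub").sum()),
        "n_keystones": int((roles.get("role", pd.Series(dtype=str))
                            == "keystone").sum())}

    # stage: tmap -------------------------------------------------------
    lens = tda.mds_lens(1.0 - sim, k=cfg.tda.lens_dims)
    net = tda.mapper_network(lens, 1.0 - sim, cfg.tda)
    onehot = pd.get_dummies(meta["location"]).astype(float)
    safe = tda.safe_table(net, onehot, cfg.tda)
    dominant = tda.dominant_variable_map(safe)
    dominant.rename_axis("node").to_csv(outdir / "tda_dominant.tsv", sep="\t")
    manifest["stages"]["tmap"] = {
        "n_nodes": net.n_nodes,
        "n_edges": net.graph.number_of_edges(),
        "n_enriched": int(sum(t["enriched"].sum() for t in safe.values()))}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    logger.info("pipeline complete; manifest at %s", outdir / "manifest.json")
    return manifest
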