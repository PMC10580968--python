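# microassembly

Community-assembly analysis of sediment prokaryotic microbiomes (16S OTU
tables), built for intertidal/mangrove survey designs where samples carry
coordinates and climate covariates.  The package quantifies how much of
community structure is stochastic versus deterministic, which taxa hold the
co-occurrence network together, and how composition stratifies over space:

* **Trait partitions** — abundant (>1% in ≥1 sample) vs rare OTUs;
  generalists vs specialists by the Levins niche breadth
  `B_j = 1 / Σ_i q_ij²` (top/bottom 10%, minimum-B ties always
  specialists).
* **Distance decay** — Bray–Curtis similarity regressed on log10 haversine
  distance, with a Mantel permutation p alongside the OLS p.
* **Sloan neutral community model** — occurrence frequency
  `F(p) = 1 − BetaCDF(d; Nm·p, Nm·(1−p))` fitted to the
  occupancy–abundance cloud by bounded non-linear least squares; reports
  `Nm`, `m = Nm/depth`, `R²` (may be negative), and per-OTU 95% envelopes.
* **CCA** — chi-square-standardized community matrix constrained on
  spatial/climate factors, marginal permutation tests per factor, and
  CCA-based variation partitioning.
* **SparCC networks** — compositional basis correlations with Dirichlet
  resampling and permutation p-values; edges at |r| > 0.6 and P < 0.05;
  hubs (top-30% degree and betweenness) and keystones (top-30% degree and
  closeness, bottom-30% betweenness); optional pathway overlay.
* **Mapper / SAFE** — a topological network of sample clusters over an MDS
  lens (resolution 40, overlap 0.75, min cluster 2, eps at the 98th
  distance percentile) with permutation-based SAFE enrichment of metadata,
  taxa, or functional variables.
* **Synthetic data** — generators with planted, recoverable structure
  (known Nm, spatial gradient, habitat specialists, correlated taxon
  blocks) so every stage has a parameter-recovery test without any
  sequence download.

See `docs/methods.md` for the models, conventions, and their rationale.

## Worked example

The numbered scripts under `analysis/` run the whole study design on a
synthetic dataset with known ground truth (100 samples on a 2000-km model
coastline, 500 taxa, depth 5000, Nm = 2000, a 1e-3/km spatial gradient, 20
planted habitat specialists, and one ρ = 0.9 correlated pair):

```
python analysis/01_simulate_communities.py
python analysis/02_trait_partitions.py
python analysis/03_distance_decay_and_ncm.py
python analysis/04_cca_environment.py
python analysis/05_cooccurrence_network.py
python analysis/06_tda_enrichment.py
```

Output of steps 02, 03 and 05 (what the numbers mean in brackets):

```
500 OTUs: 70 abundant (14.0%), 430 rare; 50 generalists (10.0%),
50 specialists (10.0%)
planted-specialist recall: 0.80 (20 planted)

all          slope=-0.083 (P=0.005)  NCM: Nm=   1418.7 m=0.2837 R2=+0.617
abundant     slope=-0.128 (P=0.005)  NCM: Nm=     31.3 m=0.0127 R2=+0.560
rare         slope=-0.039 (P=0.005)  NCM: Nm=    719.1 m=0.2837 R2=+0.972
generalists  slope=-0.063 (P=0.005)  NCM: Nm= 365011.1 m=179.6314 R2=+nan
specialists  slope=-0.360 (P=0.005)  NCM: Nm=      1.0 m=0.0035 R2=-8.380

network: 39 nodes, 53 edges, diameter 2, mean degree 2.718, clustering 0.582
planted pair (OTU00216, OTU00037) recovered as edge: True, r = 0.840
```

Reading this: every group shows a significant negative distance-decay slope
(Mantel P = 0.005 at 199 permutations); the full community fits the neutral
model well (R² = 0.62 at Nm ≈ 1400, close to the planted 2000 after the
gradient reshuffles composition), while the planted specialists are
anti-neutral (R² = −8.4) — occupancy is set by habitat, not abundance.
Generalists occupy every sample, so occupancy has no variance and R² is
undefined.  The SparCC network recovers the planted correlated pair at
r = 0.84, well above the 0.6 edge threshold.  Specialist recall is 0.8
rather than 1.0 because the spatial gradient itself creates regionally
endemic taxa with narrow niche breadth — a real confound of
occupancy-based niche indices (see `docs/methods.md`).

A `microassembly` CLI exposes the same stages
(`simulate | rarefy | traits | decay | ncm | cca | network | keystones |
tmap | run`), with `run` driving the full pipeline from a YAML config and
writing a reproducibility manifest.

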