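# microdrivers

Identification of core "driver" taxa in paired before/after-treatment
(BT/AT) gut microbiome cohorts from 16S ASV count tables.

When the same subjects are sampled before and after an intervention,
the interesting signal is rarely a single differentially abundant taxon:
it is the *reorganization* of the community — which taxa change their
interaction partners, which become more central, and whether assembly
shifts between deterministic and stochastic regimes. `microdrivers`
implements that full analysis as a tested, reusable pipeline:

* **Diversity & ordination** — richness and Shannon index
  (H = −Σ pᵢ ln pᵢ), analytic rarefaction expectations, Bray–Curtis
  dissimilarity, PCoA, non-metric MDS (Kruskal stress-1), PERMANOVA
  (pseudo-F with permutation p), and rank-sum differential abundance
  with Benjamini–Hochberg correction.
* **Assembly inference** — the Sloan neutral community model, which
  predicts a taxon's occurrence frequency from its mean relative
  abundance p̄ via F̂(p̄) = 1 − I_d(Nm·p̄, Nm·(1−p̄)) with I the
  regularized incomplete beta function, d the detection limit and N·m
  the migration parameter, scored by R² = 1 − SSE/SST on frequencies;
  Levins niche breadth B = 1/Σp² with generalist/specialist/neutral
  classes against a fixed-marginal null; and the Stone–Roberts C-score
  with a sequential-swap null and standardized effect size
  SES = (obs − mean₀)/sd₀ (positive ⇒ segregated co-occurrence).
* **Co-occurrence networks** — SparCC compositional correlations
  (log-ratio variation matrix, basis-variance system, iterative strong-
  pair exclusion, median over Dirichlet resamples), permutation edge
  p-values, edge rule |ρ| > 0.3 and p < 0.05, greedy modularity module
  detection, and the standard summary metrics (average degree 2E/N,
  density, average path length, betweenness).
* **NetShift-style BT-vs-AT comparison** — per node the neighbor-set
  Jaccard overlap, a neighbor-shift score
  NESH = |B∖A|/|B| + |B∖A|/|A∪B| + |B∖A|/max|B∖A| (A, B = BT/AT
  neighbor sets), and DelBet, the change in normalized betweenness
  centrality. Drivers are the union of top-quantile-NESH nodes and
  nodes with DelBet > 0.
* **Models** — a random-forest state classifier with out-of-bag
  permutation importance (MDA) and Gini importance (MDG), rank-based
  AUC; all-subsets covariate screening by adjusted R²; and a log-link
  negative-binomial GLM with case-resampling bootstrap significance.
* **Synthetic cohorts** — a generator emulating the target study design
  (25 paired subjects, ~29,000 reads/sample, thousands of ASVs) with
  planted differential taxa, state-specific correlation modules
  (Gaussian copula), indicator taxa, covariate effects and a neutrally
  assembled mode, so every stage has a ground-truth recovery test.

## Worked example

Simulate a paired cohort in which six taxa form a correlation module
only after treatment, build both networks, and ask which taxa drive the
rewiring:

```python
from microdrivers import (
    SimulationConfig, PlantedModule, simulate_paired_cohort,
    sparcc, edge_significance, build_network, detect_modules,
    network_metrics, netshift_compare, netshift_frame, drivers, fit_ncm,
)

cfg = SimulationConfig(
    n_subjects=25, n_asvs=60, library_size_mean=20000,
    planted_modules=[PlantedModule(asv_indices=tuple(range(6)),
                                   latent_correlation=0.85, state="AT")],
    seed=42,
)
cohort = simulate_paired_cohort(cfg)

nets = {}
for state in ("BT", "AT"):
    table = cohort.state_table(state)
    rho = sparcc(table, seed=1)
    p = edge_significance(table, rho, n_bootstraps=100, seed=2)
    net = build_network(rho, p, rho_min=0.3, alpha=0.05)
    detect_modules(net)
    m = network_metrics(net)
    print(f"{state}: {m.n_nodes} nodes, {m.n_edges} edges, "
          f"mean degree {m.average_degree:.2f}, Q = {net.modularity:.2f}")
    nets[state] = net

reports = netshift_compare(nets["BT"], nets["AT"], nesh_quantile=0.9)
top = netshift_frame(reports).sort_values("nesh", ascending=False).head(5)
print(top[["n_bt", "n_at", "exclusive", "jaccard", "nesh", "delbet"]].round(3))
```

prints

```
BT: 52 nodes, 59 edges, mean degree 2.27, Q = 0.70
AT: 51 nodes, 71 edges, mean degree 2.78, Q = 0.62
       n_bt  n_at  exclusive  jaccard   nesh  delbet
node
ASV2      0     7          7      0.0  2.875   0.897
ASV1      2     8          8      0.0  2.800   0.653
ASV5      0     6          6      0.0  2.750   0.000
ASV4      2     7          7      0.0  2.653   0.268
ASV13     0     5          5      0.0  2.625   1.000
```

Four of the five highest neighbor-shift scores belong to the planted
module (ASV1–ASV6): these taxa gained many AT-exclusive interaction
partners (`exclusive`), overlap little with their BT neighborhoods
(`jaccard` 0), and several also became more central (`delbet` > 0) —
exactly the profile the driver rule flags. A Sloan fit on the same AT
samples (`fit_ncm`) reports the migration parameter N·m and the
fraction of occupancy variation explained (here R² = 0.79: assembly is
largely, but not purely, neutral).

The same analysis runs end-to-end from a shell:

```sh
microdrivers run --seed 5 -o results/       # simulates when no input given
microdrivers run --counts counts.tsv --metadata meta.tsv -o results/
```

which writes per-stage TSV artifacts plus `summary.json` (PERMANOVA,
N·m and R² per state, C-score SES per state, network metrics, the
driver list, classifier AUC and GLM terms).

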