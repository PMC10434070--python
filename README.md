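# lakeco

Community-ecology inference for lake microbial eukaryotes (18S amplicon
count tables) along salinity gradients. The package bundles, behind one
consistent data model, the statistics used to ask how salinity restructures
plankton communities in inland lakes:

- **Diversity and distance decay** — rarefaction, richness and Shannon
  index, Bray-Curtis dissimilarity, PERMANOVA, ordinary-least-squares
  distance-decay fits with Mantel-style permutation p-values, and the
  partial Mantel test.
- **Assembly-process partitioning** — the β-nearest taxon index
  (βNTI, the standardized effect size of βMNTD against a phylogeny
  tip-shuffle null) combined with the Bray-Curtis Raup-Crick metric
  (RC_Bray) to split sample pairs into heterogeneous selection, homogeneous
  selection, dispersal limitation, homogenizing dispersal and undominated
  processes; Levins' niche breadth B and its community mean Bcom.
- **Co-occurrence networks** — Pearson correlations of log-transformed
  abundances among prevalent taxa (≥ 40 % occurrence), a random-matrix-theory
  (RMT) threshold scan, the standard topology panel, Maslov-Sneppen
  degree-preserving null ensembles, random-extinction robustness, natural
  connectivity, and Zi-Pi node-role classification (module hubs Zi ≥ 2.5,
  connectors Pi ≥ 0.62).
- **Differential abundance** of trophic guilds (consumers, saprotrophs,
  parasites, photosynthetic organisms, mixotrophs) as log₂ fold changes with
  a group-label permutation test and Benjamini-Hochberg control.
- **Biomarker models** — cross-validated feature-size selection and a 70/30
  train/test evaluation of ensemble regressors predicting salinity or a
  drought index from taxon relative abundances at ZOTU, order or class rank.

A synthetic-community generator produces abundance tables, ultrametric
phylogenies, sample metadata and trophic annotations with the statistical
structure these analyses assume — a salinity gradient across lakes, taxa
with phylogenetically conserved salinity optima, and a tunable
deterministic-filtering strength *w* (with *w* = 0 the neutral regime) — so
the whole stack is testable without any sequencing data.

## Formal core

For samples *k, m* with relative abundances *f*, patristic distance *d*:

```
βMNTD(k,m) = ½ [ Σ_i f_ik · min_{j∈m} d(i,j)  +  Σ_j f_jm · min_{i∈k} d(j,i) ]
βNTI       = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null      (tip-shuffle null)
RC_Bray    = 2 · rank(BC_obs | BC_null) − 1 ∈ [−1, 1]
```

|βNTI| > 2 → selection (heterogeneous if > 2, homogeneous if < −2);
otherwise RC_Bray > 0.95 → dispersal limitation, < −0.95 → homogenizing
dispersal, else undominated. Levins breadth: B_j = 1 / Σ_i P_ij² with P_ij
taxon *j*'s proportion of its total across samples. Natural connectivity:
λ̄ = ln((1/N) Σ e^{λ_i}) over adjacency eigenvalues.

## Worked example

```python
from lakeco import simulate_dataset, SimulationConfig
from lakeco import assembly as asm, diversity as dv

cfg = SimulationConfig(samples_per_lake=2, n_taxa=200,
                       sequencing_depth=3000, seed=42)
data = simulate_dataset(cfg)          # 200 taxa x 16 samples, 8 lakes

alpha = dv.alpha_diversity(data.table)
bc = dv.bray_curtis(data.table)
perm = dv.permanova(bc, data.metadata["lake"], n_perm=999, seed=0)

bnti = asm.bnti(data.table, data.tree, n_null=199, seed=0)
rc = asm.rc_bray(data.table, n_null=199, seed=0)
result = asm.classify_assembly(bnti, rc)
```

prints (via the obvious `print` calls):

```
mean richness: 73.0   mean Shannon: 2.959
PERMANOVA (lake): R2 = 0.992, p = 0.001
heterogeneous_selection    0.533
homogeneous_selection      0.008
dispersal_limitation       0.067
homogenizing_dispersal     0.383
undominated                0.008
```

Lake identity explains essentially all community variance on this strongly
filtered gradient (R² = 0.99), and with the default filtering strength
(*w* = 3) heterogeneous selection is the modal assembly process (53 % of
sample pairs) — communities at different salinities diverge more than the
null expects. Setting `filtering_strength=0` flips the partition to the
stochastic processes.

The same analyses are scriptable from the shell:

```bash
lakeco simulate  --seed 1 --out-dir run/
lakeco diversity --table run/abundance.tsv --metadata run/metadata.tsv --out-dir run/
lakeco assembly  --table run/abundance.tsv --tree run/tree.nwk --n-null 999 --out-dir run/
lakeco network   --table run/abundance.tsv --annotation run/annotation.tsv --out-dir run/
```

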