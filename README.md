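# biofacies

Subsurface sediments are often organized into *biogeochemical facies* —
vertically stacked oxidized, transition, and reduced zones within a single
lithofacies — and those facies shape the microbial communities living in
them. `biofacies` implements the downstream inference chain that links
facies structure to microbial community **biomass**, **richness**, and
**composition**, plus a predictive 3D facies/biomass mapping step, and a
synthetic-data generator so the whole chain can be exercised and validated
end-to-end without any external dataset.

It is aimed at microbial ecologists and biogeochemists working with OTU
tables, phylogenies, and borehole metadata from vertically structured
subsurface sites.

## What it computes

**Phylogenetic turnover and community assembly (βMNTD / βNTI).** For two
communities *k* and *m* with within-sample relative abundances *f*, and
cophenetic distances Δ on a shared phylogeny,

    βMNTD = 0.5 [ Σ_{i∈k} f_i min_{j∈m} Δ_ij  +  Σ_{i∈m} f_i min_{j∈k} Δ_ij ]

i.e. the abundance-weighted mean distance from each taxon to its nearest
relative in the other community. A null distribution is built by shuffling
taxon identities across the tips of the phylogeny (999 shuffles by default;
an exhaustive mode enumerates every permutation on small taxon pools), and

    βNTI = (βMNTD_obs − mean(βMNTD_null)) / sd(βMNTD_null).

|βNTI| > 2 indicates community turnover governed by deterministic
ecological selection (variable selection above +2, homogeneous selection
below −2); pairs inside the threshold are not distinguished from
stochastic assembly.

**Distance-matrix statistics.** Bray–Curtis dissimilarities, NMDS
(Kruskal stress-1), per-variable environmental delta matrices
(|v_j − v_k|), Mantel and partial Mantel permutation tests (p = (count+1)/
(n_perm+1), one-tailed positive by default), and Mantel-based forward
selection over candidate delta matrices: at each step the candidate with
the strongest (partial) correlation with the response is added; selection
stops at the first non-significant candidate.

**Facies statistics and richness model selection.** Kruskal–Wallis tests
with the Siegel–Castellan post-hoc critical difference on mean ranks, OLS
regressions against elevation, and forward selection of a multiple
regression for OTU richness scored by AICc
(AICc = n ln(RSS/n) + 2p + 2p(p+1)/(n−p−1)), with partial-regression
(added-variable) data for the retained predictors.

**Community summaries.** Rarefaction to a fixed depth (default 1000 reads,
single draw, seeded), relative abundances, per-sample richness, and
three-facies OTU Venn overlaps, including solving the triple intersection
from marginals by inclusion–exclusion.

**Sulfide-inclusion metrics.** Sphericity Ψ = π^(1/3)(6V)^(2/3)/A, percent
volume occupancy, and between-facies volume ratios of framboidal iron
sulfide populations.

**3D facies and biomass mapping.** Inverse-distance-weighted interpolation
of the two bounding surfaces (stratigraphic contact and redox transition)
from well logs, classification of a regular grid into facies (with a
configurable transition band half-width, default 0.25 m), and per-cell
predicted log10 16S copies/g, either the facies mean or stochastic normal
draws in log10 space.

**Synthetic data.** Yule phylogenies, Brownian-motion niche optima on a
single redox axis, Gaussian niche filtering over a lognormal metacommunity
(σ → ∞ recovers neutral assembly), facies-structured geochemistry, a
biomass hotspot at the redox transition (default 15× the reduced facies),
and well logs with trend + noise surface geometry — all bit-reproducible
from one seed, with a truth record for scoring recovery.

## Worked example

```python
import numpy as np
from biofacies.simulate import SimulationConfig, simulate_dataset
from biofacies.community import rarefy, relative_abundance, facies_venn
from biofacies.turnover import bnti
from biofacies.dissimilarity import env_delta_matrix, forward_select_distance

config = SimulationConfig(seed=42, n_wells=2, depths_per_well=5,
                          replicates_per_depth=2, n_taxa=128)
ds = simulate_dataset(config)
rarefied = rarefy(ds.otu_table, depth=1000, seed=42)
rel = relative_abundance(rarefied)

venn = facies_venn(rarefied, ds.metadata)
print(f"OTUs per facies: oxidized={venn.n_a}, transition={venn.n_b}, "
      f"reduced={venn.n_c}")

result = bnti(rel, ds.tree, n_null=999, seed=42)
meta = ds.metadata.subset(result.sample_ids)
cands = {v: env_delta_matrix(meta, v)
         for v in ("FeII_umol_g", "pH", "mica_pct", "anorthoclase_pct",
                   "organic_C_pct", "porosity")}
sel = forward_select_distance(result.to_distance_matrix(), cands,
                              n_perm=1000, seed=42)
print(sel.to_frame().to_string(index=False))
```

prints

```
OTUs per facies: oxidized=72, transition=121, reduced=66
 step         variable  statistic  p_value  accepted
    1      FeII_umol_g   0.915093 0.000999      True
    2               pH   0.280982 0.002997      True
    3    organic_C_pct   0.264455 0.007992      True
    4 anorthoclase_pct   0.154292 0.159840     False
```

The median βNTI between oxidized and reduced samples in this run is 9.15
(far above the +2 selection threshold — the redox contrast deterministically
selects different communities), while pairs within shared redox conditions
sit near the threshold. Forward selection then identifies the Fe(II) delta
matrix — the simulated redox axis — as the dominant correlate of βNTI
(Mantel r = 0.92 at the permutation floor p = 0.001), with pH, which
co-varies with redox state, entering second.

A `biofacies` console script exposes the same steps as subcommands
(`simulate`, `rarefy`, `bnti`, `mantel-select`, `richness-select`, `stats`,
`facies-map`).

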