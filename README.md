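# fungal-assembly

Quantifying the ecological processes that assemble soil fungal communities
along environmental gradients.

Microbial community turnover between any two samples can be driven by
deterministic processes (environmental selection) or stochastic ones
(dispersal and ecological drift). This package implements the two-stage
null-model framework that partitions all pairwise turnover among five
processes, together with the supporting diversity and permutation
statistics, for OTU-table + phylogeny datasets such as ITS surveys of
forest soils along an elevational gradient. A synthetic-community
generator with known assembly regimes makes the whole pipeline testable
end-to-end without any sequencing data.

## The framework

For a pair of communities *k* and *m* with relative abundances *f* and a
phylogeny with cophenetic distances *d*:

- **βMNTD** (abundance-weighted beta mean-nearest-taxon distance)

  βMNTD = ½ [ Σᵢ∈k fᵢₖ · minⱼ∈m d(i,j) + Σⱼ∈m fⱼₘ · minᵢ∈k d(i,j) ]

- **βNTI** = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null, where the null
  distribution comes from shuffling taxon labels across the tips of the
  phylogeny (999 replicates by default). |βNTI| > 2 indicates selection:
  βNTI > +2 **variable selection**, βNTI < −2 **homogenizing selection**.

- **RCbray** — for pairs with |βNTI| ≤ 2, the observed Bray-Curtis is
  compared with nulls built by probabilistic reassembly from the regional
  species pool (taxa drawn by occupancy, individuals allocated by pool
  relative abundance, preserving each sample's richness and total):
  RCbray = 2·[(#null < obs + ½·#null = obs)/reps − ½] ∈ [−1, 1].
  RCbray > +0.95 → **dispersal limitation**, RCbray < −0.95 →
  **homogenizing dispersal**, |RCbray| ≤ 0.95 → **drift** (undominated).

Per-module contribution rates (within one site, or between a pair of
sites) are the percentages of that module's sample pairs assigned to each
process. Supporting statistics: rarefaction, Shannon/richness,
Bray-Curtis/Jaccard, distance-decay regression, ANOSIM, Mantel, partial
Mantel and Pearson tests.

## Worked example

`analysis/` contains a numbered pipeline over a simulated five-site
elevational gradient (8–10 samples per site, 10,000 reads/sample, site
environments filtering a shared species pool):

```sh
python analysis/01_simulate_communities.py   # OTU table, tree, metadata
python analysis/02_diversity_gradient.py     # alpha/beta diversity, decay, ANOSIM
python analysis/03_null_models.py            # betaNTI + RCbray per pair
python analysis/04_assembly_fractions.py     # process percentages per module
python analysis/05_regime_recovery.py        # ground-truth validation
```

Output of step 02 on the default dataset:

```
distance decay (bray): slope = 4.761e-04/m, r = 0.974, p = 0.001
anosim (bray): R = 1.000, p = 0.001
```

β-diversity increases linearly with elevational separation (r = 0.97) and
sites are perfectly separated (ANOSIM R = 1), as expected when site
environments select on phylogenetically conserved traits. Step 04 then
shows the characteristic asymmetry of gradient datasets: within-site
turnover is almost entirely stochastic (deterministic total 0–11%),
while between-site turnover becomes increasingly deterministic with
elevational separation (up to 97.5% variable selection for the most
distant site pair).

Library use mirrors the scripts:

```python
from fungal_assembly import null_beta_nti, raup_crick_bray, classify_pair

nti = null_beta_nti(table, tree, reps=999, seed=1)
rc = raup_crick_bray(table, reps=999, seed=1)
label = classify_pair(nti[0].beta_nti, rc[0].rc_bray)  # e.g. "drift"
```

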