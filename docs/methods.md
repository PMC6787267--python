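# Methods

## Data model and formats

The community table is a taxa × samples matrix of non-negative integer
read counts. On disk it is tab-separated in the QIIME "classic" dialect
(taxa as rows, first header cell `#OTU_ID`); both orientations parse to
the same canonical in-memory table, so the orientation of a source file
never matters. Phylogenies are newick with branch lengths; every taxon
submitted to phylogenetic indices must be a tip. Taxa present in the tree
but absent from the table are ignored (the tree may be a supertree); taxa
in the table but missing from the tree raise an error unless pruning is
explicitly allowed, because silently dropping them would bias βMNTD
toward the retained clades. Trees with basal multifurcations (star trees)
are accepted; the file's root is taken as the root. Zero-total taxa are
dropped before any null-model computation. Result tables are TSV with
floats at 6 significant digits; percentages follow the rounding rule
below.

## Diversity

Shannon entropy uses the natural log (nats); with hundreds of OTUs this
puts typical soil-fungal values in the 2.5–4 range. Richness is the count
of taxa with positive reads. Rarefaction is a single seeded multivariate-
hypergeometric draw per sample (sampling without replacement); samples
below the target depth are dropped with a warning. β-diversity (Bray-
Curtis on counts, presence/absence Jaccard) is intended to be computed on
rarefied tables — at equal depth, count-based Bray-Curtis equals its
relative-abundance form. Distance decay regresses the n(n−1)/2 pairwise
dissimilarities on pairwise |Δelevation| by OLS; because pairs share
samples, the p-value comes from a Mantel-style permutation of sample
labels rather than from the t distribution.

## Null models

**βNTI.** The null shuffles taxon labels across all tips of the phylogeny
("taxa shuffle"), preserving topology, branch lengths and the community
matrix; equivalently, the rows/columns of the cophenetic matrix are
jointly permuted. One permutation is drawn per replicate and reused for
every sample pair, so all pairs of one run are standardized against the
same null draws. The standardized effect size uses the n−1 sample
standard deviation. βNTI is exactly invariant to rescaling all branch
lengths by a positive constant (observed value, null mean and null sd all
scale linearly); the tests assert this. Pairs with zero null sd (possible
on degenerate toy inputs) are flagged undefined and excluded from
classification rather than guessed. An `exhaustive=True` mode enumerates
all n! tip permutations for small trees and is checked against an
independent brute-force oracle.

**RCbray.** The species pool is the full table (all samples in the
analysis — the sites belong to one regional gradient); occupancy and
pool relative abundance are computed once from it. Each null community
preserves the observed sample's richness and total reads: richness taxa
are drawn without replacement with probability proportional to occupancy
(via exponential-race weighted sampling), each receives one individual,
and the remaining reads are allocated multinomially by pool relative
abundance restricted to the drawn taxa. Ties between null and observed
Bray-Curtis count half, giving the ±1-bounded index. Default replicates
for both nulls: 999 (exposed as a parameter; the validation suites use
199 to keep runtimes in seconds).

**Random streams.** Every operation takes an integer seed. βNTI replicate
r uses a substream derived from (seed, r); RCbray draws for a pair use
substreams derived from (seed, i, j, r) with (i, j) the table-order
sample indices. Results are therefore bit-reproducible and independent of
pair ordering or scheduling.

## Process classification

βNTI > +2 → variable selection; βNTI < −2 → homogenizing selection;
otherwise RCbray > +0.95 → dispersal limitation, RCbray < −0.95 →
homogenizing dispersal, else drift. Boundary conventions (measure-zero in
practice, but fixed for determinism): βNTI exactly ±2 falls through to
the RCbray branch; RCbray exactly ±0.95 classifies as drift. "Drift" is
the label used for what some formulations call "undominated" — no single
process dominant. Modules are all within-group sample pairs (C(n,2)) and
all between-group pairs (n₁·n₂). Percentages are 100·count/n_pairs
rounded half-up to two decimals; stochastic and deterministic totals are
computed from the raw counts and then rounded, so parts and totals can
disagree by at most 0.01 (published tables of this kind occasionally
round inconsistently at that digit; we keep the arithmetic rule).

## Permutation statistics

ANOSIM R = (mean between-group rank − mean within-group rank)/(M/2) with
M = n(n−1)/2 and mid-ranks for ties; Mantel r is the Pearson correlation
of condensed distance vectors; the partial Mantel statistic is the
first-order partial correlation r(d1,d2|d3). All p-values use the
add-one convention p = (#(perm ≥ obs)+1)/(perms+1), one-tailed (greater),
999 permutations by default. The partial Mantel permutes only d1
(raw permutation), the simplest defensible scheme. Pearson tests use the
two-tailed t transform with n−2 df.

## Synthetic communities

The generator emulates a gradient survey: a Yule (pure-birth) phylogeny
with unit-mean branch lengths and a final inter-speciation wait appended
to pendant branches (no zero-length tips); Brownian traits along the tree
(tip covariance = rate × shared path length), standardized before use; a
log-normal metacommunity abundance distribution; and per-group expected
compositions turned into samples by multinomial draws at exactly `depth`
reads. Group environmental optima default to an even spacing over ±1.2
trait standard deviations.

Regimes:

- **selection** — group weights ∝ base·exp(−(z_i − env_g)²/(2σ²)),
  Gaussian filtering in trait space (σ = 0.6 trait sd by default). As
  σ → ∞ the filter vanishes and the regime reduces to drift, which the
  tests assert.
- **drift** — one shared metacommunity; each sample's composition is the
  pool times mean-one log-normal noise (σ = 0.3). The noise is the
  generator's rendering of demographic stochasticity: it is calibrated so
  observed Bray-Curtis sits inside the Raup-Crick null envelope (pure
  multinomial resampling would sit below it and mimic homogenizing
  dispersal), while leaving expected abundances proportional to the pool
  and inducing no phylogenetic signal.
- **dispersal_limitation** — each taxon's accessibility is split across
  groups by a Dirichlet draw with concentration `dispersal` (default 0.3;
  smaller = stronger limitation, less overlap between group pools). Whole
  groups thereby diverge compositionally while replicates within a group
  stay coherent — dispersal limitation acting alongside drift.
- **homogenizing_dispersal** — all samples draw from one tight shared
  composition (noise σ = 0.05) over a more uneven pool (log-normal σ 2.5
  vs 1.5 elsewhere); strong dominance lowers the sampling-noise floor of
  observed Bray-Curtis below the null envelope, the RC → −1 signature.

Ground truth is the scenario's generative regime, not a per-pair
guarantee; recovery is statistical. With the documented defaults
(2 groups × 8 samples, 150 taxa, depth 2,000, 199 nulls) the pipeline
recovers selection in ≥70% of between-group pairs, drift in ≥70% of all
pairs, dispersal limitation in ≥50% of between-group pairs, and
homogenizing dispersal as the plurality label; the validation suites
average each rate over three replicate datasets because a single dataset
shares one pool/access draw across all its pairs and is occasionally
unlucky (see limitations).

## Numerical choices and problem sizes

Null-replicate counts, permutation counts and tie conventions are stated
above; all are parameters. The validation and acceptance runs use
199 null replicates and 2 × 8-sample scenarios so the full suite
completes in about a minute on one CPU; the analysis scripts use a
five-site, 48-sample, 200-taxon gradient at depth 10,000 with the same
199-replicate nulls.

## Limitations

- The generator emulates the *statistical* structure a gradient survey
  needs (groups, depth, conserved traits, regime signatures), not real
  taxonomic composition, sequencing error or compositional bias; passing
  recovery tests demonstrates that the pipeline identifies regimes under
  its own generative assumptions, not that any field dataset satisfies
  them.
- Regime recovery is dataset-level stochastic: roughly one synthetic
  dataset in ten places a chance phylogenetic clustering in the
  group-pool split (dispersal-limitation regime) or an unlucky null draw
  (drift regime) strong enough to misdirect a sizable share of its pairs.
  This reflects a genuine identifiability limit of the indices at these
  sample sizes, not an implementation defect; averaging over replicate
  datasets makes the validation stable.
- The taxa-shuffle βNTI standardization assumes the null βMNTD
  distribution is adequately summarized by mean and sd; with very uneven
  abundances its skew can inflate |βNTI| slightly beyond nominal rates.
- Alternative null schemes (richness-constrained matrix swaps,
  within-clade shuffles, per-module species pools) and incidence-based
  Raup-Crick are out of scope.
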