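"""Phylogenetic and taxonomic turnover null models: betaMNTD, betaNTI, RCbray.

The two-stage framework standardizes pairwise community turnover against
null expectations:

* **betaMNTD** — abundance-weighted beta mean-nearest-taxon distance: the
  mean cophenetic distance from each taxon in one community to its closest
  relative in the other, weighted by relative abundance and averaged over
  both directions.
* **betaNTI** — the standardized effect size of observed betaMNTD against a
  null distribution obtained by shuffling taxon labels across the tips of
  the phylogeny (topology, branch lengths and the community matrix are
  preserved). |betaNTI| > 2 indicates that selection dominates the pair's
  turnover.
* **RCbray** — Raup-Crick standardization of observed Bray-Curtis against
  nulls built by probabilistic reassembly from the regional species pool,
  preserving each sample's richness and total abundance; occupancy weights
  the chance of being drawn into a community, pool relative abundance
  weights how individuals are allocated. RCbray in [-1, 1]; beyond +/-0.95
  indicates dispersal processes.

betaNTI is exactly invariant to rescaling all branch lengths by a positive
constant (observed value, null mean and null sd all scale linearly).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from fungal_assembly.community_io import CommunityTable
from fungal_assembly.diversity import bray_curtis

logger = logging.getLogger(__name__)


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip patristic distances (sum of branch lengths on the path)."""
    return tree.tip_tip_distances()


def beta_mntd(x, y, d: np.ndarray) -> float:
    """Abundance-weighted beta mean-nearest-taxon distance between two samples.

    Parameters
    ----------
    x, y : count (or relative abundance) vectors over the same taxon order.
    d : square cophenetic distance matrix over that taxon order.

    Each taxon present in one sample contributes its distance to the
    nearest taxon present in the *other* sample (self-distance 0 when the
    taxon is shared), weighted by its relative abundance; the two directed
    means are averaged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("empty community")
    ix = np.flatnonzero(x > 0)
    iy = np.flatnonzero(y > 0)
    fx = x[ix] / x[ix].sum()
    fy = y[iy] / y[iy].sum()
    sub = d[np.ix_(ix, iy)]
    return float(0.5 * (fx @ sub.min(axis=1) + fy @ sub.min(axis=0)))


@dataclass
class BetaMNTDResult:
    sample_i: str
    sample_j: str
    beta_mntd_obs: float
    null_mean: float
    null_sd: float
    beta_nti: float  # NaN when null sd == 0
    n_null: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.beta_nti)


@dataclass
class RaupCrickResult:
    sample_i: str
    sample_j: str
    bray_obs: float
    rc_bray: float
    n_null: int


def _all_pairs(samples: list[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(samples, 2))


def _tip_permutations(n_taxa: int, reps: int, seed: int) -> np.ndarray:
    """One taxa-shuffle per replicate; replicate r draws from substream (seed, r)
    so results do not depend on pair ordering or scheduling."""
    perms = np.empty((reps, n_taxa), dtype=np.intp)
    for r in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        perms[r] = rng.permutation(n_taxa)
    return perms


def null_beta_nti(
    table: CommunityTable,
    tree: TreeNode,
    reps: int = 999,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
    exhaustive: bool = False,
) -> list[BetaMNTDResult]:
    """betaNTI for sample pairs via the taxa-shuffle null.

    For each replicate, tip labels are permuted uniformly at random across
    all tips (the same ``reps`` permutations are reused for every pair) and
    betaMNTD is recomputed; betaNTI = (obs - null mean) / null sd with the
    n-1 sample standard deviation. With ``exhaustive=True`` all n! tip
    permutations are enumerated instead (small trees only) and ``reps`` and
    ``seed`` are ignored. Pairs whose null sd is zero get beta_nti = NaN and
    are excluded from downstream classification.
    """
    table = table.drop_empty_taxa()
    dm = cophenetic_distances(tree)
    taxa = table.taxa
    missing = [t for t in taxa if t not in dm.ids]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:5]}")
    idx = [dm.ids.index(t) for t in taxa]
    d = dm.data[np.ix_(idx, idx)]
    n_taxa = len(taxa)
    samples = table.samples
    if pairs is None:
        pairs = _all_pairs(samples)
    cols = {s: table.sample_counts(s).astype(float) for s in samples}

    obs = np.array([beta_mntd(cols[a], cols[b], d) for a, b in pairs])

    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n_taxa))), dtype=np.intp)
    else:
        if reps < 2:
            raise ValueError("reps must be >= 2")
        perms = _tip_permutations(n_taxa, reps, seed)
    n_null = len(perms)

    null = np.empty((n_null, len(pairs)))
    for r, perm in enumerate(perms):
        # shuffling tip labels == jointly permuting rows/cols of d
        dp = d[np.ix_(perm, perm)]
        for k, (a, b) in enumerate(pairs):
            null[r, k] = beta_mntd(cols[a], cols[b], dp)

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    results = []
    for k, (a, b) in enumerate(pairs):
        if sd[k] > 0:
            nti = (obs[k] - mean[k]) / sd[k]
        else:
            logger.warning(
                "null sd is zero for pair (%s, %s); betaNTI undefined", a, b
            )
            nti = np.nan
        results.append(
            BetaMNTDResult(a, b, float(obs[k]), float(mean[k]), float(sd[k]),
                           float(nti), n_null)
        )
    return results


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Sequential weighted sampling without replacement (exponential race)."""
    keys = rng.exponential(size=weights.size) / weights
    return np.argpartition(keys, k - 1)[:k]


def _null_community(
    k: int,
    total: int,
    occ_w: np.ndarray,
    ab_p: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assemble one null community: draw k taxa by occupancy, seed each with
    one individual, allocate the remaining total-k by pool relative abundance."""
    chosen = _weighted_sample_without_replacement(occ_w, k, rng)
    counts = np.zeros(occ_w.size, dtype=np.int64)
    counts[chosen] = 1
    remaining = total - k
    if remaining > 0:
        p = ab_p[chosen]
        counts[chosen] += rng.multinomial(remaining, p / p.sum())
    return counts


def raup_crick_bray(
    table: CommunityTable,
    reps: int = 999,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
) -> list[RaupCrickResult]:
    """Raup-Crick index on Bray-Curtis dissimilarity for sample pairs.

    The species pool is the full table: occupancy (number of samples in
    which a taxon occurs) weights which taxa enter a null community, and
    the taxon's total relative abundance weights how the remaining
    individuals are allocated. Null communities preserve each observed
    sample's richness and total count.

    RCbray = 2 * [(count(null < obs) + 0.5 * count(null == obs)) / reps - 0.5].
    Deterministic for a given seed, independent of pair ordering.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    table = table.drop_empty_taxa()
    counts = table.counts.to_numpy()
    occupancy = (counts > 0).sum(axis=1).astype(float)
    abundance = counts.sum(axis=1).astype(float)
    ab_p = abundance / abundance.sum()
    pool_richness = counts.shape[0]
    samples = table.samples
    sample_pos = {s: i for i, s in enumerate(samples)}
    if pairs is None:
        pairs = _all_pairs(samples)

    results = []
    for a, b in pairs:
        xa = counts[:, sample_pos[a]]
        xb = counts[:, sample_pos[b]]
        ka, kb = int((xa > 0).sum()), int((xb > 0).sum())
        if ka > pool_richness or kb > pool_richness:
            raise ValueError("sample richness exceeds pool richness")
        ta, tb = int(xa.sum()), int(xb.sum())
        obs = bray_curtis(xa, xb)
        i, j = sorted((sample_pos[a], sample_pos[b]))
        below = ties = 0
        for r in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(i, j, r))
            )
            na = _null_community(ka, ta, occupancy, ab_p, rng)
            nb = _null_community(kb, tb, occupancy, ab_p, rng)
            bc = bray_curtis(na, nb)
            if abs(bc - obs) <= 1e-12:
                ties += 1
            elif bc < obs:
                below += 1
        rc = 2.0 * ((below + 0.5 * ties) / reps - 0.5)
        results.append(RaupCrickResult(a, b, float(obs), float(rc), reps))
    return results
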