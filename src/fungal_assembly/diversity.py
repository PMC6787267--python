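"""Rarefaction, alpha diversity, beta diversity and distance decay.

Shannon entropy is reported in nats (natural log). Beta diversity is
intended to be computed on rarefied counts, where equal sequencing depth
makes abundance-based Bray-Curtis on counts identical to Bray-Curtis on
relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import braycurtis as _sp_braycurtis
from skbio import DistanceMatrix

from fungal_assembly.community_io import CommunityTable

logger = logging.getLogger(__name__)


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per sample; samples whose total
    is below ``depth`` are dropped with a logged warning. Deterministic
    for a given seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    kept = {}
    dropped = []
    for sample in table.samples:
        col = table.sample_counts(sample)
        total = int(col.sum())
        if total < depth:
            dropped.append(sample)
            continue
        if total == depth:
            kept[sample] = col.copy()
        else:
            kept[sample] = rng.multivariate_hypergeometric(col, depth)
    if dropped:
        logger.warning(
            "dropped %d samples below depth %d: %s", len(dropped), depth, dropped
        )
    if not kept:
        raise ValueError(f"all samples have fewer than {depth} reads")
    out = pd.DataFrame(kept, index=table.taxa, dtype=np.int64)
    out.index.name = table.counts.index.name
    return CommunityTable(out)


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i over positive counts, in nats."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def richness(counts) -> int:
    """Number of taxa with count > 0."""
    c = np.asarray(counts)
    return int((c > 0).sum())


def alpha_diversity(table: CommunityTable) -> pd.DataFrame:
    """Per-sample Shannon (nats) and richness."""
    rows = {
        s: {"shannon": shannon(table.sample_counts(s)),
            "richness": richness(table.sample_counts(s))}
        for s in table.samples
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample"
    return df


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError("count vectors differ in length")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("zero-total count vector")


def bray_curtis(x, y) -> float:
    """Abundance-based Bray-Curtis dissimilarity in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    return float(_sp_braycurtis(x, y))


def jaccard(x, y) -> float:
    """Presence/absence Jaccard dissimilarity = 1 - |shared| / |union|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    a = x > 0
    b = y > 0
    union = int((a | b).sum())
    shared = int((a & b).sum())
    return 1.0 - shared / union


_METRICS = {"bray": bray_curtis, "jaccard": jaccard}


def beta_diversity(table: CommunityTable, metric: str = "bray") -> DistanceMatrix:
    """All-pairs dissimilarity matrix over the table's samples."""
    try:
        fn = _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    samples = table.samples
    n = len(samples)
    mat = np.zeros((n, n))
    cols = [table.sample_counts(s) for s in samples]
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = fn(cols[i], cols[j])
    return DistanceMatrix(mat, ids=samples)


def elevation_distance(elevations: pd.Series) -> DistanceMatrix:
    """Pairwise |delta elevation| in meters (1-D Euclidean)."""
    e = elevations.astype(float)
    mat = np.abs(e.to_numpy()[:, None] - e.to_numpy()[None, :])
    return DistanceMatrix(mat, ids=[str(i) for i in e.index])


@dataclass
class DistanceDecayResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n_pairs: int
    n_permutations: int


def distance_decay(
    beta: DistanceMatrix,
    elevations: pd.Series,
    permutations: int = 999,
    seed: int = 0,
) -> DistanceDecayResult:
    """OLS of pairwise beta diversity on pairwise elevational distance.

    The regression runs over the n(n-1)/2 unordered sample pairs; because
    pairs are not independent, the p-value comes from a Mantel-style
    permutation of sample labels (one-tailed, correlation >= observed,
    add-one convention).
    """
    ids = list(beta.ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 samples")
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    missing = [s for s in ids if s not in elevations.index]
    if missing:
        raise ValueError(f"samples without elevation: {missing}")
    e = elevations.loc[ids].to_numpy(dtype=float)
    bmat = beta.data
    iu = np.triu_indices(len(ids), k=1)
    y = bmat[iu]
    edist = np.abs(e[:, None] - e[None, :])
    x = edist[iu]
    if np.ptp(x) == 0:
        raise ValueError("elevational distances are constant")
    fit = sps.linregress(x, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(len(ids))
        xp = np.abs(e[perm][:, None] - e[perm][None, :])[iu]
        if np.ptp(xp) == 0:
            rp = 0.0
        else:
            rp = np.corrcoef(xp, y)[0, 1]
        if rp >= fit.rvalue:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return DistanceDecayResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(p),
        n_pairs=len(y),
        n_permutations=permutations,
    )
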