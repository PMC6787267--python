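"""Permutation and correlation statistics: ANOSIM, Mantel, partial Mantel, Pearson.

All permutation tests use the add-one convention
p = (count(perm statistic >= observed) + 1) / (n_permutations + 1),
one-tailed (greater), and are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    method: str


def _condensed(dm: DistanceMatrix) -> np.ndarray:
    n = dm.shape[0]
    iu = np.triu_indices(n, k=1)
    return dm.data[iu]


def _check_same_ids(*dms: DistanceMatrix) -> None:
    ids = dms[0].ids
    for dm in dms[1:]:
        if tuple(dm.ids) != tuple(ids):
            raise ValueError("distance matrices must share the same item order")


def _anosim_r(ranks: np.ndarray, within: np.ndarray, m: int) -> float:
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return (rb - rw) / (m / 2.0)


def anosim(
    d: DistanceMatrix,
    groups,
    permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """ANOSIM: are between-group dissimilarities larger (in rank) than within?

    R = (mean rank between - mean rank within) / (M/2), M = n(n-1)/2,
    ranks averaged over ties; p by permuting group labels.
    """
    groups = np.asarray([str(g) for g in groups])
    n = d.shape[0]
    if len(groups) != n:
        raise ValueError("one group label per sample required")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with a single sample: {small}")
    iu = np.triu_indices(n, k=1)
    dist = d.data[iu]
    ranks = sps.rankdata(dist)
    m = dist.size
    within = groups[iu[0]] == groups[iu[1]]
    r_obs = _anosim_r(ranks, within, m)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        gp = groups[perm]
        wp = gp[iu[0]] == gp[iu[1]]
        if _anosim_r(ranks, wp, m) >= r_obs:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return PermutationTestResult(float(r_obs), float(p), permutations, seed, "anosim")


def _pearson_vec(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant distance vector: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Mantel test: Pearson r between two distance matrices' lower triangles,
    p by jointly permuting rows/columns of d1."""
    _check_same_ids(d1, d2)
    n = d1.shape[0]
    v2 = _condensed(d2)
    iu = np.triu_indices(n, k=1)
    r_obs = _pearson_vec(_condensed(d1), v2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        dp = d1.data[np.ix_(perm, perm)][iu]
        if np.ptp(dp) == 0:
            continue
        if np.corrcoef(dp, v2)[0, 1] >= r_obs:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return PermutationTestResult(float(r_obs), float(p), permutations, seed, "mantel")


def _partial_r(r12: float, r13: float, r23: float) -> float:
    denom = (1 - r13**2) * (1 - r23**2)
    if denom <= 0:
        raise ValueError("conditioning matrix perfectly correlated with an input")
    return (r12 - r13 * r23) / np.sqrt(denom)


def partial_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    d3: DistanceMatrix,
    permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Partial Mantel: first-order partial correlation of d1 and d2 given d3.

    r(d1,d2|d3) = (r12 - r13*r23) / sqrt((1-r13^2)(1-r23^2)) on the
    condensed vectors; p by permuting d1's rows/columns and recomputing.
    """
    _check_same_ids(d1, d2, d3)
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1, v2, v3 = _condensed(d1), _condensed(d2), _condensed(d3)
    r12 = _pearson_vec(v1, v2)
    r13 = _pearson_vec(v1, v3)
    r23 = _pearson_vec(v2, v3)
    if abs(r13) >= 1 or abs(r23) >= 1:
        raise ValueError("perfect correlation with conditioning matrix")
    r_obs = _partial_r(r12, r13, r23)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        vp = d1.data[np.ix_(perm, perm)][iu]
        if np.ptp(vp) == 0:
            continue
        rp12 = np.corrcoef(vp, v2)[0, 1]
        rp13 = np.corrcoef(vp, v3)[0, 1]
        denom = (1 - rp13**2) * (1 - r23**2)
        if denom <= 0:
            continue
        if (rp12 - rp13 * r23) / np.sqrt(denom) >= r_obs:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return PermutationTestResult(
        float(r_obs), float(p), permutations, seed, "partial_mantel"
    )


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-tailed t-test p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_table(alpha: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and p of each alpha-diversity index against each covariate."""
    rows = []
    common = alpha.index.intersection(covariates.index)
    for index_col in alpha.columns:
        for cov in covariates.columns:
            sub = pd.concat(
                [alpha.loc[common, index_col], covariates.loc[common, cov]], axis=1
            ).dropna()
            r, p = pearson(sub.iloc[:, 0], sub.iloc[:, 1])
            rows.append({"diversity_index": index_col, "covariate": cov,
                         "r": r, "p_value": p, "n": len(sub)})
    return pd.DataFrame(rows)
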