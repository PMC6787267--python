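import itertools

import numpy as np
import pandas as pd
import pytest

from fungal_assembly import (
    CommunityTable,
    beta_mntd,
    bray_curtis,
    cophenetic_distances,
    null_beta_nti,
    raup_crick_bray,
)

from conftest import toy_tree


def brute_force_beta_mntd(x, y, d):
    """Independent double-loop reference for the abundance-weighted
    beta mean-nearest-taxon distance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    total = 0.0
    for present, other in ((x, y), (y, x)):
        f = present / present.sum()
        acc = 0.0
        for i in np.flatnonzero(present):
            best = min(d[i, j] for j in np.flatnonzero(other))
            acc += f[i] * best
        total += 0.5 * acc
    return total


def table_from(matrix, taxa, samples):
    return CommunityTable(
        pd.DataFrame(np.asarray(matrix, dtype=np.int64), index=taxa,
                     columns=samples)
    )


class TestCophenetic:
    def test_path_sums_by_hand(self, three_tip_tree):
        dm = cophenetic_distances(three_tip_tree)
        assert dm["A", "B"] == 2.0
        assert dm["A", "C"] == 4.0
        assert dm["B", "C"] == 4.0
        assert np.allclose(np.diag(dm.data), 0.0)

    def test_star_tree(self):
        dm = cophenetic_distances(toy_tree("(A:3,B:3,C:3,D:3);"))
        off = dm.data[np.triu_indices(4, 1)]
        assert np.allclose(off, 6.0)


class TestBetaMNTD:
    def test_identical_supports_give_zero(self, three_tip_tree):
        d = cophenetic_distances(three_tip_tree).data
        assert beta_mntd([3, 1, 2], [1, 5, 9], d) == 0.0

    def test_two_singletons(self, three_tip_tree):
        dm = cophenetic_distances(three_tip_tree)
        d = dm.data
        ia, ic = dm.ids.index("A"), dm.ids.index("C")
        x = np.zeros(3)
        y = np.zeros(3)
        x[ia] = 4
        y[ic] = 7
        assert beta_mntd(x, y, d) == pytest.approx(dm["A", "C"])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = 5
            # random additive distances from a random tree-free metric proxy:
            # any symmetric non-negative matrix with zero diagonal works here
            d = rng.uniform(0.1, 3.0, (n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            x = rng.integers(0, 5, n)
            y = rng.integers(0, 5, n)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert beta_mntd(x, y, d) == pytest.approx(
                brute_force_beta_mntd(x, y, d)
            )

    def test_symmetry(self, three_tip_tree):
        d = cophenetic_distances(three_tip_tree).data
        x, y = [3, 0, 1], [0, 2, 2]
        assert beta_mntd(x, y, d) == pytest.approx(beta_mntd(y, x, d))


class TestBetaNTI:
    TREE = "(((A:1,B:2):1,C:3):1,(D:1,E:1):2);"

    def exhaustive_oracle(self, table, tree, pairs):
        """Enumerate every tip permutation and standardize by hand."""
        dm = cophenetic_distances(tree)
        taxa = table.taxa
        idx = [dm.ids.index(t) for t in taxa]
        d = dm.data[np.ix_(idx, idx)]
        cols = {s: table.sample_counts(s).astype(float) for s in table.samples}
        out = {}
        for a, b in pairs:
            obs = brute_force_beta_mntd(cols[a], cols[b], d)
            null = [
                brute_force_beta_mntd(
                    cols[a], cols[b], d[np.ix_(perm, perm)]
                )
                for perm in itertools.permutations(range(len(taxa)))
            ]
            null = np.array(null)
            out[(a, b)] = (obs - null.mean()) / null.std(ddof=1)
        return out

    def test_exhaustive_enumeration_matches_oracle(self):
        tree = toy_tree("((A:1,B:2):1,(C:3,D:1):2);")
        table = table_from([[5, 0], [1, 2], [0, 4], [3, 1]],
                           list("ABCD"), ["X", "Y"])
        res = null_beta_nti(table, tree, exhaustive=True,
                            pairs=[("X", "Y")])
        oracle = self.exhaustive_oracle(table, tree, [("X", "Y")])
        assert res[0].n_null == 24
        assert res[0].beta_nti == pytest.approx(oracle[("X", "Y")])

    def test_identical_communities_nonpositive(self):
        tree = toy_tree(self.TREE)
        table = table_from([[2, 2], [1, 1], [0, 0], [3, 3], [1, 1]],
                           list("ABCDE"), ["X", "Y"])
        res = null_beta_nti(table, tree, reps=99, seed=0)
        assert res[0].beta_mntd_obs == 0.0
        assert res[0].beta_nti <= 0.0 or not res[0].defined

    def test_branch_length_scale_invariance(self):
        tree1 = toy_tree(self.TREE)
        tree10 = toy_tree("(((A:10,B:20):10,C:30):10,(D:10,E:10):20);")
        table = table_from([[4, 0], [1, 2], [0, 5], [2, 1], [0, 3]],
                           list("ABCDE"), ["X", "Y"])
        r1 = null_beta_nti(table, tree1, reps=49, seed=3)[0]
        r10 = null_beta_nti(table, tree10, reps=49, seed=3)[0]
        assert r10.beta_mntd_obs == pytest.approx(10 * r1.beta_mntd_obs)
        assert r10.beta_nti == pytest.approx(r1.beta_nti)

    def test_deterministic_and_pair_order_independent(self):
        tree = toy_tree(self.TREE)
        table = table_from(
            [[4, 0, 1], [1, 2, 0], [0, 5, 2], [2, 1, 1], [0, 3, 4]],
            list("ABCDE"), ["X", "Y", "Z"],
        )
        pairs = [("X", "Y"), ("X", "Z")]
        a = null_beta_nti(table, tree, reps=49, seed=3, pairs=pairs)
        b = null_beta_nti(table, tree, reps=49, seed=3, pairs=pairs[::-1])
        by_pair_a = {(r.sample_i, r.sample_j): r.beta_nti for r in a}
        by_pair_b = {(r.sample_i, r.sample_j): r.beta_nti for r in b}
        assert by_pair_a == by_pair_b

    def test_null_calibration_under_tip_shuffle(self):
        # data made phylogeny-free by construction: betaNTI should be
        # centred and rarely beyond +/-2
        rng = np.random.default_rng(2)
        tree = toy_tree(
            "((((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1):1,"
            "(((I:1,J:1):1,(K:1,L:1):1):1,((M:1,N:1):1,(O:1,P:1):1):1):1);"
        )
        taxa = list("ABCDEFGHIJKLMNOP")
        ntis = []
        for trial in range(30):
            counts = rng.integers(0, 6, size=(16, 2))
            if (counts.sum(axis=0) == 0).any():
                continue
            table = table_from(counts, taxa, ["X", "Y"])
            res = null_beta_nti(table, tree, reps=99, seed=trial)
            if res[0].defined:
                ntis.append(res[0].beta_nti)
        ntis = np.array(ntis)
        assert abs(ntis.mean()) < 0.5
        assert (np.abs(ntis) > 2).mean() <= 0.15


class TestRaupCrick:
    def pool_table(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 8, size=(12, 6))
        counts[:, 1] = counts[:, 0]  # two identical communities in the pool
        counts[0] += 1  # keep every sample non-empty
        taxa = [f"OTU_{i}" for i in range(12)]
        return table_from(counts, taxa, [f"S{j}" for j in range(6)])

    def test_bounds_and_identical_pair_near_minus_one(self):
        table = self.pool_table()
        res = raup_crick_bray(table, reps=199, seed=1)
        assert all(-1.0 <= r.rc_bray <= 1.0 for r in res)
        identical = [r for r in res
                     if {r.sample_i, r.sample_j} == {"S0", "S1"}][0]
        assert identical.bray_obs == 0.0
        assert identical.rc_bray <= -0.9

    def test_obs_outside_null_support_hits_boundaries(self):
        table = self.pool_table()
        res = raup_crick_bray(table, reps=49, seed=2,
                              pairs=[("S0", "S1")])[0]
        # obs = 0 can never exceed a null Bray-Curtis, so RC = -1 exactly
        # unless some null draw ties at zero
        assert res.rc_bray == pytest.approx(-1.0, abs=0.05)

    def test_matches_independent_null_sampler(self):
        """Cross-check against a separately coded null: same occupancy-
        weighted selection and abundance-weighted allocation, implemented
        with inverse-CDF sampling instead of the exponential race."""
        table = self.pool_table()
        pair = ("S2", "S4")
        res = raup_crick_bray(table, reps=199, seed=3, pairs=[pair])[0]

        counts = table.counts.to_numpy()
        occ = (counts > 0).sum(axis=1).astype(float)
        ab = counts.sum(axis=1).astype(float)
        rng = np.random.default_rng(99)
        i, j = table.samples.index(pair[0]), table.samples.index(pair[1])
        obs = bray_curtis(counts[:, i], counts[:, j])

        def one_null(col):
            k, total = int((col > 0).sum()), int(col.sum())
            chosen = []
            avail = list(range(len(occ)))
            w = occ.copy()
            for _ in range(k):
                p = w[avail] / w[avail].sum()
                pick = rng.choice(avail, p=p)
                chosen.append(pick)
                avail.remove(pick)
            out = np.zeros(len(occ), dtype=int)
            out[chosen] = 1
            p_ab = ab[chosen] / ab[chosen].sum()
            out[chosen] += rng.multinomial(total - k, p_ab)
            return out

        nulls = np.array([
            bray_curtis(one_null(counts[:, i]), one_null(counts[:, j]))
            for _ in range(199)
        ])
        rc_ref = 2 * (((nulls < obs).sum() + 0.5 * (nulls == obs).sum())
                      / len(nulls) - 0.5)
        assert res.rc_bray == pytest.approx(rc_ref, abs=0.25)

    def test_bit_reproducible_and_pair_order_independent(self):
        table = self.pool_table()
        pairs = [("S0", "S2"), ("S3", "S5")]
        a = raup_crick_bray(table, reps=99, seed=5, pairs=pairs)
        b = raup_crick_bray(table, reps=99, seed=5, pairs=pairs[::-1])
        by_a = {(r.sample_i, r.sample_j): r.rc_bray for r in a}
        by_b = {(r.sample_i, r.sample_j): r.rc_bray for r in b}
        assert by_a == by_b
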