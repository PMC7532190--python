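import numpy as np
import pytest
from scipy.optimize import minimize

from evoscape.core_io import RangeTable, load_tree
from evoscape.phylo import (Chronogram, RateMatrix, asr_bm, bm_rate, patristic,
                            sim_bm, timescale_equal, timescale_initial,
                            timescale_mbl)


def chain_durations(chron):
    """Durations along the root->I1->I2->t0 chain of the chain_tree fixture."""
    dur = chron.durations()
    return dur[5], dur[4], dur[0]


class TestTimescaleInitial:
    def test_node_ages_from_fads(self):
        tree = load_tree("((A,B),C);", ["A", "B", "C"])
        ranges = RangeTable(taxa=["A", "B", "C"], fad=[100, 90, 80],
                            lad=[95, 85, 75])
        chron = timescale_initial(tree, ranges, root_extension=5.0)
        ages = {chron.labels[i]: chron.ages[i] for i in range(3)}
        assert ages == {"A": 100, "B": 90, "C": 80}
        ab = chron.parent[chron.tip_index("A")]
        assert chron.ages[ab] == 100  # oldest descendant
        assert chron.ages[chron.root] == 105

    def test_equal_fads_give_zero_duration_branch(self):
        tree = load_tree("((A,B),C);", ["A", "B", "C"])
        ranges = RangeTable(taxa=["A", "B", "C"], fad=[90, 90, 80],
                            lad=[80, 80, 70])
        chron = timescale_initial(tree, ranges, root_extension=3.0)
        assert np.nanmin(chron.durations()) == pytest.approx(0.0)

    def test_negative_root_extension_rejected(self):
        tree = load_tree("(A,B);", ["A", "B"])
        ranges = RangeTable(taxa=["A", "B"], fad=[90, 90], lad=[80, 80])
        with pytest.raises(ValueError, match="root_extension"):
            timescale_initial(tree, ranges, root_extension=-1.0)

    def test_missing_range_rejected(self):
        tree = load_tree("(A,B);", ["A", "B"])
        ranges = RangeTable(taxa=["A"], fad=[90], lad=[80])
        with pytest.raises(ValueError, match="range"):
            timescale_initial(tree, ranges)


class TestTimescaleEqual:
    def test_shares_donor_time_along_zero_run(self, chain_tree):
        eq = timescale_equal(chain_tree)
        assert chain_durations(eq) == pytest.approx((2, 2, 2))

    def test_single_zero_branch_splits_in_half(self):
        # (6, 0) path root->X->a; sibling c anchors X's subtree
        chron = Chronogram(labels=["a", "c"], parent=np.array([2, 2, 3, -1]),
                           ages=np.array([2.0, 0.0, 2.0, 8.0]))
        eq = timescale_equal(chron)
        dur = eq.durations()
        assert dur[0] == pytest.approx(3.0)  # X -> a
        assert dur[2] == pytest.approx(3.0)  # root -> X
        assert eq.ages[0] == 2.0  # tip unchanged

    def test_identity_without_zero_branches(self, quartet_tree):
        eq = timescale_equal(quartet_tree)
        assert np.allclose(eq.ages, quartet_tree.ages)

    def test_zero_run_to_root_is_an_error(self):
        chron = Chronogram(labels=["a", "b"], parent=np.array([2, 2, -1]),
                           ages=np.array([5.0, 0.0, 5.0]))
        with pytest.raises(ValueError, match="root_extension"):
            timescale_equal(chron)

    def test_preserves_root_to_tip_totals(self, chain_tree):
        eq = timescale_equal(chain_tree)
        assert np.allclose(eq.ages[:4], chain_tree.ages[:4])
        assert eq.ages[eq.root] == chain_tree.ages[chain_tree.root]


class TestTimescaleMbl:
    def test_chain_example(self, chain_tree):
        mb = timescale_mbl(chain_tree, 1.0)
        assert chain_durations(mb) == pytest.approx((4, 1, 1))

    def test_no_change_when_all_long_enough(self, quartet_tree):
        mb = timescale_mbl(quartet_tree, 0.5)
        assert np.allclose(mb.ages, quartet_tree.ages)

    def test_root_pushed_older(self):
        chron = Chronogram(labels=["a", "b"], parent=np.array([2, 2, -1]),
                           ages=np.array([0.0, 0.0, 0.5]))
        mb = timescale_mbl(chron, 3.0)
        assert mb.ages[2] == pytest.approx(3.0)  # pushed older by 2.5
        assert np.nanmin(mb.durations()) >= 3.0

    def test_requires_positive_mbl(self, chain_tree):
        with pytest.raises(ValueError, match="mbl"):
            timescale_mbl(chain_tree, 0.0)


class TestPatristic:
    def test_two_tips(self, two_tip_tree):
        D = patristic(two_tip_tree)
        assert D.D[0, 1] == pytest.approx(3.0)
        assert D.D[0, 0] == 0.0

    def test_triplet_symmetry(self):
        tree = load_tree("((A:1,B:1):1,C:2);", ["A", "B", "C"])
        chron = Chronogram.from_tree(tree)
        D = patristic(chron).D
        i = {t: n for n, t in enumerate(patristic(chron).taxa)}
        assert D[i["A"], i["B"]] == pytest.approx(2.0)
        assert D[i["A"], i["C"]] == pytest.approx(D[i["B"], i["C"]])
        assert D[i["A"], i["C"]] == pytest.approx(4.0)


class TestASR:
    def test_two_tip_root_is_inverse_duration_weighted_mean(self, two_tip_tree):
        vals = asr_bm(two_tip_tree, np.array([[0.0], [3.0]]))
        assert vals[2, 0] == pytest.approx(1.0)

    def test_constant_tips_everywhere_constant(self, quartet_tree):
        vals = asr_bm(quartet_tree, np.full((4, 2), 7.0))
        assert np.allclose(vals, 7.0)

    def test_matches_numerical_minimizer(self, random_tree_16):
        chron = random_tree_16
        rng = np.random.default_rng(0)
        x = rng.normal(size=chron.n_tips)
        est = asr_bm(chron, x[:, None])[chron.n_tips:, 0]
        dur = chron.durations()

        def objective(internal):
            full = np.concatenate([x, internal])
            s = 0.0
            for v in range(chron.n_nodes):
                p = chron.parent[v]
                if p >= 0:
                    s += (full[v] - full[p]) ** 2 / max(dur[v], 1e-8)
            return s

        res = minimize(objective, est + rng.normal(scale=0.5, size=est.size),
                       method="L-BFGS-B", tol=1e-14)
        assert np.allclose(est, res.x, atol=1e-5)

    def test_root_equals_gls_phylogenetic_mean(self, random_tree_16):
        chron = random_tree_16
        rng = np.random.default_rng(1)
        x = rng.normal(size=chron.n_tips)
        root_hat = asr_bm(chron, x[:, None])[chron.root, 0]
        # GLS mean with BM covariance C_ij = shared path length from root
        n = chron.n_tips
        root_age = chron.ages[chron.root]
        P = patristic(chron).D
        depth_i = root_age - chron.ages[:n]
        C = 0.5 * (depth_i[:, None] + depth_i[None, :] - P)
        Cinv = np.linalg.inv(C)
        ones = np.ones(n)
        gls = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
        assert root_hat == pytest.approx(gls, abs=1e-8)

    def test_degenerate_two_tip_zero_durations(self):
        chron = Chronogram(labels=["a", "b"], parent=np.array([2, 2, -1]),
                           ages=np.array([5.0, 5.0, 5.0]))
        with pytest.raises(ValueError, match="no finite ML"):
            asr_bm(chron, np.array([[0.0], [1.0]]))


class TestBMRate:
    def test_star_like_tree_recovers_variance(self):
        # near-star topology: a comb whose internal nodes are epsilon-spaced
        # just above age 1, tips at 0 -> contrasts ~ iid increments
        n = 500
        labels = [f"t{i}" for i in range(n)]
        M = 2 * n - 1
        parent = np.full(M, -1)
        age = np.zeros(M)
        prev = 0
        for k, v in enumerate(range(n, M)):
            parent[prev] = v
            parent[k + 1] = v
            age[v] = 1.0 + 1e-6 * k
            prev = v
        chron = Chronogram(labels=labels, parent=parent, ages=age)
        rng = np.random.default_rng(3)
        sigma2 = 0.7
        x = sim_bm(chron, RateMatrix(R=np.array([[sigma2]])), np.zeros(1), 1,
                   seed=10)[0, :n, 0]
        est = bm_rate(chron, x[:, None]).R[0, 0]
        assert abs(est - sigma2) / sigma2 < 0.15

    def test_constant_tips_zero_rate(self, quartet_tree):
        R = bm_rate(quartet_tree, np.full((4, 2), 3.0))
        assert np.allclose(R.R, 0.0)

    def test_needs_three_tips(self, two_tip_tree):
        with pytest.raises(ValueError, match="3 tips"):
            bm_rate(two_tip_tree, np.array([[0.0], [1.0]]))


class TestSimBM:
    def test_zero_rate_keeps_root_value(self, quartet_tree):
        out = sim_bm(quartet_tree, RateMatrix(R=np.zeros((2, 2))),
                     np.array([1.0, -2.0]), 5, seed=0)
        assert np.allclose(out, np.array([1.0, -2.0]))

    def test_tip_variance_scales_with_depth(self, quartet_tree):
        out = sim_bm(quartet_tree, RateMatrix(R=np.eye(1)), np.zeros(1), 2000,
                     seed=1)
        var = out[:, 0, 0].var()
        assert 0.9 * 2.0 <= var <= 1.1 * 2.0  # tip depth 2, unit rate

    def test_seeded_reproducibility(self, quartet_tree):
        a = sim_bm(quartet_tree, RateMatrix(R=np.eye(2)), np.zeros(2), 3, seed=5)
        b = sim_bm(quartet_tree, RateMatrix(R=np.eye(2)), np.zeros(2), 3, seed=5)
        assert np.array_equal(a, b)

    def test_non_psd_rate_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            RateMatrix(R=np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestPrune:
    def test_prune_preserves_ages_and_patristic(self, random_tree_16):
        chron = random_tree_16
        keep = chron.labels[:10]
        sub = chron.prune(keep)
        assert sorted(sub.labels) == sorted(keep)
        P_full = patristic(chron)
        P_sub = patristic(sub)
        for a in keep[:4]:
            for b in keep[4:8]:
                i, j = P_full.taxa.index(a), P_full.taxa.index(b)
                i2, j2 = P_sub.taxa.index(a), P_sub.taxa.index(b)
                assert P_sub.D[i2, j2] == pytest.approx(P_full.D[i, j])

    def test_newick_roundtrip(self, random_tree_16):
        nwk = random_tree_16.to_newick()
        tree = load_tree(nwk, random_tree_16.labels)
        back = Chronogram.from_tree(tree)
        assert sorted(back.labels) == sorted(random_tree_16.labels)
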