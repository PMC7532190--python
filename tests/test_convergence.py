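import numpy as np
import pytest

from evoscape.convergence import (angle_state_convergence, stayton_metrics,
                                  stayton_pvalues)
from evoscape.phylo import Chronogram


@pytest.fixture
def injected_case():
    """Two cherries off a root: lineage ancestors (0.5) and (2) below an
    MRCA at 0, with off-path tips B (0) and D (3)."""
    chron = Chronogram(labels=["A", "B", "C", "D"],
                       parent=np.array([4, 4, 5, 5, 6, 6, -1]),
                       ages=np.array([0, 0, 0, 0, 1, 1, 2.0]))
    anc = np.array([[1.0], [0.0], [1.1], [3.0], [0.5], [2.0], [0.0]])
    X = anc[:4]
    return chron, X, anc


class TestStaytonMetrics:
    def test_injected_hand_example(self, injected_case):
        chron, X, anc = injected_case
        m = stayton_metrics(chron, X, ["A", "C"], anc=anc)
        assert m["C1"] == pytest.approx(1 - 0.1 / 1.5, abs=1e-10)
        assert m["C2"] == pytest.approx(1.4, abs=1e-10)
        assert m["C3"] == pytest.approx(1.4 / 3.9, abs=1e-10)
        assert m["C4"] == pytest.approx(1.4 / 5.4, abs=1e-10)

    def test_identical_tips_give_c1_of_one(self, injected_case):
        chron, X, anc = injected_case
        anc2 = anc.copy()
        anc2[2, 0] = anc2[0, 0]  # tip C == tip A
        m = stayton_metrics(chron, anc2[:4], ["A", "C"], anc=anc2)
        assert m["C1"] == pytest.approx(1.0)

    def test_metric_identities(self, random_tree_16):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(16, 3))
        from evoscape.convergence import _PairGeometry, _pair_metrics
        from evoscape.phylo import asr_bm

        V = asr_bm(random_tree_16, X)
        checked = 0
        for a, b in [(0, 9), (1, 12), (3, 14), (2, 8)]:
            g = _PairGeometry(random_tree_16, a, b)
            pm = _pair_metrics(V, g)
            if pm["C1"] <= 0 or pm["C1"] >= 1:
                continue
            checked += 1
            dtip = np.linalg.norm(V[a] - V[b])
            dmax = dtip / (1 - pm["C1"])
            assert pm["C2"] == pytest.approx(pm["C1"] * dmax, abs=1e-10)
            l_lin = pm["C2"] / pm["C3"]
            l_clade = pm["C2"] / pm["C4"]
            assert l_clade >= l_lin - 1e-10  # clade includes the two lineages
        assert checked >= 1

    def test_rotation_invariance(self, random_tree_16):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(16, 2))
        theta = 0.7
        Q = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        m1 = stayton_metrics(random_tree_16, X, [0, 9])
        m2 = stayton_metrics(random_tree_16, X @ Q.T, [0, 9])
        for k in m1:
            assert m1[k] == pytest.approx(m2[k], abs=1e-9)

    def test_c1_bounded_zero_one(self, random_tree_16):
        rng = np.random.default_rng(4)
        for _ in range(20):
            X = rng.normal(size=(16, 2))
            m = stayton_metrics(random_tree_16, X, [1, 12])
            assert 0.0 <= m["C1"] <= 1.0

    def test_no_divergence_is_an_error(self, quartet_tree):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="Dmax"):
            stayton_metrics(quartet_tree, X, ["A", "C"])

    def test_unknown_focal_tip(self, quartet_tree):
        with pytest.raises(ValueError, match="not in tree"):
            stayton_metrics(quartet_tree, np.zeros((4, 1)), ["A", "Z"])


class TestStaytonPvalues:
    def test_seeded_reproducibility(self, random_tree_16):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(16, 2))
        r1 = stayton_pvalues(random_tree_16, X, [0, 9], nsim=50, seed=9)
        r2 = stayton_pvalues(random_tree_16, X, [0, 9], nsim=50, seed=9)
        assert r1 == r2

    def test_pvalues_in_unit_interval(self, random_tree_16):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(16, 2))
        res = stayton_pvalues(random_tree_16, X, [2, 13], nsim=50, seed=1)
        for m in ("C1", "C2", "C3", "C4"):
            assert 0.0 < res[f"p_{m}"] <= 1.0

    def test_convergent_pair_detected(self, synth_default):
        from evoscape.synthdata import convergent_focal_groups
        from evoscape.traitprep import (euclidean_missing,
                                        filter_by_completeness, ztransform)
        from evoscape.ordination import pcoa_cailliez

        data = synth_default
        filt, _ = filter_by_completeness(data["table"], 0.45, "craniodental")
        filt = filt.select_traits(trait_class="craniodental")
        D = euclidean_missing(ztransform(filt))
        pc = pcoa_cailliez(D)
        chron = data["chronogram"].prune(D.taxa)
        groups = convergent_focal_groups(chron, data["truth"])
        order = [D.taxa.index(t) for t in chron.labels]
        X = pc.coords[order][:, :2]
        ps = [stayton_pvalues(chron, X, tips, nsim=200, seed=3)["p_C1"]
              for tips in groups.values() if len(tips) >= 2]
        assert min(ps) < 0.05


class TestAngleConvergence:
    @pytest.fixture
    def star(self):
        return Chronogram(labels=["a", "b", "c", "d"],
                          parent=np.array([4, 4, 4, 4, -1]),
                          ages=np.array([0.0, 0, 0, 0, 5.0]))

    def test_right_angle(self, star):
        X = np.array([[1.0, 0], [0, 1.0], [1, 1], [-2, -2]])  # centred
        res = angle_state_convergence(star, X, ["a", "b"], nrand=10, seed=0)
        assert res["ang_state"] == pytest.approx(90.0)

    def test_hand_example_mean_angle_and_per_ma(self, star):
        X = np.array([[1.0, 0], [0, 1.0], [1, 1], [-2, -2]])
        res = angle_state_convergence(star, X, ["a", "b", "c"], nrand=10,
                                      seed=0)
        assert res["ang_state"] == pytest.approx(60.0)
        assert res["ang_state_time"] == pytest.approx(6.0)  # 10 Ma apart

    def test_zero_norm_state_tip_rejected(self, star):
        # tip a sits exactly at the centroid, so its centred vector is zero
        X = np.array([[0.0, 0.0], [0, 4.0], [4, 0], [-4, -4]])
        with pytest.raises(ValueError, match="zero-norm"):
            angle_state_convergence(star, X, ["a", "b"], nrand=5, seed=0)

    def test_small_angles_flag_convergence(self, star):
        X = np.array([[2.0, 0.1], [2.0, -0.1], [-1, 3], [-3, -3]])
        res = angle_state_convergence(star, X, ["a", "b"], nrand=200, seed=0)
        rand_res = angle_state_convergence(star, X, ["a", "c"], nrand=200,
                                           seed=0)
        assert res["ang_state"] < rand_res["ang_state"]

    def test_seeded_reproducibility(self, star):
        X = np.array([[1.0, 0], [0, 1.0], [1, 1], [-2, -2]])
        r1 = angle_state_convergence(star, X, ["a", "b"], nrand=50, seed=2)
        r2 = angle_state_convergence(star, X, ["a", "b"], nrand=50, seed=2)
        assert r1 == r2
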