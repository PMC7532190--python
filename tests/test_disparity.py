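import numpy as np
import pytest

from evoscape.core_io import RangeTable
from evoscape.disparity import (assign_bins, bootstrap_disparity,
                                compare_groups, dispersion_test,
                                disparity_through_time, sum_of_ranges,
                                sum_of_variances)


class TestSumOfVariances:
    def test_one_axis(self):
        assert sum_of_variances(np.array([[0.0], [2.0]])) == pytest.approx(2.0)

    def test_axes_add(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2)) * np.array([1.0, np.sqrt(2)])
        sov = sum_of_variances(X)
        assert sov == pytest.approx(X[:, 0].var(ddof=1) + X[:, 1].var(ddof=1))

    def test_centroid_point_never_increases_axis_variance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 3))
        Xc = np.vstack([X, X.mean(axis=0)])
        assert np.all(Xc.var(axis=0, ddof=1) <= X.var(axis=0, ddof=1) + 1e-12)

    def test_needs_two_taxa(self):
        with pytest.raises(ValueError, match="2 taxa"):
            sum_of_variances(np.array([[1.0, 2.0]]))


class TestBootstrap:
    def test_zero_variance_degenerate(self):
        rep = bootstrap_disparity(np.ones((6, 2)), B=50, seed=0)
        assert rep.observed_sov == 0.0
        assert rep.boot_median == 0.0 and rep.q025 == rep.q975 == 0.0

    def test_seeded_reproducibility(self):
        X = np.random.default_rng(2).normal(size=(12, 3))
        r1 = bootstrap_disparity(X, B=100, seed=42)
        r2 = bootstrap_disparity(X, B=100, seed=42)
        assert np.array_equal(r1.boot_values, r2.boot_values)

    def test_intervals_nested_and_cover_observed(self):
        rng = np.random.default_rng(3)
        covered = 0
        for rep in range(40):
            X = rng.normal(size=(200, 2))
            r = bootstrap_disparity(X, B=200, seed=rng)
            assert r.q025 <= r.q25 <= r.boot_median <= r.q75 <= r.q975
            covered += r.q025 <= r.observed_sov <= r.q975
        assert covered >= 36  # ~95% coverage at n=200


class TestCompareGroups:
    def test_exact_extreme_case(self):
        p = compare_groups([0, 0, 0], [5, 5, 5])
        assert p == pytest.approx(0.1)  # 2 of 20 arrangements as extreme

    def test_identical_samples_p_one(self):
        assert compare_groups([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 100)
        b = rng.normal(3, 1, 100)
        assert compare_groups(a, b) < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compare_groups([], [1.0])


class TestBins:
    def test_midpoint_rule(self):
        r = RangeTable(taxa=["x"], fad=[170], lad=[160])
        bins = {"older": (174.0, 163.5), "younger": (163.5, 145.0)}
        out = assign_bins(r, bins, rule="midpoint")
        assert out == {"older": ["x"], "younger": []}  # midpoint 165

    def test_any_overlap_can_duplicate(self):
        r = RangeTable(taxa=["x"], fad=[170], lad=[160])
        bins = {"older": (174.0, 163.5), "younger": (163.5, 145.0)}
        out = assign_bins(r, bins, rule="any-overlap")
        assert out["older"] == ["x"] and out["younger"] == ["x"]

    def test_unassigned_taxa_warn(self):
        r = RangeTable(taxa=["x"], fad=[20], lad=[10])
        with pytest.warns(UserWarning, match="no bin"):
            assign_bins(r, {"b": (200.0, 100.0)})


class TestDisparityThroughTime:
    def test_single_bin_equals_plain_bootstrap(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 2))
        taxa = [f"t{i}" for i in range(10)]
        ranges = RangeTable(taxa=taxa, fad=np.full(10, 150.0),
                            lad=np.full(10, 140.0))
        reps = disparity_through_time(X, taxa, ranges,
                                      {"only": (200.0, 100.0)}, B=50, seed=7)
        assert reps["only"].observed_sov == pytest.approx(sum_of_variances(X))

    def test_thin_bin_flagged(self):
        X = np.random.default_rng(6).normal(size=(5, 2))
        taxa = [f"t{i}" for i in range(5)]
        ranges = RangeTable(taxa=taxa, fad=[150, 150, 150, 150, 90],
                            lad=[140, 140, 140, 140, 80])
        reps = disparity_through_time(
            X, taxa, ranges, {"full": (200.0, 100.0), "thin": (100.0, 50.0)},
            B=20, seed=0)
        assert reps["thin"] is None
        assert reps["full"].n_taxa == 4


class TestDispersion:
    def test_full_set_degenerate(self):
        X = np.random.default_rng(7).normal(size=(8, 2))
        res = dispersion_test(X, np.arange(8), nrand=10, seed=0)
        assert res["p_sov"] == 1.0 and "note" in res

    def test_tight_cluster_underdispersed(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.05, size=(6, 2)),
                       rng.normal(0, 3.0, size=(24, 2))])
        res = dispersion_test(X, np.arange(6), nrand=499, seed=1)
        assert res["q_sov"] < 0.05 and res["p_sov"] < 0.05

    def test_reports_sum_of_ranges_too(self):
        X = np.random.default_rng(9).normal(size=(12, 2))
        res = dispersion_test(X, np.arange(4), nrand=99, seed=2)
        assert res["sor"] == pytest.approx(sum_of_ranges(X[:4]))
        assert 0 < res["p_sor"] <= 1

    def test_sov_identity_on_pcoa_scores(self):
        """SoV over all positive PCoA axes = (n/(n-1)) mean squared distance
        to centroid."""
        from evoscape.ordination import pcoa_cailliez
        from evoscape.traitprep import DistanceMatrix

        rng = np.random.default_rng(10)
        pts = rng.normal(size=(9, 4))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ordn = pcoa_cailliez(DistanceMatrix(taxa=[f"t{i}" for i in range(9)],
                                            D=D))
        sov = sum_of_variances(ordn.coords)
        centred = ordn.coords - ordn.coords.mean(axis=0)
        msd = (centred ** 2).sum(axis=1).mean()
        assert sov == pytest.approx(9 / 8 * msd, rel=1e-9)
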