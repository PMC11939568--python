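"""k-NN weights, global/local Moran's I, permutation inference, LISA typing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from emospat.spatial import (
    RegionSet,
    SpatialWeights,
    compute_heat,
    global_moran,
    global_moran_test,
    haversine_matrix,
    knn_weights,
    lisa_summary,
    local_moran,
    local_moran_test,
    valence_dominance,
)
from emospat.staging import StagePartition
from emospat._errors import DegenerateInputError, UnknownRegionError
from conftest import (
    brute_force_global_moran,
    brute_force_local_moran,
    random_weights,
)


class TestRegionSet:
    def test_invariants(self):
        with pytest.raises(ValueError, match="unique"):
            RegionSet(("A", "A"), [0, 1], [0, 1])
        with pytest.raises(ValueError, match="at least 2"):
            RegionSet(("A",), [0], [0])
        with pytest.raises(ValueError, match="WGS84"):
            RegionSet(("A", "B"), [0, 200], [0, 0])

    def test_unknown_codes_listed(self):
        rs = RegionSet(("A", "B"), [0, 1], [0, 1])
        with pytest.raises(UnknownRegionError, match="C"):
            rs.index_of(["A", "C"])


class TestKnnWeights:
    def test_line_of_four_k1(self):
        rs = RegionSet(("A", "B", "C", "D"), lon=[0.0, 1.0, 2.0, 3.0], lat=[0.0] * 4)
        W = knn_weights(rs, 1).matrix
        assert W[0, 1] == 1        # endpoint links inward
        assert W[3, 2] == 1
        assert W[1, 0] == 1 or W[1, 2] == 1
        assert (W.sum(axis=1) == 1).all()

    def test_complete_graph_at_k_nminus1(self):
        rng = np.random.default_rng(0)
        rs = RegionSet(tuple("ABCDE"), rng.uniform(0, 10, 5), rng.uniform(0, 10, 5))
        W = knn_weights(rs, 4).matrix
        assert (W == 1 - np.eye(5)).all()

    def test_duplicate_centroids_tie_break_deterministic(self):
        rs = RegionSet(("A", "B", "C", "D"), lon=[0.0, 0.0, 5.0, 9.0],
                       lat=[0.0, 0.0, 0.0, 0.0])
        W1 = knn_weights(rs, 2)
        W2 = knn_weights(rs, 2)
        assert (W1.matrix == W2.matrix).all()
        assert (W1.matrix.sum(axis=1) == 2).all()
        # C is equidistant from nothing, but A/B are coincident: earlier code wins
        assert W1.matrix[2, 0] == 1 and W1.matrix[2, 1] == 0

    def test_k_out_of_range(self):
        rs = RegionSet(("A", "B"), [0, 1], [0, 1])
        with pytest.raises(ValueError):
            knn_weights(rs, 2)

    def test_haversine_known_distance(self):
        # one degree of longitude at the equator ≈ 111.19 km
        D = haversine_matrix(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        assert D[0, 1] == pytest.approx(111.19, abs=0.5)


def paired_weights():
    """Two isolated pairs: 0↔1, 2↔3 (k=1)."""
    M = np.zeros((4, 4))
    M[0, 1] = M[1, 0] = M[2, 3] = M[3, 2] = 1
    return SpatialWeights(M, 1, ("A", "B", "C", "D"))


class TestMoranExtremes:
    def test_paired_same_gives_plus_one(self):
        W = paired_weights()
        x = np.array([1.0, 1.0, -1.0, -1.0])
        assert global_moran(x, W) == pytest.approx(1.0, abs=1e-15)
        assert local_moran(x, W) == pytest.approx(np.ones(4), abs=1e-15)

    def test_paired_opposite_gives_minus_one(self):
        W = paired_weights()
        x = np.array([1.0, -1.0, 1.0, -1.0])
        assert global_moran(x, W) == pytest.approx(-1.0, abs=1e-15)

    def test_from_geometry(self, paired_regions):
        """The same extremes arise from real k-NN construction on centroids."""
        W = knn_weights(paired_regions, 1)
        assert global_moran(np.array([1.0, 1, -1, -1]), W) == pytest.approx(1.0)
        assert global_moran(np.array([1.0, -1, 1, -1]), W) == pytest.approx(-1.0)


class TestMoranOracle:
    def test_matches_double_loop(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(5, 50))
            k = int(rng.integers(1, min(n - 1, 10)))
            W = random_weights(rng, n, k)
            x = rng.normal(size=n)
            assert global_moran(x, W) == pytest.approx(
                brute_force_global_moran(x, W), abs=1e-12)
            np.testing.assert_allclose(
                local_moran(x, W), brute_force_local_moran(x, W), atol=1e-12)

    def test_local_global_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            k = int(rng.integers(1, min(n - 1, 8)))
            W = random_weights(rng, n, k)
            x = rng.normal(size=n)
            assert local_moran(x, W).sum() == pytest.approx(
                global_moran(x, W) * W.s0, abs=1e-10)

    def test_translation_scale_invariance(self):
        rng = np.random.default_rng(3)
        W = random_weights(rng, 20, 4)
        x = rng.normal(size=20)
        for a, b in [(2.5, 0), (1, -7.0), (-3.0, 4.0)]:
            assert global_moran(a * x + b, W) == pytest.approx(global_moran(x, W))
            np.testing.assert_allclose(local_moran(a * x + b, W),
                                       local_moran(x, W), atol=1e-10)

    def test_zero_deviation_region(self):
        W = paired_weights()
        x = np.array([0.0, 2.0, -2.0, 0.0])  # regions A, D sit at the mean
        I_i = local_moran(x, W)
        assert I_i[0] == 0.0 and I_i[3] == 0.0

    def test_degenerate_input(self):
        W = paired_weights()
        with pytest.raises(DegenerateInputError):
            global_moran(np.ones(4), W)
        with pytest.raises(DegenerateInputError):
            local_moran(np.zeros(4), W)


class TestGlobalMoranTest:
    def test_permutation_expectation_near_null(self):
        rng = np.random.default_rng(19)
        W = random_weights(rng, 31, 9)
        x = rng.normal(size=31)
        res = global_moran_test(x, W, n_perm=4999, seed=1)
        se = np.sqrt(res.VAR_I / res.n_perm)
        assert abs(res.E_I - (-1 / 30)) < 3 * se

    def test_analytic_moments_match_permutation(self):
        rng = np.random.default_rng(23)
        W = random_weights(rng, 31, 9)
        x = rng.normal(size=31)
        ana = global_moran_test(x, W, method="randomization_analytic")
        perm = global_moran_test(x, W, n_perm=9999, seed=2)
        assert ana.E_I == pytest.approx(-1 / 30, abs=1e-15)
        assert perm.VAR_I == pytest.approx(ana.VAR_I, rel=0.1)
        assert abs(ana.Z - perm.Z) < 0.2

    def test_exhaustive_enumeration_n4(self):
        """Pseudo p matches the exact permutation-null tail at n=4."""
        W = paired_weights()
        x = np.array([1.0, 1.0, -1.0, -1.0])
        observed = global_moran(x, W)
        exact = [global_moran(np.array(p), W)
                 for p in itertools.permutations(x)]
        q = np.mean([i >= observed - 1e-12 for i in exact])  # exact tail prob
        assert observed == pytest.approx(max(exact))
        res = global_moran_test(x, W, n_perm=1999, seed=5)
        se = np.sqrt(q * (1 - q) / 1999)
        assert res.p == pytest.approx(q, abs=4 * se + 1e-3)

    def test_alternatives(self):
        rng = np.random.default_rng(29)
        W = random_weights(rng, 15, 3)
        x = rng.normal(size=15)
        pg = global_moran_test(x, W, n_perm=499, seed=0, alternative="greater").p
        pl = global_moran_test(x, W, n_perm=499, seed=0, alternative="less").p
        pt = global_moran_test(x, W, n_perm=499, seed=0, alternative="two-sided").p
        assert 0 < pg <= 1 and 0 < pl <= 1
        assert pt <= 2 * min(pg, pl) + 1e-12

    def test_small_n_perm_warns(self):
        W = paired_weights()
        with pytest.warns(UserWarning, match="n_perm"):
            global_moran_test(np.array([1.0, 2, 3, 4]), W, n_perm=50, seed=0)


class TestLocalMoranTest:
    def test_quadrant_rule_hl_outlier(self):
        """A high value surrounded by low neighbours types HL when significant."""
        rng = np.random.default_rng(31)
        n = 20
        W = random_weights(rng, n, 4)
        x = rng.normal(size=n) * 0.05
        x[0] = 5.0
        x[np.nonzero(W.matrix[0])[0]] = -2.0
        res = local_moran_test(x, W, n_perm=999, seed=3)
        assert res.cluster[0] in ("HL", "NS")
        if res.p_i[0] < 0.05:
            assert res.cluster[0] == "HL"

    def test_alpha_zero_all_ns(self):
        rng = np.random.default_rng(37)
        W = random_weights(rng, 12, 3)
        res = local_moran_test(rng.normal(size=12), W, n_perm=199, seed=0, alpha=0.0)
        assert set(res.cluster) == {"NS"}

    def test_zero_deviation_region_is_ns_flagged(self):
        W = paired_weights()
        x = np.array([0.0, 2.0, -2.0, 0.0])
        res = local_moran_test(x, W, n_perm=199, seed=0)
        assert res.cluster[0] == "NS" and np.isnan(res.Z_i[0])

    def test_fdr_never_adds_significant_regions(self):
        rng = np.random.default_rng(43)
        W = random_weights(rng, 25, 6)
        x = rng.normal(size=25)
        x[:5] += 3.0
        plain = local_moran_test(x, W, n_perm=499, seed=1)
        adjusted = local_moran_test(x, W, n_perm=499, seed=1, fdr=True)
        sig = lambda r: {i for i, c in enumerate(r.cluster) if c != "NS"}
        assert sig(adjusted) <= sig(plain)

    def test_row_standardised_weights_supported(self):
        rng = np.random.default_rng(47)
        Wb = random_weights(rng, 16, 4)
        Ws = Wb.row_standardised()
        assert np.allclose(Ws.matrix.sum(axis=1), 1.0)
        x = rng.normal(size=16)
        # the local-global identity is algebraic, so it holds for any weights
        assert local_moran(x, Ws).sum() == pytest.approx(
            global_moran(x, Ws) * Ws.s0, abs=1e-10)
        res = local_moran_test(x, Ws, n_perm=199, seed=0)
        assert len(res.cluster) == 16

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(41)
        results = {}
        for lab in ("T1", "T2"):
            W = random_weights(rng, 18, 4)
            results[lab] = local_moran_test(rng.normal(size=18), W, n_perm=199,
                                            seed=int(rng.integers(1e6)))
        table = lisa_summary(results)
        assert (table.sum(axis=1) == 18).all()


# --------------------------------------------------------------------------
# heat + dominance

def two_stage_partition():
    return StagePartition.from_breaks("2022-06-09", "2022-06-14",
                                      "2022-06-11", "2022-06-13")


def heat_posts():
    rows = []
    # region A: 6 emotion posts in T1 → heat ln 7; region B: none → 0
    for i in range(6):
        rows.append((f"a{i}", "2022-06-09", "A", "", 3.0, "positive"))
    rows.append(("n0", "2022-06-09", "A", "", 0.0, "neutral"))  # not emotion-bearing
    rows.append(("b0", "2022-06-12", "B", "", -2.0, "negative"))
    return pd.DataFrame(rows, columns=["post_id", "timestamp", "region_code",
                                       "text", "score", "valence"])


class TestComputeHeat:
    def test_log_transform_and_zero_regions(self):
        regions = RegionSet(("A", "B"), [0, 1], [0, 1])
        heat = compute_heat(heat_posts(), two_stage_partition(), regions)
        h = heat.set_index(["region_code", "stage"])["heat"]
        assert h[("A", "T1")] == pytest.approx(np.log(7))
        assert h[("B", "T1")] == 0.0              # ln(1+0)
        assert h[("A", "T2")] == 0.0
        assert h[("B", "T2")] == pytest.approx(np.log(2))
        # whole-window row aggregates both stages
        assert h[("A", "T")] == pytest.approx(np.log(7))

    def test_one_row_per_region_stage(self):
        regions = RegionSet(("A", "B"), [0, 1], [0, 1])
        heat = compute_heat(heat_posts(), two_stage_partition(), regions)
        assert not heat.duplicated(["region_code", "stage"]).any()
        assert set(heat["stage"]) == {"T", "T1", "T2", "T3"}

    def test_unknown_region_rejected(self):
        regions = RegionSet(("A", "X"), [0, 1], [0, 1])
        with pytest.raises(UnknownRegionError, match="B"):
            compute_heat(heat_posts(), two_stage_partition(), regions)


class TestValenceDominance:
    def test_rules(self):
        regions = RegionSet(("A", "B", "C"), [0, 1, 2], [0, 1, 2])
        rows = [("p1", "2022-06-09", "A", "", 1.0, "positive")] * 5
        rows += [("p2", "2022-06-09", "A", "", -1.0, "negative")] * 2
        rows += [("p3", "2022-06-09", "B", "", 1.0, "positive")] * 3
        rows += [("p4", "2022-06-09", "B", "", -1.0, "negative")] * 3
        df = pd.DataFrame(rows, columns=["post_id", "timestamp", "region_code",
                                         "text", "score", "valence"])
        dom = valence_dominance(df, two_stage_partition(), regions)
        d = dom.set_index(["region_code", "stage"])["dominant"]
        assert d[("A", "T1")] == "positive"
        assert d[("B", "T1")] == "tie"
        assert d[("C", "T1")] == "none"
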