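import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from pallidyn import stratify as st


def hypergeom_less_tail(k1, n1, k2, n2):
    """Independent oracle: one-sided Fisher p (fraction1 < fraction2) by direct
    hypergeometric enumeration over the 2x2 tables with fixed margins."""
    K = k1 + k2
    N = n1 + n2
    denom = math.comb(N, n1)
    p = 0.0
    for x in range(0, min(K, n1) + 1):
        if K - x > n2:
            continue
        if x <= k1:
            p += math.comb(K, x) * math.comb(N - K, n1 - x) / denom
    return p


def fractions_frame(counts, n=150):
    genes = [f"G{i}" for i in range(len(counts))]
    df = pd.DataFrame({"k": counts, "n": [n] * len(counts)}, index=genes)
    df["fraction"] = df["k"] / df["n"]
    return df.sort_values("fraction")


class TestFractions:
    def test_basic_fraction(self):
        t = pd.DataFrame({"gene": ["A"] * 40, "flag": [True] * 10 + [False] * 30})
        fr = st.phenomenon_fractions(t, "flag")
        assert fr.loc["A", "fraction"] == 0.25

    def test_counts_sum_and_order_invariance(self, cohort_table):
        fr = st.phenomenon_fractions(cohort_table, "is_bursting")
        assert fr["k"].sum() == int(cohort_table["is_bursting"].sum())
        shuffled = cohort_table.sample(frac=1, random_state=0)
        fr2 = st.phenomenon_fractions(shuffled, "is_bursting")
        pd.testing.assert_frame_equal(fr, fr2)


class TestFisherOneSided:
    @pytest.mark.parametrize("k1,n1,k2,n2", [(10, 100, 40, 100), (5, 80, 30, 60), (0, 50, 10, 50)])
    def test_matches_enumeration_oracle(self, k1, n1, k2, n2):
        assert st.fisher_one_sided(k1, n1, k2, n2) == pytest.approx(
            hypergeom_less_tail(k1, n1, k2, n2), rel=1e-9
        )


class TestGroupPartition:
    def test_identical_fractions_one_group(self):
        part = st.fisher_group_partition(fractions_frame([30, 30, 30, 30]))
        assert len(part.groups) == 1

    def test_two_blocks_recovered(self):
        part = st.fisher_group_partition(fractions_frame([10, 11, 9, 12, 45, 44, 46, 43], n=100))
        assert len(part.groups) == 2
        assert {g for g in part.groups[0]} == {"G0", "G1", "G2", "G3"}

    def test_alpha_one_splits_everything(self):
        part = st.fisher_group_partition(fractions_frame([10, 20, 30, 40], n=100), alpha=1.0)
        assert len(part.groups) == 4

    def test_narrative_three_block_pattern(self):
        # tonicity-like fractions: three well-separated blocks -> three groups
        tonic = fractions_frame([68, 70, 72, 30, 32, 12, 13, 14, 15], n=150)
        assert len(st.fisher_group_partition(tonic).groups) == 3
        # burstiness-like: low+mid merge, top block separates -> two groups
        burst = fractions_frame([8, 12, 15, 22, 24, 60, 62, 64, 66], n=150)
        assert len(st.fisher_group_partition(burst).groups) == 2


class TestBoundaryThreshold:
    def test_matches_bruteforce_scan(self):
        est = st.estimate_boundary_threshold((10, 100), (40, 100))
        for k in range(10, 101):
            if hypergeom_less_tail(k, 100, 40, 100) > 0.05:
                expected = 100.0 * k / 100
                break
        assert est.threshold_pct == pytest.approx(expected)

    def test_bruteforce_grid_agreement(self):
        for (k1, n1, k2, n2) in [(5, 80, 30, 60), (20, 200, 90, 180), (2, 40, 25, 50)]:
            est = st.estimate_boundary_threshold((k1, n1), (k2, n2))
            scan = None
            for k in range(k1, n1 + 1):
                if hypergeom_less_tail(k, n1, k2, n2) > 0.05:
                    scan = 100.0 * k / n1
                    break
            assert est.threshold_pct == pytest.approx(scan)

    def test_equal_fractions_stop_immediately(self):
        est = st.estimate_boundary_threshold((20, 100), (20, 100))
        assert est.threshold_pct == 20.0 and len(est.p_trace) == 1

    def test_trace_monotone_nondecreasing(self):
        for low, high in [((10, 100), (40, 100)), ((5, 60), (50, 90)), ((8, 120, ), (70, 150))]:
            est = st.estimate_boundary_threshold(low[:2], high[:2])
            ps = [p for _, p in est.p_trace]
            assert all(ps[i] <= ps[i + 1] + 1e-12 for i in range(len(ps) - 1))

    def test_monotone_in_high_count(self):
        t1 = st.estimate_boundary_threshold((10, 100), (40, 100)).threshold_pct
        t2 = st.estimate_boundary_threshold((10, 100), (55, 100)).threshold_pct
        assert t2 >= t1


class TestJSDistance:
    def test_hand_computed_value(self):
        # KL to the mixture: JS divergence 0.3113 bits, distance 0.558
        d = st.js_distance_hist(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert d == pytest.approx(0.5579, abs=1e-3)
        assert d**2 == pytest.approx(0.3113, abs=1e-3)

    def test_identical_and_disjoint(self):
        p = np.array([0.2, 0.8])
        assert st.js_distance_hist(p, p) == pytest.approx(0.0, abs=1e-12)
        assert st.js_distance_hist(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_cumulative_matrix_is_metric(self, cohort_table):
        feats = ["firing_regularity", "cv", "firing_rate"]
        D = st.js_cumulative_distance(cohort_table, feats)
        A = D.to_numpy()
        assert np.allclose(A, A.T)
        assert np.allclose(np.diag(A), 0)
        n = len(A)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert A[i, j] <= A[i, k] + A[k, j] + 1e-9

    def test_identical_distributions_give_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=200)
        t = pd.DataFrame({"gene": ["A"] * 200 + ["B"] * 200, "x": np.tile(vals, 2)})
        D = st.js_cumulative_distance(t, ["x"])
        assert D.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)


class TestUPGMA:
    def test_two_leaves(self):
        m = pd.DataFrame([[0, 3.0], [3.0, 0]], index=["A", "B"], columns=["A", "B"])
        d = st.upgma(m)
        assert len(d.merges) == 1 and d.merges[0][2] == pytest.approx(1.5)
        assert d.newick.endswith(";")

    def test_three_leaf_hand_merge(self):
        m = pd.DataFrame([[0, 2, 6], [2, 0, 6], [6, 6, 0]], index=list("ABC"), columns=list("ABC"), dtype=float)
        d = st.upgma(m)
        assert d.merges[0][:2] == (frozenset("A"), frozenset("B"))
        assert d.merges[0][2] == pytest.approx(1.0)
        assert d.merges[1][2] == pytest.approx(3.0)

    def test_matches_scipy_average_linkage_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            X = rng.uniform(1, 10, (5, 5))
            D = (X + X.T) / 2
            np.fill_diagonal(D, 0)
            dm = pd.DataFrame(D, index=list("ABCDE"), columns=list("ABCDE"))
            ours = sorted(h for _, _, h in st.upgma(dm).merges)
            ref = sorted(linkage(squareform(D), method="average")[:, 2] / 2)
            np.testing.assert_allclose(ours, ref)

    def test_heights_nondecreasing_ultrametric(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            X = rng.uniform(0.1, 5, (7, 7))
            D = (X + X.T) / 2
            np.fill_diagonal(D, 0)
            labels = [f"L{i}" for i in range(7)]
            d = st.upgma(pd.DataFrame(D, index=labels, columns=labels))
            hs = [h for _, _, h in d.merges]
            assert all(hs[i] <= hs[i + 1] + 1e-12 for i in range(len(hs) - 1))

    def test_cut_recovers_blocks(self):
        # block-structured distances: cutting at 2 recovers the blocks
        D = np.full((4, 4), 5.0)
        D[:2, :2] = 1.0
        D[2:, 2:] = 1.0
        np.fill_diagonal(D, 0)
        labels = list("ABCD")
        d = st.upgma(pd.DataFrame(D, index=labels, columns=labels))
        groups = {frozenset(g) for g in st.cut_dendrogram(d, 2)}
        assert groups == {frozenset("AB"), frozenset("CD")}
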