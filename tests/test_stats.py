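import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wsdgat.stats import (
    StatsError,
    ancom_w,
    anosim,
    bray_curtis,
    mann_whitney,
    nmds,
    spearman,
    wilcoxon_signed_rank,
    wisconsin,
)
from _oracles import (
    anosim_r_oracle,
    mann_whitney_enum,
    spearman_enum_p,
    wilcoxon_z_oracle,
)


def df(data, **kw):
    return pd.DataFrame(np.asarray(data, dtype=float), **kw)


class TestWisconsin:
    def test_scalar_matrix(self):
        out = wisconsin(df([[5.0]]))
        assert out.iloc[0, 0] == 1.0

    def test_rows_sum_to_one_and_col_max_was_one(self):
        rng = np.random.default_rng(0)
        m = df(rng.uniform(0.1, 9, (4, 7)))
        out = wisconsin(m)
        assert np.allclose(out.sum(axis=1), 1.0)
        colstd = m / m.max(axis=0)
        assert np.allclose(colstd.max(axis=0), 1.0)

    def test_matches_stepwise_oracle(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 5, (3, 4))
        m[0, 0] = 0.0
        out = wisconsin(df(m))
        for i in range(3):
            row = [m[i, j] / m[:, j].max() for j in range(4)]
            tot = sum(row)
            for j in range(4):
                assert out.iloc[i, j] == pytest.approx(row[j] / tot)

    def test_zero_column_names_opu(self):
        m = df([[1.0, 0.0], [2.0, 0.0]], columns=["OPU1", "OPU2"])
        with pytest.raises(StatsError, match="OPU2"):
            wisconsin(m)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(df([[1, 2, 3], [1, 2, 3]]))
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_support_one(self):
        d = bray_curtis(df([[1, 0], [0, 3]]))
        assert d.iloc[0, 1] == 1.0

    def test_formula_example(self):
        d = bray_curtis(df([[1, 2, 3], [3, 2, 1]]))
        assert d.iloc[0, 1] == pytest.approx(1 / 3)

    def test_symmetric_bounded_zero_diagonal(self):
        rng = np.random.default_rng(2)
        d = bray_curtis(df(rng.uniform(0, 4, (6, 9)))).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= 0) & (d <= 1)).all()

    def test_two_zero_rows_rejected(self):
        with pytest.raises(StatsError, match="all-zero"):
            bray_curtis(df([[0, 0], [0, 0], [1, 2]]))


class TestNMDS:
    def planar_points(self, n=6, seed=3):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (n, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return pd.DataFrame(d)

    def test_exact_planar_embedding(self):
        res = nmds(self.planar_points(4), k=2, n_starts=10, seed=0)
        assert res.stress <= 1e-3

    def test_full_dimensional_embedding(self):
        d = self.planar_points(5, seed=8)
        res = nmds(d, k=4, n_starts=10, seed=1)
        assert res.stress <= 1e-3

    def test_stress_non_increasing_within_start(self):
        res = nmds(self.planar_points(7, seed=5), k=2, n_starts=5, seed=2)
        h = res.stress_history
        assert all(b <= a + 1e-12 for a, b in zip(h, h[1:]))

    def test_coordinates_centered(self):
        res = nmds(self.planar_points(6), k=2, n_starts=5, seed=3)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_separated_groups_recovered(self):
        """Two tight 6-sample groups: between-group coordinate separation
        dwarfs the within-group spread and stress is low."""
        rng = np.random.default_rng(4)
        pts = np.vstack(
            [rng.normal(0, 0.3, (6, 2)), rng.normal(8, 0.3, (6, 2)) ]
        )
        d = pd.DataFrame(np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)))
        res = nmds(d, k=2, n_starts=10, seed=5)
        assert res.stress < 0.05
        y = res.coordinates.to_numpy()
        centers = y[:6].mean(0), y[6:].mean(0)
        gap = np.linalg.norm(centers[0] - centers[1])
        spread = max(
            np.linalg.norm(y[:6] - centers[0], axis=1).max(),
            np.linalg.norm(y[6:] - centers[1], axis=1).max(),
        )
        assert gap > 3 * spread

    def test_asymmetric_input_rejected(self):
        m = df([[0, 1, 2], [1, 0, 1], [9, 1, 0]])
        with pytest.raises(StatsError, match="symmetric"):
            nmds(m)


class TestAnosim:
    def two_groups(self, sep, n=4, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack(
            [rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))]
        )
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return pd.DataFrame(d), ["a"] * n + ["b"] * n

    def test_complete_separation_r_one(self):
        d, g = self.two_groups(50.0)
        res = anosim(d, g, seed=1)
        assert res.statistic == pytest.approx(1.0)

    def test_exact_p_equals_enumeration(self):
        """n=6 samples: exact p equals exhaustive enumeration over all
        distinct label assignments, with R recomputed by a naive oracle."""
        d, g = self.two_groups(3.0, n=3, seed=2)
        res = anosim(d, g, method="exact")
        D = d.to_numpy()
        rs = []
        for comb in itertools.combinations(range(6), 3):
            lab = ["a" if i in comb else "b" for i in range(6)]
            rs.append(anosim_r_oracle(D, lab))
        r_obs = anosim_r_oracle(D, g)
        want = sum(1 for r in rs if r >= r_obs - 1e-12) / len(rs)
        assert res.statistic == pytest.approx(r_obs)
        assert res.p_value == pytest.approx(want)
        assert res.exact

    def test_r_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim

        d, g = self.two_groups(2.0, n=5, seed=3)
        dm = skbio.DistanceMatrix(d.to_numpy(), ids=[str(i) for i in range(10)])
        want = sk_anosim(dm, grouping=g, permutations=0)["test statistic"]
        got = anosim(d, g, n_perm=99, seed=0, method="permutation")
        assert got.statistic == pytest.approx(want)

    def test_exchangeable_groups_r_near_zero(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 1, (12, 3))
        d = pd.DataFrame(
            np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        )
        res = anosim(d, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=0)
        assert abs(res.statistic) < 0.35
        assert res.p_value > 0.05

    def test_singleton_group_rejected(self):
        d, _ = self.two_groups(1.0, n=2)
        with pytest.raises(StatsError, match="two members"):
            anosim(d, ["a", "a", "a", "b"])

    def test_permutation_p_reproducible(self):
        d, g = self.two_groups(2.0, n=6, seed=4)
        a = anosim(d, g, n_perm=199, seed=7, method="permutation")
        b = anosim(d, g, n_perm=199, seed=7, method="permutation")
        assert a.p_value == b.p_value
        assert a.p_value >= 1 / 200


class TestMannWhitney:
    def test_complete_separation_3v3_one_sided(self):
        res = mann_whitney([7, 8, 9], [1, 2, 3], alternative="greater")
        assert res.exact
        assert res.p_value == pytest.approx(0.05)

    def test_equal_samples_two_sided_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, list(x))
        assert res.p_value == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 2), (3, 3), (4, 3), (4, 4)])
    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_agrees_with_enumeration(self, n1, n2, alternative):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = list(rng.uniform(0, 1, n1))
            y = list(rng.uniform(0, 1, n2))
            res = mann_whitney(x, y, alternative=alternative)
            want = mann_whitney_enum(x, y, alternative)
            assert res.p_value == pytest.approx(want)

    def test_exact_agrees_with_scipy(self):
        rng = np.random.default_rng(11)
        x, y = rng.uniform(0, 1, 8), rng.uniform(0, 1, 6)
        res = mann_whitney(list(x), list(y))
        want = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.statistic == pytest.approx(want.statistic)
        assert res.p_value == pytest.approx(want.pvalue)

    def test_normal_approx_agrees_with_scipy(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(0, 1, 30), rng.normal(0.8, 1, 25)
        res = mann_whitney(list(x), list(y))
        want = sps.mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic")
        assert res.p_value == pytest.approx(want.pvalue, rel=1e-9)


class TestWilcoxonSignedRank:
    def test_shifted_pairs_strongly_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = x + 1.0
        res = wilcoxon_signed_rank(x, y)
        assert res.z < -3
        assert res.p_value < 0.001

    def test_antisymmetric_differences_null(self):
        x = np.arange(1.0, 11.0)
        y = x + np.array([0.5, -0.5] * 5)
        res = wilcoxon_signed_rank(x, y)
        assert res.p_value > 0.9

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.3, 1, 10)
        res = wilcoxon_signed_rank(x, y)
        z, p = wilcoxon_z_oracle(list(x), list(y))
        assert res.z == pytest.approx(z, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_normal_approx(self):
        rng = np.random.default_rng(22)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.4, 1, 25)
        res = wilcoxon_signed_rank(x, y)
        want = sps.wilcoxon(x, y, correction=False, method="approx")
        assert res.p_value == pytest.approx(want.pvalue, rel=1e-9)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(StatsError, match="zero"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestSpearman:
    def test_monotone_is_one(self):
        res = spearman([1, 2, 3, 5, 9], [2, 4, 9, 12, 30])
        assert res.statistic == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        res = spearman([1, 2, 3, 4], [9, 7, 5, 1])
        assert res.statistic == pytest.approx(-1.0)

    def test_exact_p_equals_enumeration_n7(self):
        rng = np.random.default_rng(31)
        x = list(rng.uniform(0, 1, 7))
        y = list(rng.uniform(0, 1, 7))
        res = spearman(x, y)
        assert res.exact
        assert res.p_value == pytest.approx(spearman_enum_p(x, y))

    def test_rho_agrees_with_scipy(self):
        rng = np.random.default_rng(32)
        x = rng.normal(0, 1, 20)
        y = x + rng.normal(0, 1, 20)
        res = spearman(list(x), list(y))
        want = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(want.statistic)
        assert res.p_value == pytest.approx(want.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(StatsError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestAncomW:
    def table(self, rng, m=15, spike=None):
        base = rng.poisson(30, (12, m)).astype(float)
        if spike is not None:
            base[:6, spike] *= 10
        return pd.DataFrame(base, index=[f"s{i}" for i in range(12)],
                            columns=[f"OPU{j}" for j in range(m)])

    def test_identical_groups_no_detection(self):
        rng = np.random.default_rng(41)
        half = rng.poisson(25, (6, 10)).astype(float)
        tab = pd.DataFrame(np.vstack([half, half]),
                           index=[f"s{i}" for i in range(12)])
        res = ancom_w(tab, ["a"] * 6 + ["b"] * 6)
        assert not res["detected"].any()

    def test_spiked_opu_wins(self):
        rng = np.random.default_rng(42)
        tab = self.table(rng, spike=3)
        res = ancom_w(tab, ["a"] * 6 + ["b"] * 6)
        assert res.loc["OPU3", "W"] == res["W"].max()
        assert res.loc["OPU3", "detected"]

    def test_single_opu_rejected(self):
        tab = pd.DataFrame({"OPU1": np.ones(12)})
        with pytest.raises(StatsError, match="two OPUs"):
            ancom_w(tab, ["a"] * 6 + ["b"] * 6)

    def test_small_group_rejected(self):
        tab = pd.DataFrame(np.ones((4, 5)))
        with pytest.raises(StatsError, match="3 samples"):
            ancom_w(tab, ["a", "a", "b", "b"])
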