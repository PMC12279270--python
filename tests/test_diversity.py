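import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from micromet.diversity import (
    aitchison_distance,
    alpha_diversity,
    chao1,
    dispersion_test,
    faith_pd,
    inverse_simpson,
    ordinate,
    permanova,
    shannon,
)
from micromet.io import FeatureTable
from micromet.preprocess import clr_transform


def _ft(values, kind="asv_counts", features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return FeatureTable(pd.DataFrame(values, index=features, columns=samples), kind)


class TestAlphaDiversity:
    def test_uniform_community(self):
        counts = np.array([10, 10, 10, 10])
        assert shannon(counts) == pytest.approx(math.log(4), abs=1e-12)
        assert inverse_simpson(counts) == pytest.approx(4.0, abs=1e-12)

    def test_chao1_closed_form(self):
        # S_obs 5, F1 2, F2 1 -> 5 + 4/2 = 7
        assert chao1(np.array([5, 3, 1, 1, 2])) == 7.0

    def test_chao1_no_doubletons_fallback(self):
        # F2 = 0 -> S_obs + F1 (F1 - 1) / 2
        assert chao1(np.array([5, 1, 1, 1])) == 4 + 3 * 2 / 2

    def test_chao1_never_below_observed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 6, 30)
            if counts.sum() == 0:
                continue
            assert chao1(counts) >= (counts > 0).sum()

    def test_faith_pd_toy_tree(self):
        tree = TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1):0;"])
        assert faith_pd(["A", "B"], tree) == pytest.approx(3.0)

    def test_faith_pd_monotone_in_taxa(self):
        tree = TreeNode.read(["((A:1,B:2):1,(C:3,D:1):2):0;"])
        sets = [["A"], ["A", "B"], ["A", "B", "C"], ["A", "B", "C", "D"]]
        pds = [faith_pd(s, tree) for s in sets]
        assert all(b >= a for a, b in zip(pds, pds[1:]))

    def test_matches_skbio_alpha_metrics(self):
        from skbio.diversity import alpha as skalpha

        rng = np.random.default_rng(1)
        counts = rng.integers(0, 30, 40)
        assert shannon(counts) == pytest.approx(
            skalpha.shannon(counts, base=math.e)
        )
        assert inverse_simpson(counts) == pytest.approx(skalpha.enspie(counts))
        assert chao1(counts) == pytest.approx(
            skalpha.chao1(counts, bias_corrected=False)
        )

    def test_table_interface_reports_empty_sample_as_missing(self):
        table = _ft([[3, 0], [1, 0]])
        out = alpha_diversity(table)
        assert np.isnan(out.loc["s1", "shannon"])
        assert out.loc["s0", "shannon"] > 0

    def test_shannon_maximal_iff_uniform(self):
        assert shannon(np.array([7, 7, 7])) == pytest.approx(math.log(3))
        assert shannon(np.array([10, 2, 2])) < math.log(3)


class TestAitchison:
    def test_identical_samples_distance_zero(self):
        clr = _ft([[0.5, 0.5], [-0.5, -0.5]], kind="clr_values")
        dm = aitchison_distance(clr)
        assert dm[("s0", "s1")] == 0.0

    def test_3_4_5_triangle(self):
        clr = _ft([[0.0, 3.0], [0.0, 4.0]], kind="clr_values")
        dm = aitchison_distance(clr)
        assert dm[("s0", "s1")] == pytest.approx(5.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        table = _ft(rng.uniform(1, 50, (10, 6)))
        clr = clr_transform(table, 0.5)
        dm = aitchison_distance(clr)
        x = clr.data.to_numpy()
        for i, j in itertools.combinations(range(6), 2):
            expected = math.sqrt(((x[:, i] - x[:, j]) ** 2).sum())
            assert dm[(f"s{i}", f"s{j}")] == pytest.approx(expected, rel=1e-12)


class TestOrdination:
    def test_pcoa_recovers_euclidean_geometry(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(7, 4))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(coords)),
                            ids=[f"s{i}" for i in range(7)])
        res = ordinate(dm, "pcoa", k=6)
        emb = res.coordinates.to_numpy()
        recon = squareform(pdist(emb))
        np.testing.assert_allclose(recon, dm.data, rtol=1e-8, atol=1e-8)

    def test_collinear_points_have_one_real_axis(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(pts)), ids=["a", "b", "c"])
        res = ordinate(dm, "pcoa", k=2)
        spacing = np.abs(np.diff(np.sort(res.coordinates["axis_1"].to_numpy())))
        np.testing.assert_allclose(np.sort(spacing), [1.0, 2.0], atol=1e-9)
        assert res.eigenvalue_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_samples_coincide(self):
        dm = DistanceMatrix(
            np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]]),
            ids=["a", "b", "c"],
        )
        res = ordinate(dm, "pcoa")
        a, b = res.coordinates.loc["a"], res.coordinates.loc["b"]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_nmds_runs_and_reports_stress(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(9, 3))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(coords)),
                            ids=[f"s{i}" for i in range(9)])
        res = ordinate(dm, "nmds", k=2, seed=1)
        assert res.stress is not None and res.stress >= 0
        assert res.coordinates.shape == (9, 2)


def _toy_dm():
    """4 samples, within-pair distance 0.2, cross-pair distance 1."""
    d = np.full((4, 4), 1.0)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.2
    d[2, 3] = d[3, 2] = 0.2
    return DistanceMatrix(d, ids=["a1", "a2", "b1", "b2"])


class TestPermanova:
    def test_enumeration_example(self):
        dm = _toy_dm()
        groups = pd.Series(["A", "A", "B", "B"], index=["a1", "a2", "b1", "b2"])
        res = permanova(dm, groups, n_permutations=999, seed=0)
        assert res.method == "exact"
        assert res.statistic == pytest.approx(49.0)
        assert res.p_value == pytest.approx(2 / 6)

    def test_group_relabeling_symmetry(self):
        dm = _toy_dm()
        g1 = pd.Series(["A", "A", "B", "B"], index=dm.ids)
        g2 = pd.Series(["B", "B", "A", "A"], index=dm.ids)
        r1 = permanova(dm, g1, seed=0)
        r2 = permanova(dm, g2, seed=0)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_brute_force_enumeration(self):
        """Exact p equals brute force over all label assignments (n <= 8)."""
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(8)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        labels = ["A"] * 4 + ["B"] * 4
        groups = pd.Series(labels, index=ids)
        res = permanova(dm, groups, n_permutations=999, seed=0)

        # independent brute force over all distinct assignments
        d2 = dm.data**2

        def pseudo_f(codes):
            n = 8
            ss_t = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
            ss_w = 0.0
            for g in (0, 1):
                idx = [i for i in range(n) if codes[i] == g]
                ss_w += sum(
                    d2[i, j] for i in idx for j in idx if i < j
                ) / len(idx)
            return (ss_t - ss_w) / 1 / (ss_w / 6)

        observed = pseudo_f([0, 0, 0, 0, 1, 1, 1, 1])
        count = total = 0
        for combo in itertools.combinations(range(8), 4):
            codes = [0 if i in combo else 1 for i in range(8)]
            total += 1
            if pseudo_f(codes) >= observed - 1e-12:
                count += 1
        assert res.statistic == pytest.approx(observed)
        assert res.p_value == pytest.approx(count / total)

    def test_matches_skbio_statistic(self):
        import skbio.stats.distance as sksd

        rng = np.random.default_rng(6)
        pts = rng.normal(size=(15, 4))
        pts[:7] += 1.0
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(15)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        groups = pd.Series(["A"] * 7 + ["B"] * 8, index=ids)
        ours = permanova(dm, groups, n_permutations=999, seed=0)
        theirs = sksd.permanova(dm, groups.values, permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_small_group_rejected(self):
        dm = _toy_dm()
        groups = pd.Series(["A", "B", "B", "B"], index=dm.ids)
        with pytest.raises(ValueError, match=">= 2 samples"):
            permanova(dm, groups)


class TestDispersion:
    def test_equal_dispersion_is_null(self):
        dm = _toy_dm()  # both pairs have identical internal geometry
        groups = pd.Series(["A", "A", "B", "B"], index=dm.ids)
        res = dispersion_test(dm, groups, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_tight_vs_spread_contrast(self):
        rng = np.random.default_rng(7)
        tight = rng.normal(scale=0.05, size=(10, 3))
        spread = rng.normal(scale=3.0, size=(10, 3))
        pts = np.vstack([tight, spread])
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(20)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        groups = pd.Series(["T"] * 10 + ["S"] * 10, index=ids)
        res = dispersion_test(dm, groups, n_permutations=999, seed=0)
        assert res.statistic > 10
        assert res.p_value < 0.05

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 3))
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(12)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        g1 = pd.Series(["A"] * 6 + ["B"] * 6, index=ids)
        g2 = pd.Series(["B"] * 6 + ["A"] * 6, index=ids)
        assert dispersion_test(dm, g1, seed=0).statistic == pytest.approx(
            dispersion_test(dm, g2, seed=0).statistic
        )
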