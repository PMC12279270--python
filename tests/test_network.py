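import itertools
import math

import numpy as np
import pandas as pd
import pytest

from micromet import AnalysisConfig, to_absolute
from micromet.io import CohortDesign, FeatureTable, TaxonomyTable
from micromet.network import (
    build_networks,
    collapse_to_genus,
    cross_state_sets,
    spearman,
    strong_positive_genus_sets,
    variable_genera,
)


def brute_force_spearman_p(x, y):
    """Exact two-sided permutation p over all n! orderings."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)

    def rho_of(perm):
        ryp = ry[list(perm)]
        cx, cy = rx - rx.mean(), ryp - ryp.mean()
        return (cx @ cy) / math.sqrt((cx**2).sum() * (cy**2).sum())

    observed = abs(rho_of(range(len(x))))
    count = total = 0
    for perm in itertools.permutations(range(len(x))):
        total += 1
        if abs(rho_of(perm)) >= observed - 1e-12:
            count += 1
    return count / total


class TestSpearman:
    def test_identity_and_reversal(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        rho, _ = spearman(x, x)
        assert rho == pytest.approx(1.0)
        rho_rev, _ = spearman(sorted(x), sorted(x, reverse=True))
        assert rho_rev == pytest.approx(-1.0)

    def test_textbook_d_squared_example(self):
        # sum d^2 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_degenerate(self):
        rho, p = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert (rho, p) == (0.0, 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            spearman([1, 2, 3, 4], [1, 2, 3])

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exact_p_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(3):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            _, p = spearman(x, y)
            assert p == pytest.approx(brute_force_spearman_p(x, y), abs=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=25), rng.normal(size=25)
        rho1, p1 = spearman(x, y)
        rho2, p2 = spearman(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_antisymmetric_under_reversal(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(x, -y)
        assert rho1 == pytest.approx(-rho2, abs=1e-12)

    def test_matches_scipy_for_large_n(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        x, y = rng.normal(size=40), rng.normal(size=40)
        rho, p = spearman(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestBuildNetworks:
    def test_planted_edge_lands_in_its_cohort(self, planted_bundle):
        b = planted_bundle
        absolute = to_absolute(b.counts, b.biomass)
        res = build_networks(absolute, b.metabolites, b.design,
                             taxonomy=b.taxonomy)
        hc_pairs = set(
            zip(res.networks["HC"].edges["genus"],
                res.networks["HC"].edges["metabolite_id"])
        )
        assert ("g001", "m001") in hc_pairs
        for cohort in ("CD", "UC"):
            pairs = set(
                zip(res.networks[cohort].edges["genus"],
                    res.networks[cohort].edges["metabolite_id"])
            )
            assert ("g001", "m001") not in pairs

    def test_full_table_covers_every_pair_and_family(self, planted_bundle):
        b = planted_bundle
        absolute = to_absolute(b.counts, b.biomass)
        res = build_networks(absolute, b.metabolites, b.design,
                             taxonomy=b.taxonomy)
        full = res.full_results
        assert len(full) == 3 * 30 * 10
        for cohort, sub in full.groupby("cohort"):
            ok = sub[~sub["degenerate"]]
            # BH was applied within the cohort family
            from test_univariate import brute_force_bh

            np.testing.assert_allclose(
                ok["q"].to_numpy(), brute_force_bh(ok["p"].to_numpy()), atol=1e-12
            )

    def test_extreme_threshold_keeps_only_perfect_monotone(self, planted_bundle):
        b = planted_bundle
        absolute = to_absolute(b.counts, b.biomass)
        cfg = AnalysisConfig(r_threshold=1.0)
        res = build_networks(absolute, b.metabolites, b.design, cfg, b.taxonomy)
        for net in res.networks.values():
            assert (net.edges["rho"].abs() >= 1.0 - 1e-12).all()

    def test_tiny_cohort_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(12)]
        taxa = FeatureTable(
            pd.DataFrame(np.exp(rng.normal(size=(3, 12))),
                         index=["a1", "a2", "a3"], columns=ids),
            "absolute_abundance",
        )
        mets = FeatureTable(
            pd.DataFrame(np.exp(rng.normal(size=(2, 12))),
                         index=["m1", "m2"], columns=ids),
            "metabolite_concentration",
        )
        design = CohortDesign(
            pd.DataFrame({"group": ["HC"] * 3 + ["CD"] * 5 + ["UC"] * 4},
                         index=ids)
        )
        with caplog.at_level("WARNING", logger="micromet"):
            res = build_networks(taxa, mets, design)
        assert "HC" not in res.networks
        assert any("skipped" in r.message for r in caplog.records)


class TestGenusCollapse:
    def _network(self, rows, cohort="HC"):
        from micromet.network import CorrelationNetwork

        edges = pd.DataFrame(
            rows,
            columns=["cohort", "taxon_id", "genus", "metabolite_id", "rho",
                     "p", "q", "n_samples", "degenerate"],
        )
        return CorrelationNetwork(cohort, edges,
                                  sorted(edges["taxon_id"].unique()),
                                  sorted(edges["metabolite_id"].unique()))

    def test_two_strains_one_genus_edge(self):
        net = self._network([
            ["HC", "a1", "g1", "m1", 0.6, 0.001, 0.01, 20, False],
            ["HC", "a2", "g1", "m1", 0.7, 0.001, 0.01, 20, False],
        ])
        collapsed = collapse_to_genus(net)
        assert len(collapsed) == 1
        assert collapsed.loc[0, "n_asvs"] == 2
        assert sorted(collapsed.loc[0, "rho_values"]) == [0.6, 0.7]

    def test_distinct_genera_unchanged(self):
        net = self._network([
            ["HC", "a1", "g1", "m1", 0.6, 0.001, 0.01, 20, False],
            ["HC", "a2", "g2", "m1", 0.7, 0.001, 0.01, 20, False],
        ])
        assert len(collapse_to_genus(net)) == 2

    def test_metabolite_tally_matches_brute_force(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(40):
            rows.append(["HC", f"a{i}", f"g{rng.integers(0, 5)}",
                         f"m{rng.integers(0, 8)}", 0.6, 0.001, 0.01, 20, False])
        net = self._network(rows)
        collapsed = collapse_to_genus(net)
        raw = pd.DataFrame(rows, columns=["cohort", "taxon_id", "genus",
                                          "metabolite_id", "rho", "p", "q",
                                          "n", "deg"])
        expected = raw.groupby("genus")["metabolite_id"].nunique()
        got = collapsed.groupby("genus")["metabolite_id"].nunique()
        pd.testing.assert_series_equal(got, expected, check_names=False)


class TestCrossStateSets:
    def test_hand_enumerated_regions(self):
        sets = {
            "HC": {("a", "m"), ("b", "m"), ("c", "m")},
            "CD": {("b", "m"), ("d", "m")},
            "UC": {("b", "m")},
        }
        venn = cross_state_sets(sets).set_index("region")
        assert venn.loc["HC", "count"] == 2
        assert venn.loc["CD", "count"] == 1
        assert venn.loc["HC&CD&UC", "count"] == 1
        assert venn.loc["UC", "count"] == 0
        assert venn.loc["HC&CD", "count"] == 0

    def test_identical_sets_fill_triple_region(self):
        s = {("g", "m1"), ("g", "m2")}
        venn = cross_state_sets({"HC": s, "CD": s, "UC": s}).set_index("region")
        assert venn.loc["HC&CD&UC", "count"] == 2
        assert venn["count"].sum() == 2

    def test_disjoint_sets_only_singletons(self):
        venn = cross_state_sets(
            {"HC": {("a", "m")}, "CD": {("b", "m")}, "UC": {("c", "m")}}
        ).set_index("region")
        assert venn.loc["HC", "count"] == 1
        assert venn[venn.index.str.contains("&")]["count"].sum() == 0

    def test_region_counts_sum_to_union(self):
        rng = np.random.default_rng(6)
        sets = {
            c: {(f"g{rng.integers(0, 6)}", f"m{rng.integers(0, 6)}")
                for _ in range(15)}
            for c in ("HC", "CD", "UC")
        }
        venn = cross_state_sets(sets)
        assert venn["count"].sum() == len(set().union(*sets.values()))


class TestVariableGenera:
    def test_symmetric_difference_definition(self):
        sets = {"HC": {("g", "m1"), ("g", "m2")}, "CD": {("g", "m2"), ("g", "m3")}}
        out = variable_genera(sets).set_index("genus")
        assert out.loc["g", "variability"] == 2  # m1 and m3

    def test_identical_across_states_is_zero(self):
        s = {("g", "m1"), ("g", "m2")}
        out = variable_genera({"HC": s, "CD": s}).set_index("genus")
        assert out.loc["g", "variability"] == 0

    def test_single_state_counts_everything(self):
        sets = {"HC": {("g", "m1"), ("g", "m2"), ("g", "m3")}, "CD": set()}
        out = variable_genera(sets).set_index("genus")
        assert out.loc["g", "variability"] == 3

    def test_ranking_breaks_ties_lexicographically(self):
        sets = {
            "HC": {("b", "m1"), ("a", "m1")},
            "CD": {("b", "m2"), ("a", "m2")},
        }
        out = variable_genera(sets)
        assert list(out["genus"]) == ["a", "b"]
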