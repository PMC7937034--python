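import numpy as np
import pandas as pd
import pytest
from scipy import stats

import funlink as fl
from funlink.errors import UndefinedAUCError
from funlink.evidence import default_registry, pair_key

GENES = ["gA", "gB", "gC", "gD"]


@pytest.fixture()
def bundle() -> fl.EvidenceBundle:
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(
        [[1, 2, 3, 4], [2, 4, 6, 8], [4, 1, 3, 2], [1, 1, 2, 5]],
        index=GENES, columns=list("wxyz"), dtype=float,
    )
    phylo = pd.DataFrame(
        [[1, 1, 0, 1, 0, 0, 1, 0, 1, 1],
         [1, 0, 0, 1, 0, 1, 1, 0, 1, 0],
         [0, 1, 1, 0, 1, 0, 0, 1, 0, 0],
         [1, 1, 1, 0, 0, 0, 1, 1, 0, 1]],
        index=GENES, columns=[f"s{i}" for i in range(10)],
    )
    return fl.EvidenceBundle(
        expression=expr,
        annotations={"gA": {"t1", "t2"}, "gB": {"t1"}, "gC": {"t3"}, "gD": set()},
        localizations={"gA": {"nucleus", "cytosol"}, "gB": {"nucleus", "cytosol"},
                       "gC": {"membrane"}},
        domains={"gA": {"d1", "d2"}, "gB": {"d3"}, "gC": {"d4"}},
        domain_interactions={("d1", "d3"): 0.9, ("d2", "d3"): 0.4},
        phylo_profiles=phylo,
        interologs={("gA", "gB")},
    )


class TestFeatureValues:
    def test_identical_localization_sets_give_jaccard_one(self, bundle):
        fm = fl.compute_features([("gA", "gB")], bundle)
        assert fm.column("coloc_jaccard")[0] == pytest.approx(1.0)
        assert fm.column("coloc_any_shared")[0] == 1.0

    def test_no_interacting_domains_scores_zero(self, bundle):
        fm = fl.compute_features([("gA", "gC")], bundle)  # d1/d2 vs d4: nothing
        for name in fm.feature_names:
            if name.startswith("domain_"):
                assert fm.column(name)[0] == 0.0

    def test_proportional_expression_gives_pearson_one(self, bundle):
        fm = fl.compute_features([("gA", "gB")], bundle)
        assert fm.column("coexpr_pearson")[0] == pytest.approx(1.0)

    def test_pearson_and_spearman_match_scipy(self, bundle):
        fm = fl.compute_features([("gC", "gD")], bundle)
        x = bundle.expression.loc["gC"].to_numpy()
        y = bundle.expression.loc["gD"].to_numpy()
        assert fm.column("coexpr_pearson")[0] == pytest.approx(stats.pearsonr(x, y)[0])
        assert fm.column("coexpr_spearman")[0] == pytest.approx(stats.spearmanr(x, y)[0])

    def test_domain_count_feature_counts_interacting_pairs(self, bundle):
        fm = fl.compute_features([("gA", "gB")], bundle)
        assert fm.column("domain_count_none")[0] == 2.0  # d1-d3 and d2-d3
        assert fm.column("domain_max_none")[0] == pytest.approx(0.9)
        assert fm.column("domain_sum_none")[0] == pytest.approx(1.3)
        # normalisation by the domain-pair count |Da|*|Db| = 2
        assert fm.column("domain_count_pairs")[0] == pytest.approx(1.0)

    def test_interolog_indicator(self, bundle):
        fm = fl.compute_features([("gA", "gB"), ("gA", "gC")], bundle)
        assert list(fm.column("interolog_indicator")) == [1.0, 0.0]

    def test_phylo_features_match_direct_formulas(self, bundle):
        fm = fl.compute_features([("gA", "gB")], bundle)
        pa = bundle.phylo_profiles.loc["gA"].to_numpy()
        pb = bundle.phylo_profiles.loc["gB"].to_numpy()
        assert fm.column("phylo_pearson")[0] == pytest.approx(stats.pearsonr(pa, pb)[0])
        jac = (pa & pb).sum() / (pa | pb).sum()
        assert fm.column("phylo_jaccard")[0] == pytest.approx(jac)
        # mutual information against sklearn's contingency implementation
        from sklearn.metrics import mutual_info_score

        mi_nats = mutual_info_score(pa, pb)
        assert fm.column("phylo_mutual_info")[0] == pytest.approx(mi_nats / np.log(2))

    def test_shared_annotation_ic_uses_rarest_shared_term(self, bundle):
        fm = fl.compute_features([("gA", "gB")], bundle)
        # t1 is carried by 2 of 3 annotated genes -> IC = -log2(2/3)
        assert fm.column("annot_min_shared_ic")[0] == pytest.approx(-np.log2(2 / 3))
        assert fm.column("annot_shared_count")[0] == 1.0

    def test_missing_gene_defaults_to_zero_not_error(self, bundle):
        fm = fl.compute_features([("gA", "unknown")], bundle)
        assert np.all(np.isfinite(fm.values))
        assert fm.column("coexpr_pearson")[0] == 0.0

    def test_features_are_symmetric_in_the_pair(self, bundle):
        ab = fl.compute_features([("gA", "gB"), ("gB", "gC")], bundle)
        ba = fl.compute_features([("gB", "gA"), ("gC", "gB")], bundle)
        np.testing.assert_allclose(ab.values, ba.values)

    def test_all_values_finite_on_degenerate_evidence(self):
        ev = fl.EvidenceBundle(
            expression=pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["a", "b"],
                                    columns=["c1", "c2"]),
            phylo_profiles=pd.DataFrame([[0, 0], [1, 1]], index=["a", "b"],
                                        columns=["s1", "s2"]),
        )
        fm = fl.compute_features([("a", "b")], ev)
        assert np.all(np.isfinite(fm.values))
        assert fm.column("coexpr_pearson")[0] == 0.0  # constant rows


class TestRegistry:
    def test_default_census(self):
        reg = default_registry()
        assert reg.census() == {
            "interolog": 1,
            "phylo_profile": 3,
            "domain_interaction": 23,
            "colocalization": 4,
            "coexpression": 2,
            "shared_annotation": 3,
        }
        assert reg.total() == sum(reg.census().values()) == 36

    def test_registry_subset_preserves_order(self):
        reg = default_registry()
        sub = reg.subset(["coexpr_pearson", "interolog_indicator"])
        assert sub.names == ["interolog_indicator", "coexpr_pearson"]


class TestRocAuc:
    def test_perfect_separation(self):
        assert fl.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_complete_tie_is_half(self):
        assert fl.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_three_of_four_concordant(self):
        # pairs: (0.9,0.6)+ (0.9,0.1)+ (0.4,0.6)- (0.4,0.1)+ -> 3/4
        assert fl.roc_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == 0.75

    def test_single_class_raises(self):
        with pytest.raises(UndefinedAUCError):
            fl.roc_auc([0.1, 0.2], [1, 1])

    def test_complement_identity(self):
        rng = np.random.default_rng(5)
        s = rng.random(60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        assert fl.roc_auc(s, y) + fl.roc_auc(s, 1 - y) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        assert fl.roc_auc(np.exp(3 * s), y) == pytest.approx(fl.roc_auc(s, y))

    def test_matches_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        s = rng.integers(0, 5, 200).astype(float)  # heavy ties
        y = rng.integers(0, 2, 200)
        assert fl.roc_auc(s, y) == pytest.approx(roc_auc_score(y, s))


class TestSelectFeatures:
    def test_strict_inequality_at_boundary(self):
        assert fl.select_features({"f1": 0.55, "f2": 0.72, "f3": 0.60}) == ["f2"]

    def test_empty_input(self):
        assert fl.select_features({}) == []

    def test_planted_signal_passes_and_shuffled_fails(self, small_bundle):
        rng = np.random.default_rng(13)
        pos = [g.pair for g in small_bundle.gold]
        neg = fl.sample_negatives(small_bundle.truth.genes, pos, 5, seed=13)
        pairs = pos + sorted(neg)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        fm = fl.compute_features(pairs, small_bundle.evidence)
        aucs = fl.feature_aucs(fm, labels)
        assert aucs["coexpr_pearson"] > 0.6  # planted coexpression signal
        shuffled = rng.permutation(labels)
        while shuffled.sum() == 0:
            shuffled = rng.permutation(labels)
        null_aucs = fl.feature_aucs(fm, shuffled)
        assert abs(null_aucs["coexpr_pearson"] - 0.5) < 0.15
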