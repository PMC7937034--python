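import numpy as np
import pytest

import funlink as fl
from funlink.errors import UndefinedDensityError, ValidationError
from funlink.gsla import GslaConfig, cross_pair_count, q1_density, q2_pvalue


def triangle():
    net = fl.Interactome()
    net.add_edge("a", "b")
    net.add_edge("b", "c")
    net.add_edge("a", "c")
    return net


class TestMapIds:
    MAPPING = {"alias1": "HG1", "alias2": "HG1", "P123": "HG2", "HG3": "HG3"}

    def test_canonical_ids_pass_through(self):
        mapped, unmapped = fl.map_ids(["HG1", "HG2"], self.MAPPING)
        assert (mapped, unmapped) == (["HG1", "HG2"], [])

    def test_unknown_token_reported_not_dropped(self):
        mapped, unmapped = fl.map_ids(["HG1", "whatisthis"], self.MAPPING)
        assert mapped == ["HG1"]
        assert unmapped == ["whatisthis"]

    def test_aliases_collapse_to_one_gene(self):
        mapped, _ = fl.map_ids(["alias1", "alias2", "P123"], self.MAPPING)
        assert mapped == ["HG1", "HG2"]

    def test_all_unmapped_is_fatal(self):
        with pytest.raises(ValidationError):
            fl.map_ids(["x", "y"], self.MAPPING)

    def test_mapping_table_round_trip(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text(
            "namespace\talias\tcanonical\n"
            "uniprot\tP123\tHG2\n"
            "symbol\talias1\tHG1\n"
        )
        table = fl.gsla.read_mapping_table(p)
        assert fl.map_ids(["P123", "alias1"], table)[0] == ["HG2", "HG1"]


class TestQ1Density:
    def test_quarter_density(self, path_net):
        d, n = q1_density(path_net, {"g1", "g2"}, {"g3", "g4"})
        assert (d, n) == (0.25, 1)

    def test_overlapping_sets_use_distinct_cross_pairs(self, path_net):
        d, n = q1_density(path_net, {"g1", "g2"}, {"g2", "g3"})
        assert n == 2  # (g1,g2) and (g2,g3)
        assert d == pytest.approx(2 / 3)

    def test_disjoint_no_edges_zero(self, path_net):
        d, n = q1_density(path_net, {"g1"}, {"g4"})
        assert (d, n) == (0.0, 0)

    def test_identical_singletons_undefined(self, path_net):
        with pytest.raises(UndefinedDensityError):
            q1_density(path_net, {"g1"}, {"g1"})

    def test_cross_pair_count_matches_enumeration(self):
        rng = np.random.default_rng(2)
        universe = [f"u{i}" for i in range(12)]
        for _ in range(25):
            A = set(rng.choice(universe, rng.integers(1, 8), replace=False))
            B = set(rng.choice(universe, rng.integers(1, 8), replace=False))
            brute = {tuple(sorted((x, y))) for x in A for y in B if x != y}
            assert cross_pair_count(A, B) == len(brute)


class TestRewiring:
    def test_triangle_is_rigid(self):
        net = triangle()
        rw = fl.rewire_degree_preserving(net, swaps_per_edge=50, seed=1)
        assert rw.edge_pairs() == net.edge_pairs()

    def test_path_degree_sequence_preserved(self, path_net):
        rw = fl.rewire_degree_preserving(path_net, swaps_per_edge=100, seed=2)
        assert sorted(rw.degree(g) for g in rw.genes) == [1, 1, 2, 2]

    def test_er_net_degrees_exact_and_edges_shuffled(self, er_net):
        rw = fl.rewire_degree_preserving(er_net, swaps_per_edge=10, seed=3)
        assert rw.genes == er_net.genes
        for g in er_net.genes:
            assert rw.degree(g) == er_net.degree(g)
        assert rw.edge_pairs() != er_net.edge_pairs()

    def test_seed_reproducibility(self, er_net):
        a = fl.rewire_degree_preserving(er_net, seed=4)
        b = fl.rewire_degree_preserving(er_net, seed=4)
        c = fl.rewire_degree_preserving(er_net, seed=5)
        assert a.edge_pairs() == b.edge_pairs()
        assert a.edge_pairs() != c.edge_pairs()

    def test_isolated_genes_survive(self):
        net = fl.Interactome(genes=["lonely"])
        net.add_edge("a", "b")
        net.add_edge("c", "d")
        rw = fl.rewire_degree_preserving(net, seed=0)
        assert "lonely" in rw.genes
        assert rw.degree("lonely") == 0


class TestQ2:
    def test_zero_observed_density_gives_p_one(self, er_net):
        genes = sorted(er_net.genes)
        # two fresh genes with no edges at all
        er = er_net.copy()
        er.add_gene("zz1")
        er.add_gene("zz2")
        p, _ = q2_pvalue(er, {"zz1"}, {"zz2"}, GslaConfig(n_permutations=99, q2_alpha=0.05, seed=0))
        assert p == 1.0

    def test_p_value_bounds(self, er_net):
        rng = np.random.default_rng(6)
        genes = sorted(er_net.genes)
        cfg = GslaConfig(n_permutations=99, q2_alpha=0.05, seed=6)
        for _ in range(5):
            A = set(rng.choice(genes, 10, replace=False))
            B = set(rng.choice(genes, 10, replace=False))
            p, nulls = q2_pvalue(er_net, A, B, cfg)
            assert 1 / 100 <= p <= 1.0
            assert len(nulls) == 99

    def test_planted_block_attains_minimal_p(self):
        # dense bipartite block inside a sparse background
        rng = np.random.default_rng(7)
        net = fl.Interactome()
        A = [f"a{i}" for i in range(12)]
        B = [f"b{i}" for i in range(12)]
        bg = [f"z{i}" for i in range(40)]
        for x in A:
            for y in B:
                if rng.random() < 0.7:
                    net.add_edge(x, y)
        allg = A + B + bg
        for _ in range(150):
            i, j = rng.integers(0, len(allg), 2)
            if i != j:
                net.add_edge(allg[i], allg[j])
        cfg = GslaConfig(n_permutations=199, q2_alpha=0.05, seed=7)
        p, _ = q2_pvalue(net, set(A), set(B), cfg)
        assert p == 1 / 200

    def test_alpha_below_resolution_warns(self):
        with pytest.warns(UserWarning, match="minimal attainable"):
            GslaConfig(q2_alpha=0.001, n_permutations=99)


@pytest.fixture(scope="module")
def planted_run():
    cfg = fl.FixtureConfig(
        n_genes=120, n_modules=3, module_size_range=(30, 50),
        p_edge_within=0.3, p_edge_between=0.01, n_gold=0, seed=21,
    )
    bundle = fl.generate(cfg)
    mod1 = sorted(bundle.sets["module_01"].members)
    query = fl.GeneSet("query", "half of module 1", frozenset(mod1[: len(mod1) // 2]))
    rest = fl.GeneSet("rest_of_module_01", "other half", frozenset(mod1[len(mod1) // 2:]))
    rng = np.random.default_rng(21)
    genes = sorted(bundle.truth.genes)
    refs = fl.GeneSetCollection([rest])
    for k in range(6):
        refs.add(fl.GeneSet(f"random_{k}", "random genes",
                            frozenset(rng.choice(genes, 30, replace=False))))
    gcfg = GslaConfig(n_permutations=199, q2_alpha=0.05, seed=21)
    with pytest.warns(UserWarning):  # query below 50 genes
        results = fl.gsla_run(bundle.truth, query, refs, gcfg)
    return bundle, query, results


class TestGslaRun:
    def test_planted_module_passes_and_leads_ranking(self, planted_run):
        _, _, results = planted_run
        assert results.results[0].ref_set == "rest_of_module_01"
        top = results.results[0]
        assert top.passes_q1 and top.passes_q2
        assert top.p_value == 1 / 200

    def test_q2_skipped_for_q1_failures(self, planted_run):
        _, _, results = planted_run
        for r in results.results:
            if not r.passes_q1:
                assert not r.q2_tested
                assert r.p_value == 1.0

    def test_connecting_pairs_oriented_query_first(self, planted_run):
        bundle, query, results = planted_run
        top = results.results[0]
        assert len(top.connecting_pairs) == top.n_inter_edges
        for q, t in top.connecting_pairs:
            assert q in query.members
            assert bundle.truth.has_edge(q, t)

    def test_reference_containing_query_itself_is_handled(self, planted_run):
        bundle, query, _ = planted_run
        refs = fl.GeneSetCollection([fl.GeneSet("self", "the query itself",
                                                query.members)])
        with pytest.warns(UserWarning):
            res = fl.gsla_run(bundle.truth, query, refs,
                              GslaConfig(n_permutations=49, seed=1))
        assert len(res) == 1  # overlap density formula, no crash

    def test_empty_reference_collection_rejected(self, planted_run):
        bundle, query, _ = planted_run
        with pytest.raises(ValidationError):
            fl.GeneSetLinkageAnalysis(bundle.truth, query, fl.GeneSetCollection())

    def test_fixed_seed_bit_reproducible(self, planted_run):
        bundle, query, _ = planted_run
        rng = np.random.default_rng(33)
        genes = sorted(bundle.truth.genes)
        refs = fl.GeneSetCollection([
            fl.GeneSet(f"r{k}", "", frozenset(rng.choice(genes, 25, replace=False)))
            for k in range(3)
        ])
        gcfg = GslaConfig(n_permutations=99, q2_alpha=0.05, seed=5)
        with pytest.warns(UserWarning):
            r1 = fl.gsla_run(bundle.truth, query, refs, gcfg)
        with pytest.warns(UserWarning):
            r2 = fl.gsla_run(bundle.truth, query, refs, gcfg)
        assert r1.results == r2.results

    def test_report_has_ten_parameter_lines(self, planted_run, tmp_path):
        _, _, results = planted_run
        out = tmp_path / "report.tsv"
        results.to_tsv(out)
        lines = out.read_text().splitlines()
        assert sum(1 for l in lines if l.startswith("#")) == 10
        assert lines[10].split("\t")[0] == "ref_set"
        assert len(lines) == 11 + len(results)


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        coll = fl.GeneSetCollection([
            fl.GeneSet("s1", "first", frozenset({"a", "b"})),
            fl.GeneSet("s2", "second", frozenset({"c"})),
        ])
        p = tmp_path / "sets.gmt"
        fl.write_gmt(coll, p)
        back = fl.read_gmt(p)
        assert {s.name for s in back} == {"s1", "s2"}
        assert back["s1"].members == coll["s1"].members

    def test_short_line_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("name_only\tdesc\n")
        with pytest.raises(Exception):
            fl.read_gmt(p)
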