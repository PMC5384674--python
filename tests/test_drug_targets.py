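"""Network proximity, module drug census, and candidate nomination."""

import random

import networkx as nx
import pytest

from netmod.drug_targets import (
    DrugTargetMap,
    load_drug_targets,
    load_expression,
    min_distances,
    module_census,
    nominate_targets,
    proximity_null,
)
from netmod.modules import Module, ModulePartition

from conftest import random_scored_graph


def connected_test_graph(seed=0):
    g = random_scored_graph(60, 0.08, seed=seed)
    comps = list(nx.connected_components(g))
    main = max(comps, key=len)
    for comp in comps:
        if comp is not main:
            g.add_edge(min(main), min(comp), score=900)
    return g


class TestMinDistances:
    def test_target_in_seeds_distance_zero(self):
        g = nx.path_graph(["A", "B", "C"])
        r = min_distances(g, {"A"}, {"A", "C"})
        assert r.distances["A"] == 0

    def test_adjacent_target_distance_one(self):
        g = nx.path_graph(["A", "B", "C"])
        r = min_distances(g, {"B"}, {"A"})
        assert r.distances["B"] == 1

    def test_unmapped_targets_dropped(self):
        g = nx.path_graph(["A", "B"])
        r = min_distances(g, {"B", "GHOST"}, {"A"})
        assert r.n_unmapped == 1
        assert set(r.distances) == {"B"}

    def test_unreachable_target_gets_sentinel(self):
        g = nx.Graph([("A", "B"), ("X", "Y")])
        r = min_distances(g, {"X"}, {"A"})
        assert r.distances["X"] == -1
        assert r.observed == []

    def test_no_mapped_targets_raises(self):
        g = nx.path_graph(["A", "B"])
        with pytest.raises(ValueError):
            min_distances(g, {"GHOST"}, {"A"})

    def test_matches_per_source_bfs_oracle(self):
        g = connected_test_graph(seed=12)
        rng = random.Random(12)
        nodes = sorted(g.nodes)
        seeds = set(rng.sample(nodes, 8))
        targets = set(rng.sample(nodes, 15))
        r = min_distances(g, targets, seeds)
        for t, d in r.distances.items():
            # independent oracle: one BFS per target
            lengths = nx.single_source_shortest_path_length(g, t)
            oracle = min((lengths[s] for s in seeds if s in lengths), default=-1)
            assert d == oracle

    def test_adding_edges_never_increases_distances(self):
        g = connected_test_graph(seed=3)
        rng = random.Random(3)
        nodes = sorted(g.nodes)
        seeds, targets = set(nodes[:5]), set(nodes[40:55])
        before = min_distances(g, targets, seeds).distances
        g2 = g.copy()
        for _ in range(30):
            u, v = rng.sample(nodes, 2)
            g2.add_edge(u, v, score=900)
        after = min_distances(g2, targets, seeds).distances
        for t in before:
            if before[t] != -1:
                assert after[t] <= before[t]


class TestProximityNull:
    def test_identical_observed_and_null_gives_t_zero(self):
        # a complete graph puts every non-seed node at distance 1
        g = nx.complete_graph([f"N{i}" for i in range(12)])
        r = proximity_null(g, {"N1", "N2"}, {"N0"}, n_samples=10, seed=0)
        assert r.p_value > 0.5 or r.t_statistic == pytest.approx(0.0, abs=1e-6)

    def test_null_sample_count_respected(self):
        g = connected_test_graph(seed=5)
        nodes = sorted(g.nodes)
        r = proximity_null(g, set(nodes[:10]), set(nodes[50:]), n_samples=17, seed=1)
        assert len(r.null_distances) == 17

    def test_planted_proximal_targets_significant(self):
        """Targets placed within one hop of the seeds stand out from the
        uniform null in >= 19 of 20 seeded runs."""
        successes = 0
        for seed in range(20):
            g = nx.gnp_random_graph(300, 0.012, seed=seed)
            g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
            rng = random.Random(seed)
            nodes = sorted(g.nodes)
            seeds = set(rng.sample(nodes, 15))
            pool = set(seeds)
            for s in seeds:
                pool.update(g.neighbors(s))
            targets = set(rng.sample(sorted(pool), min(30, len(pool))))
            r = proximity_null(g, targets, seeds, n_samples=100, seed=seed)
            successes += (r.p_value < 0.05 and r.t_statistic < 0)
        assert successes >= 19

    def test_degree_matched_mode_runs(self):
        g = connected_test_graph(seed=9)
        nodes = sorted(g.nodes)
        r = proximity_null(g, set(nodes[:8]), set(nodes[30:40]),
                           n_samples=20, seed=2, degree_matched=True)
        assert len(r.null_distances) == 20


class TestModuleCensus:
    def make(self):
        g = nx.Graph()
        # module MA = {A1..A4}; T1,T2 inside (drug D1), T3 inside (drug D2)
        for u, v in (("A1", "A2"), ("A2", "A3"), ("A3", "A4"), ("A1", "OUT1"),
                     ("A2", "NBR"), ("OUT1", "OUT2")):
            g.add_edge(u, v)
        p = ModulePartition(
            modules=(
                Module("MA", frozenset({"A1", "A2", "A3", "A4"})),
                Module("MB", frozenset({"OUT1", "OUT2", "NBR"})),
            ),
            source_graph_nodes=7,
        )
        return g, p

    def test_direct_targets_and_drug_counts(self):
        g, p = self.make()
        dmap = DrugTargetMap(frozenset({("D1", "A1"), ("D1", "A2"), ("D2", "A3")}))
        census = {c.module_id: c for c in module_census(g, p, dmap, {"MA": {"A2"}})}
        assert census["MA"].direct_targets == {"A1", "A2", "A3"}
        assert census["MA"].drugs == {"D1", "D2"}

    def test_neighbor_target_outside_module(self):
        g, p = self.make()
        dmap = DrugTargetMap(frozenset({("D1", "NBR")}))
        census = {c.module_id: c for c in module_census(g, p, dmap, {"MA": {"A2"}})}
        assert census["MA"].neighbor_targets == {"NBR"}
        assert census["MA"].direct_targets == frozenset()

    def test_counts_match_set_algebra_oracle(self):
        g = connected_test_graph(seed=21)
        rng = random.Random(21)
        nodes = sorted(g.nodes)
        half = len(nodes) // 2
        p = ModulePartition(
            modules=(
                Module("M1", frozenset(nodes[:half])),
                Module("M2", frozenset(nodes[half:])),
            ),
            source_graph_nodes=len(nodes),
        )
        targets = {(f"D{i % 4}", t) for i, t in enumerate(rng.sample(nodes, 20))}
        dmap = DrugTargetMap(frozenset(targets))
        seeds_by_module = {
            "M1": set(rng.sample(nodes[:half], 6)),
            "M2": set(rng.sample(nodes[half:], 6)),
        }
        for c in module_census(g, p, dmap, seeds_by_module):
            members = set(p.by_id(c.module_id).members)
            expect_direct = dmap.targets & members
            neighbor_pool = set()
            for s in seeds_by_module[c.module_id]:
                neighbor_pool |= set(g.neighbors(s))
            expect_neighbor = (dmap.targets & neighbor_pool) - members
            assert c.direct_targets == expect_direct
            assert c.neighbor_targets == expect_neighbor
            assert c.direct_targets.isdisjoint(c.neighbor_targets)
            assert c.drugs == {d for d, t in targets if t in expect_direct}


class TestNominateTargets:
    def test_qualifying_gene_nominated(self):
        dmap = DrugTargetMap(frozenset({("AED1", "OLD")}), {"AED1": "AED"})
        out = nominate_targets({"NEW", "OLD"}, {"NEW", "OLD"}, dmap, {"AED1"})
        assert out == ["NEW"]

    def test_expression_filter_drops_unexpressed(self):
        dmap = DrugTargetMap(frozenset())
        expression = {"EXPR": {"hippocampus"}, "SILENT": {"liver"}}
        out = nominate_targets({"EXPR", "SILENT"}, {"EXPR", "SILENT"}, dmap, set(),
                               expression=expression)
        assert out == ["EXPR"]

    def test_planted_module_nominates_exactly_qualifying_six(self):
        """6 qualifying genes nominated; AED-targeted, off-pathway and
        unexpressed genes excluded."""
        qualifying = {f"Q{i}" for i in range(6)}
        members = qualifying | {"AEDHIT", "OFFPATH", "SILENT"}
        pathway = qualifying | {"AEDHIT", "SILENT"}
        dmap = DrugTargetMap(frozenset({("AED1", "AEDHIT")}), {"AED1": "AED"})
        expression = {g: {"cerebral cortex"} for g in qualifying | {"AEDHIT", "OFFPATH"}}
        out = nominate_targets(members, pathway, dmap, {"AED1"}, expression=expression)
        assert out == sorted(qualifying)

    def test_empty_pathway_gives_empty_list(self):
        assert nominate_targets({"A"}, set(), DrugTargetMap(frozenset()), set()) == []

    def test_output_subset_of_members(self):
        rng = random.Random(8)
        members = {f"G{i}" for i in rng.sample(range(50), 20)}
        pathway = {f"G{i}" for i in rng.sample(range(50), 25)}
        out = nominate_targets(members, pathway, DrugTargetMap(frozenset()), set())
        assert set(out) <= members


class TestIO:
    def test_drug_target_table_round_trip(self, tmp_path):
        path = tmp_path / "dt.tsv"
        path.write_text("drug_id\ttarget\tclass\nD1\tT1\tAED\nD1\tT2\tAED\nD2\tT1\tother\n")
        dmap = load_drug_targets(path)
        assert dmap.targets_of("D1") == {"T1", "T2"}
        assert dmap.drugs_of("T1") == {"D1", "D2"}
        assert dmap.drugs_in_class("AED") == {"D1"}

    def test_expression_table(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("gene\ttissue\texpressed\nG1\tcerebral cortex\tyes\n"
                        "G1\tliver\tno\nG2\thippocampus\tno\n")
        expr = load_expression(path)
        assert expr == {"G1": {"cerebral cortex"}}
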