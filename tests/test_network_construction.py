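"""GRN assembly stages: pathway filter, DE retention, hubs, intermediaries, TFs."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from scboolnet.network_construction import (ConstructionConfig, GRNDraft,
                                            InteractomeGraph, assemble_network,
                                            build_grn,
                                            connect_with_intermediaries,
                                            enrich_transcription_factors,
                                            retain_differential, select_hubs,
                                            select_expressed_pathway_genes)


def graph_of(edges) -> InteractomeGraph:
    g = nx.Graph()
    g.add_edges_from(edges)
    return InteractomeGraph(g)


def expr_table(values: dict[str, float], column: str = "REF") -> pd.DataFrame:
    return pd.DataFrame({column: pd.Series(values, dtype=float)})


class TestPathwaySelection:
    def test_retains_genes_present_in_either_table(self):
        tumor = expr_table({"G1": 5.0})
        control = expr_table({"G3": 2.0})
        retained, report = select_expressed_pathway_genes(
            {"P": {"G1", "G2", "G3"}}, tumor, control)
        assert retained["P"] == {"G1", "G3"}
        assert report["P"] == {"total": 3, "retained": 2, "excluded": 1}

    def test_apoptosis_sized_fixture(self):
        # 161-gene list of which 32 covered by expression (emulated split)
        pathway = {f"G{i:03d}" for i in range(161)}
        covered = {f"G{i:03d}" for i in range(32)}
        tumor = expr_table({g: 1.0 for g in covered})
        retained, report = select_expressed_pathway_genes(
            {"APOPTOSIS": pathway}, tumor, tumor)
        assert report["APOPTOSIS"] == {"total": 161, "retained": 32,
                                       "excluded": 129}
        assert retained["APOPTOSIS"] == covered

    def test_disjoint_sets_give_empty_retention(self, caplog):
        tumor = expr_table({"X": 1.0})
        retained, _ = select_expressed_pathway_genes({"P": {"A", "B"}},
                                                     tumor, tumor)
        assert retained["P"] == set()

    def test_empty_expression_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            select_expressed_pathway_genes({"P": {"A"}}, pd.DataFrame(),
                                           pd.DataFrame())


class TestDifferentialRetention:
    def test_keeps_up_and_down_only(self):
        de = pd.DataFrame({"gene": ["A", "B", "C"],
                           "status": ["up", "ns", "down"]}).set_index("gene")
        kept, report = retain_differential({"A", "B", "C"}, de)
        assert set(kept) == {"A", "C"}
        assert report == {"input": 3, "retained": 2, "up": 1, "down": 1}

    def test_nine_up_nine_down_split(self):
        genes = {f"G{i}" for i in range(32)}
        status = (["up"] * 9 + ["down"] * 9 + ["ns"] * 14)
        de = pd.DataFrame({"gene": sorted(genes), "status": status}).set_index("gene")
        kept, report = retain_differential(genes, de)
        assert report["retained"] == 18
        assert report["up"] == 9 and report["down"] == 9

    def test_missing_rows_default_to_ns(self):
        de = pd.DataFrame({"gene": ["A"], "status": ["up"]}).set_index("gene")
        kept, _ = retain_differential({"A", "Z"}, de)
        assert set(kept) == {"A"}

    def test_all_ns_yields_empty_set(self):
        de = pd.DataFrame({"gene": ["A"], "status": ["ns"]}).set_index("gene")
        kept, _ = retain_differential({"A"}, de)
        assert kept == {}


class TestHubSelection:
    def test_boundary_inclusive_at_threshold(self):
        edges = [("HUB", f"P{i}") for i in range(50)]
        assert select_hubs({"HUB"}, graph_of(edges), 50) == {"HUB"}

    def test_one_below_threshold_excluded(self):
        edges = [("HUB", f"P{i}") for i in range(49)]
        assert select_hubs({"HUB"}, graph_of(edges), 50) == set()

    def test_star_graph_keeps_only_center(self):
        edges = [("C", f"L{i}") for i in range(60)]
        genes = {"C"} | {f"L{i}" for i in range(10)}
        assert select_hubs(genes, graph_of(edges), 50) == {"C"}

    def test_degree_counts_distinct_partners_and_self_loop_once(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_edge("A", "B")  # redundant evidence collapses
        g.add_edge("A", "A")  # self-interaction counts one partner
        inter = InteractomeGraph(g)
        assert inter.degree("A") == 2
        assert inter.degree("ABSENT") == 0


class TestIntermediaries:
    CONFIG = ConstructionConfig(low_expression_threshold=1.0,
                                reference_sample="REF")

    def test_direct_edge_needs_no_intermediary(self):
        draft = connect_with_intermediaries(
            {"A", "B"}, graph_of([("A", "B")]),
            expr_table({"A": 5, "B": 5}), self.CONFIG)
        assert set(draft.nodes) == {"A", "B"}
        assert len(draft.edges) == 1

    def test_four_internal_vertices_exceed_bound(self):
        chain = [("A", "X1"), ("X1", "X2"), ("X2", "X3"), ("X3", "X4"),
                 ("X4", "B")]
        expr = expr_table({g: 5.0 for g in "A B X1 X2 X3 X4".split()})
        draft = connect_with_intermediaries({"A", "B"}, graph_of(chain),
                                            expr, self.CONFIG)
        assert set(draft.nodes) == {"A", "B"}
        assert any("unconnected" in line for line in draft.log)

    def test_expression_gate_on_intermediary(self):
        g = graph_of([("A", "X"), ("X", "B")])
        ok = connect_with_intermediaries(
            {"A", "B"}, g, expr_table({"X": 5.0}), self.CONFIG)
        assert ok.nodes.get("X") == "intermediary"
        rejected = connect_with_intermediaries(
            {"A", "B"}, g, expr_table({"X": 0.5}), self.CONFIG)
        assert "X" not in rejected.nodes

    def test_matches_exhaustive_path_enumeration_on_toy_graphs(self):
        """Admitted paths equal brute-force simple-path search, <= 10 nodes."""
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = 8
            names = [f"N{i}" for i in range(n)]
            g = nx.gnp_random_graph(n, 0.3, seed=trial)
            edges = [(names[a], names[b]) for a, b in g.edges]
            if not edges:
                continue
            seeds = {names[0], names[1]}
            expressed = {nm: float(rng.uniform(2, 8)) for nm in names}
            inter = graph_of(edges)
            draft = connect_with_intermediaries(seeds, inter,
                                                expr_table(expressed),
                                                self.CONFIG)
            # oracle: all simple paths with <= 3 internal non-seed vertices
            gx = nx.Graph(edges)
            candidates = []
            if names[0] in gx and names[1] in gx:
                for path in nx.all_simple_paths(gx, names[0], names[1], cutoff=4):
                    internal = tuple(path[1:-1])
                    if all(v not in seeds for v in internal):
                        candidates.append(internal)
            if inter.has_edge(names[0], names[1]):
                expected_internal = ()
            elif candidates:
                best_len = min(len(c) for c in candidates)
                expected_internal = min(c for c in candidates
                                        if len(c) == best_len)
            else:
                expected_internal = None
            got = {v for v, prov in draft.nodes.items() if prov == "intermediary"}
            if expected_internal is None or expected_internal == ():
                assert got == set()
            else:
                assert got == set(expected_internal)


class TestTFEnrichment:
    def tf_df(self, rows):
        return pd.DataFrame(rows, columns=["tf", "target", "mode"])

    def base_draft(self, vertices):
        draft = GRNDraft()
        for v in vertices:
            draft.add_node(v, "seed")
        return draft

    def test_tf_with_network_target_added(self):
        draft = enrich_transcription_factors(
            self.base_draft(["G"]), self.tf_df([("T", "G", "activation")]))
        assert draft.nodes["T"] == "tf_table"
        assert any(e["source"] == "T" and e["target"] == "G"
                   for e in draft.edges)

    def test_tf_without_network_target_ignored(self):
        draft = enrich_transcription_factors(
            self.base_draft(["G"]), self.tf_df([("T", "OTHER", "activation")]))
        assert "T" not in draft.nodes

    def test_added_set_equals_relational_join(self):
        rng = np.random.default_rng(6)
        tfs = [f"T{i}" for i in range(12)]
        targets = [f"G{i}" for i in range(30)]
        rows = [(tfs[rng.integers(12)], targets[rng.integers(30)], "activation")
                for _ in range(60)]
        vertices = set(targets[:10])
        draft = enrich_transcription_factors(self.base_draft(vertices),
                                             self.tf_df(rows))
        expected = {tf for tf, tgt, _ in rows if tgt in vertices}
        got = {v for v, prov in draft.nodes.items() if prov == "tf_table"}
        assert got == expected


class TestAssembly:
    def test_two_node_chain(self):
        draft = GRNDraft()
        draft.add_node("T", "tf_table")
        draft.add_node("G", "seed")
        draft.add_edge("T", "G", "tf_table", directed=True, sign="activation")
        net, _ = assemble_network(draft, {}, ConstructionConfig())
        assert net.rules["G"].source_text == "T"
        assert net.rules["T"].is_identity  # frozen input

    def test_single_activator_inhibitor_rule(self):
        draft = GRNDraft()
        for v in ("G", "A", "B"):
            draft.add_node(v, "seed")
        draft.add_edge("A", "G", "tf_table", directed=True, sign="activation")
        draft.add_edge("B", "G", "tf_table", directed=True, sign="inhibition")
        net, _ = assemble_network(draft, {}, ConstructionConfig())
        rule = net.rules["G"]
        assert rule.evaluate({"A": 1, "B": 0, "G": 0}) == 1
        assert rule.evaluate({"A": 1, "B": 1, "G": 0}) == 0

    def test_unresolvable_sign_lists_pairs(self):
        draft = GRNDraft()
        draft.add_node("A", "seed")
        draft.add_node("B", "seed")
        draft.add_edge("A", "B", "interactome", directed=False)
        with pytest.raises(ValueError, match="A->B"):
            assemble_network(draft, {}, ConstructionConfig())

    def test_default_to_activation_flag(self):
        draft = GRNDraft()
        draft.add_node("A", "seed")
        draft.add_node("B", "seed")
        draft.add_edge("A", "B", "interactome", directed=False)
        net, _ = assemble_network(
            draft, {}, ConstructionConfig(default_unsigned_to_activation=True))
        assert net.rules["B"].source_text == "A"
        assert net.rules["A"].source_text == "B"


class TestFullConstruction:
    def build_inputs(self):
        """Small hand-checkable evidence set: 2 hubs, 1 intermediary, 1 TF."""
        pathways = {"P1": {"H1", "H2", "NSG", "ABSENT"}}
        tumor = expr_table({"H1": 9, "H2": 9, "NSG": 9, "IM": 5.0}, "TUM")
        control = expr_table({"H1": 9, "H2": 9, "NSG": 9}, "CTL")
        de = pd.DataFrame({"gene": ["H1", "H2", "NSG"],
                           "status": ["up", "down", "ns"]}).set_index("gene")
        edges = ([("H1", f"F1_{i}") for i in range(50)]
                 + [("H2", f"F2_{i}") for i in range(50)]
                 + [("H1", "IM"), ("IM", "H2")])
        tf = pd.DataFrame([("TF1", "H1", "activation"),
                           ("TFX", "ELSEWHERE", "activation")],
                          columns=["tf", "target", "mode"])
        signs = {(a, b): "activation" for a, b in
                 [("H1", "IM"), ("IM", "H1"), ("IM", "H2"), ("H2", "IM")]}
        config = ConstructionConfig(low_expression_threshold=1.0,
                                    reference_sample="TUM")
        return pathways, tumor, control, de, graph_of(edges), tf, signs, config

    def test_stage_counts_match_hand_computation(self):
        args = self.build_inputs()
        net, report = build_grn(*args)
        assert report["pathways"]["P1"] == {"total": 4, "retained": 3,
                                            "excluded": 1}
        assert report["differential"]["retained"] == 2
        assert report["n_hubs"] == 2
        assert report["n_intermediaries"] == 1
        assert report["n_tfs"] == 1
        assert set(net.symbols) == {"H1", "H2", "IM", "TF1"}

    def test_construction_is_deterministic(self):
        from scboolnet.boolean_network import write_rules
        net1, _ = build_grn(*self.build_inputs())
        net2, _ = build_grn(*self.build_inputs())
        assert write_rules(net1) == write_rules(net2)

    def test_stages_are_monotone(self):
        """DE retention only removes; intermediaries/TFs only add."""
        pathways, tumor, control, de, inter, tf, signs, config = self.build_inputs()
        retained, _ = select_expressed_pathway_genes(pathways, tumor, control)
        pool = set().union(*retained.values())
        kept, _ = retain_differential(pool, de)
        assert set(kept) <= pool
        hubs = select_hubs(set(kept), inter, config.min_hub_degree)
        assert hubs <= set(kept)
        draft = connect_with_intermediaries(hubs, inter, tumor, config)
        assert hubs <= set(draft.nodes)
        draft2 = enrich_transcription_factors(draft, tf)
        assert set(draft.nodes) <= set(draft2.nodes)

    def test_every_edge_signed_and_nonseed_provenance_tracked(self):
        net, _ = build_grn(*self.build_inputs())
        assert all(e.sign in ("activation", "inhibition") for e in net.edges)
        prov = {e.provenance for e in net.edges}
        assert prov <= {"interactome", "intermediary", "tf_table", "manual"}
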