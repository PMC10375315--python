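import textwrap

import networkx as nx
import numpy as np
import pytest

from pathvnn.ontology import (OntologyError, OntologyGraph, TermAnnotation,
                              build_layout, load_annotations, parse_obo)
from pathvnn.synthetic import generate_ontology, write_ontology_files


def write_obo(tmp_path, body):
    p = tmp_path / "t.obo"
    p.write_text("format-version: 1.2\n" + textwrap.dedent(body))
    return str(p)


def chain_annotation(genes_on: dict[str, set[str]], universe=("g1", "g2", "g3")):
    channels = {ch: {t: set(g) for t, g in genes_on.items()}
                for ch in ("mutation", "amplification", "deletion", "expression")}
    return TermAnnotation(channels=channels,
                          universes={ch: list(universe) for ch in channels})


class TestParseObo:
    def test_three_term_chain(self, tmp_path):
        path = write_obo(tmp_path, """
            [Term]
            id: A
            is_a: B

            [Term]
            id: B
            is_a: C

            [Term]
            id: C
        """)
        g = parse_obo(path)
        assert g.terms == {"A", "B", "C"}
        assert g.edges == {("A", "B"), ("B", "C")}
        assert g.root == "C"

    def test_cycle_raises_naming_an_edge(self, tmp_path):
        path = write_obo(tmp_path, """
            [Term]
            id: A
            is_a: B

            [Term]
            id: B
            is_a: A
        """)
        with pytest.raises(OntologyError, match="cycle"):
            parse_obo(path)

    def test_obsolete_terms_skipped(self, tmp_path):
        path = write_obo(tmp_path, """
            [Term]
            id: A
            is_a: B

            [Term]
            id: B

            [Term]
            id: Z
            is_obsolete: true
            is_a: B
        """)
        g = parse_obo(path)
        assert "Z" not in g.terms

    def test_missing_file_raises(self):
        with pytest.raises(OSError):
            parse_obo("/nonexistent/file.obo")

    def test_generated_tree_term_count(self, tmp_path):
        # complete tree, depth 4, branching 3: 1 + 3 + 9 + 27 terms
        graph, ann, _ = generate_ontology(depth=4, branching=3, n_genes=50,
                                          genes_per_term=4, seed=0)
        paths = write_ontology_files(graph, ann, str(tmp_path))
        g = parse_obo(paths["obo"])
        assert len(g.terms) == 40
        assert g.root == "T:ROOT"


class TestLoadAnnotations:
    def test_gmt_dedup_and_universe_filter(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("T1\td\tg1\tg2\tg2\tg9\n")
        ann = load_annotations({"mutation": str(p)},
                               {"mutation": ["g1", "g2", "g3"]})
        assert ann.genes("mutation", "T1") == {"g1", "g2"}
        assert ann.dropped_genes["mutation"] == 1

    def test_two_column_tsv(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("T1\tg1\nT1\tg2\nT2\tg3\n")
        ann = load_annotations({"expression": str(p)},
                               {"expression": ["g1", "g2", "g3"]})
        assert ann.genes("expression", "T2") == {"g3"}

    def test_channels_independent(self, tmp_path):
        pm = tmp_path / "m.tsv"
        pm.write_text("T1\tg1\n")
        pe = tmp_path / "e.tsv"
        pe.write_text("T1\tg2\n")
        ann = load_annotations(
            {"mutation": str(pm), "expression": str(pe)},
            {"mutation": ["g1", "g2"], "expression": ["g1", "g2"]})
        assert ann.genes("mutation", "T1") == {"g1"}
        assert ann.genes("expression", "T1") == {"g2"}

    def test_unknown_term_policy(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("NOPE\tg1\n")
        graph = OntologyGraph(terms={"R"}, edges=set(), root="R")
        ann = load_annotations({"mutation": str(p)}, {"mutation": ["g1"]},
                               graph=graph)
        assert ann.dropped_terms["mutation"] == 1
        with pytest.raises(KeyError):
            load_annotations({"mutation": str(p)}, {"mutation": ["g1"]},
                             graph=graph, unknown_term="error")


class TestBuildLayout:
    def chain(self):
        return OntologyGraph(terms={"root", "mid", "leaf"},
                             edges={("leaf", "mid"), ("mid", "root")},
                             root="root")

    def test_chain_genes_on_leaf_all_retained(self):
        ann = chain_annotation({"leaf": {"g1"}})
        layout = build_layout(self.chain(), ann, min_genes=1)
        assert set(layout.order) == {"root", "mid", "leaf"}
        assert layout.children["mid"] == ["leaf"]

    def test_chain_genes_on_mid_prunes_leaf(self):
        ann = chain_annotation({"mid": {"g1"}})
        layout = build_layout(self.chain(), ann, min_genes=1)
        assert set(layout.order) == {"root", "mid"}
        assert layout.children["mid"] == []

    def test_reattachment_through_pruned_intermediate(self):
        # leaf has genes, mid does not: mid is kept only as a connector;
        # with mid also geneless and pruned in a 4-chain, leaf re-attaches up
        g = OntologyGraph(terms={"root", "a", "b", "leaf"},
                          edges={("leaf", "b"), ("b", "a"), ("a", "root")},
                          root="root")
        ann = chain_annotation({"leaf": {"g1"}, "root": {"g2"}})
        layout = build_layout(g, ann, min_genes=1)
        # b and a have no genes but have a retained descendant -> retained
        assert set(layout.order) == {"root", "a", "b", "leaf"}

    def test_no_pruning_on_fully_annotated_tree(self):
        graph, ann, _ = generate_ontology(depth=3, branching=2, n_genes=30,
                                          genes_per_term=3, seed=1)
        layout = build_layout(graph, ann, propagate=True)
        assert len(layout.order) == 7
        pos = {t: i for i, t in enumerate(layout.order)}
        for parent, kids in layout.children.items():
            for c in kids:
                assert pos[c] < pos[parent]

    def test_root_pruned_raises(self):
        ann = chain_annotation({})
        with pytest.raises(OntologyError, match="empty model"):
            build_layout(self.chain(), ann)

    def test_idempotence(self):
        graph, ann, _ = generate_ontology(depth=4, branching=2, n_genes=40,
                                          genes_per_term=3, seed=2)
        layout = build_layout(graph, ann)
        layout2 = build_layout(layout.as_graph(), ann)
        assert set(layout2.order) == set(layout.order)

    def test_propagation_unions_descendant_genes(self):
        graph, ann, leaf_genes = generate_ontology(depth=3, branching=2,
                                                   n_genes=30, genes_per_term=3,
                                                   seed=3)
        layout = build_layout(graph, ann, propagate=True)
        root_genes = set(layout.term_genes("mutation", "T:ROOT"))
        assert root_genes == set().union(*leaf_genes.values())

    def test_json_round_trip(self):
        graph, ann, _ = generate_ontology(depth=3, branching=3, n_genes=30,
                                          genes_per_term=3, seed=4)
        layout = build_layout(graph, ann)
        from pathvnn.ontology import OntologyLayout
        restored = OntologyLayout.from_json(layout.to_json())
        assert restored.order == layout.order
        assert restored.children == layout.children
        assert restored.gene_index == layout.gene_index


@pytest.mark.parametrize("seed", range(10))
def test_topological_order_on_random_dags(seed):
    """Children always precede parents, for randomly wired DAG ontologies."""
    rng = np.random.default_rng(seed)
    graph, ann, _ = generate_ontology(
        depth=int(rng.integers(3, 5)), branching=int(rng.integers(2, 4)),
        n_genes=40, genes_per_term=3,
        n_cross_edges=int(rng.integers(0, 5)), seed=seed)
    layout = build_layout(graph, ann, propagate=bool(seed % 2))
    pos = {t: i for i, t in enumerate(layout.order)}
    for parent, kids in layout.children.items():
        for c in kids:
            assert pos[c] < pos[parent]
    # reachability: every retained term reaches the root via retained terms
    g = nx.DiGraph()
    g.add_nodes_from(layout.order)
    for parent, kids in layout.children.items():
        g.add_edges_from((c, parent) for c in kids)
    for t in layout.order:
        assert nx.has_path(g, t, layout.root)
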