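"""KGML parsing, writing, node expansion and layout."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st
from lxml import etree

from funhop import (
    Entry,
    FixtureSpec,
    Graphics,
    PathwayGraph,
    Relation,
    expand_nodes,
    layout_expanded,
    make_pathway,
    node_attribute_table,
    read_kgml,
    to_networkx,
    write_graphml,
    write_kgml,
)
from funhop.kgml import flatten_groups

from _oracles import rect_overlap


class TestReadKgml:
    def test_fixture_counts_match_xml_text(self, fixture_kgml_path):
        graph = read_kgml(fixture_kgml_path)
        text = fixture_kgml_path.read_text()
        assert len(graph.entries) == text.count("<entry ") == 5
        assert len(graph.reactions) == text.count("<reaction ") == 3
        assert len(graph.relations) == text.count("<relation ") == 1
        assert graph.pathway_id == "hsa90001"
        assert graph.title == "fixture pathway"

    def test_gene_ids_split_on_whitespace(self, fixture_kgml_path):
        graph = read_kgml(fixture_kgml_path)
        assert graph.entries["4"].gene_ids == ["hsa:1737", "hsa:1738"]
        assert graph.entries["5"].gene_ids == ["hsa:5091"]
        assert graph.entries["1"].gene_ids == []

    def test_graphics_captured(self, fixture_kgml_path):
        g = read_kgml(fixture_kgml_path).entries["4"].graphics
        assert (g.x, g.y, g.width, g.height) == (175, 200, 46, 17)
        assert g.name == "DLAT..."

    def test_empty_pathway(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text('<?xml version="1.0"?><pathway name="path:hsa0" title="t"/>')
        graph = read_kgml(path)
        assert len(graph.entries) == 0 and len(graph.reactions) == 0

    def test_malformed_xml_names_line(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<pathway>\n<entry id=1></pathway>")
        with pytest.raises(ValueError, match="line"):
            read_kgml(path)

    def test_unknown_entry_type_kept_with_warning(self, tmp_path):
        path = tmp_path / "odd.xml"
        path.write_text(
            '<pathway name="path:x" title="t">'
            '<entry id="1" name="foo" type="weirdtype"/></pathway>'
        )
        with pytest.warns(UserWarning, match="weirdtype"):
            graph = read_kgml(path)
        assert graph.entries["1"].entry_type == "weirdtype"


class TestWriteKgml:
    def test_round_trip_identity(self, fixture_kgml_path, tmp_path):
        graph = read_kgml(fixture_kgml_path)
        out = tmp_path / "out.xml"
        write_kgml(graph, out)
        assert read_kgml(out) == graph

    def test_expanded_children_emitted_per_gene(self, fixture_kgml_path, tmp_path):
        graph = expand_nodes(read_kgml(fixture_kgml_path))
        out = tmp_path / "out.xml"
        write_kgml(graph, out)
        root = etree.parse(str(out)).getroot()
        children = root.findall("entry[@funhop_parent]")
        assert len(children) == 2  # one per gene of the hsa:1737/hsa:1738 node
        assert all(c.find("graphics") is not None for c in children)

    def test_expanded_round_trip(self, fixture_kgml_path, tmp_path):
        graph = layout_expanded(expand_nodes(read_kgml(fixture_kgml_path)))
        out = tmp_path / "out.xml"
        write_kgml(graph, out)
        assert read_kgml(out) == graph

    def test_unknown_attributes_preserved(self, tmp_path):
        path = tmp_path / "extra.xml"
        path.write_text(
            '<pathway name="path:x" title="t">'
            '<entry id="1" name="hsa:1" type="gene" customattr="kept"/></pathway>'
        )
        out = tmp_path / "out.xml"
        write_kgml(read_kgml(path), out)
        assert etree.parse(str(out)).getroot().find("entry").get("customattr") == "kept"

    def test_empty_graph_minimal_document(self, tmp_path):
        out = tmp_path / "min.xml"
        write_kgml(PathwayGraph(pathway_id="hsa0"), out)
        root = etree.parse(str(out)).getroot()
        assert root.tag == "pathway" and len(root) == 0

    def test_dangling_relation_rejected(self, tmp_path):
        graph = PathwayGraph(pathway_id="x")
        graph.entries["1"] = Entry(entry_id="1", entry_type="gene", gene_ids=["hsa:1"])
        graph.relations.append(Relation("1", "99", "ECrel"))
        with pytest.raises(ValueError, match="99"):
            write_kgml(graph, tmp_path / "x.xml")


class TestExpandNodes:
    def test_multi_gene_entry_gets_one_child_per_gene(self):
        graph = PathwayGraph(pathway_id="x")
        graph.entries["7"] = Entry(
            entry_id="7", entry_type="gene",
            gene_ids=["hsa:5160", "hsa:5161", "hsa:5162"],
        )
        out = expand_nodes(graph)
        children = out.entries["7"].expanded_children
        assert [c.gene_ids for c in children] == [["hsa:5160"], ["hsa:5161"], ["hsa:5162"]]
        assert [c.entry_id for c in children] == ["7_1", "7_2", "7_3"]

    def test_single_gene_entry_unchanged(self, fixture_kgml_path):
        out = expand_nodes(read_kgml(fixture_kgml_path))
        assert out.entries["5"].expanded_children == []

    def test_displayable_rows_sum_of_entry_sizes(self):
        graph = PathwayGraph(pathway_id="x")
        for i, size in enumerate((1, 2, 4), start=1):
            graph.entries[str(i)] = Entry(
                entry_id=str(i), entry_type="gene",
                gene_ids=[f"hsa:{i}{j}" for j in range(size)],
            )
        out = expand_nodes(graph)
        assert sum(1 for _ in out.gene_nodes()) == 1 + 2 + 4

    @given(seed=st.integers(0, 10_000))
    def test_gene_multiset_conserved_and_idempotent(self, seed):
        graph, _, _ = make_pathway(FixtureSpec(n_compounds=4, n_gene_entries=5, seed=seed))
        expanded = expand_nodes(graph)
        assert sorted(expanded.all_gene_ids()) == sorted(graph.all_gene_ids())
        for entry in expanded.gene_entries():
            if entry.is_expanded:
                union = [g for c in entry.expanded_children for g in c.gene_ids]
                assert sorted(union) == sorted(entry.gene_ids)
        assert expand_nodes(expanded) == expanded

    @given(seed=st.integers(0, 10_000))
    def test_expansion_leaves_compounds_and_reactions_alone(self, seed):
        graph, _, _ = make_pathway(FixtureSpec(n_compounds=5, n_gene_entries=6, seed=seed))
        expanded = expand_nodes(graph)
        compounds = lambda g: {e.entry_id for e in g.entries.values()
                               if e.entry_type == "compound"}
        assert compounds(expanded) == compounds(graph)
        assert [(r.reaction_id, r.substrates, r.products) for r in expanded.reactions] == \
               [(r.reaction_id, r.substrates, r.products) for r in graph.reactions]

    def test_group_entries_flattened(self):
        graph = PathwayGraph(pathway_id="x")
        graph.entries["1"] = Entry(entry_id="1", entry_type="gene", gene_ids=["hsa:1"])
        graph.entries["2"] = Entry(entry_id="2", entry_type="gene", gene_ids=["hsa:2"])
        graph.entries["3"] = Entry(entry_id="3", entry_type="group", components=["1", "2"])
        graph.entries["4"] = Entry(entry_id="4", entry_type="gene", gene_ids=["hsa:4"])
        graph.relations.append(Relation("3", "4", "PPrel"))
        flat = flatten_groups(graph)
        assert "3" not in flat.entries
        assert {(r.entry1, r.entry2) for r in flat.relations} == {("1", "4"), ("2", "4")}


class TestLayout:
    def test_children_stack_vertically_from_parent(self):
        graph = PathwayGraph(pathway_id="x")
        graph.entries["1"] = Entry(
            entry_id="1", entry_type="gene", gene_ids=["hsa:1", "hsa:2", "hsa:3"],
            graphics=Graphics(x=100.0, y=200.0, width=46.0, height=17.0),
        )
        out = layout_expanded(expand_nodes(graph))
        ys = [c.graphics.y for c in out.entries["1"].expanded_children]
        assert ys == [200.0, 217.0, 234.0]
        assert all(c.graphics.x == 100.0 and c.graphics.width == 46.0
                   for c in out.entries["1"].expanded_children)

    def test_no_pairwise_overlap_between_adjacent_stacks(self):
        graph, _, _ = make_pathway(
            FixtureSpec(n_compounds=5, n_gene_entries=8, genes_per_entry=(2, 4), seed=3)
        )
        out = layout_expanded(expand_nodes(graph))
        boxes = []
        for entry in out.gene_entries():
            for child in entry.expanded_children:
                g = child.graphics
                boxes.append((g.x, g.y, g.width, g.height))
        for a, b in itertools.combinations(boxes, 2):
            assert not rect_overlap(a, b), (a, b)


class TestExports:
    def test_graphml_has_per_gene_nodes(self, fixture_kgml_path, tmp_path):
        graph = layout_expanded(expand_nodes(read_kgml(fixture_kgml_path)))
        out = tmp_path / "g.graphml"
        write_graphml(graph, out)
        import networkx as nx

        g = nx.read_graphml(out)
        # 3 compounds + 1 single gene + 2 expanded children (parent replaced)
        assert g.number_of_nodes() == 6
        assert "4_1" in g and "4_2" in g and "4" not in g

    def test_node_attribute_table_rows(self, fixture_kgml_path):
        graph = expand_nodes(read_kgml(fixture_kgml_path))
        df = node_attribute_table(graph)
        assert list(df["kegg_id"]) == ["hsa:1737", "hsa:1738", "hsa:5091"]

    def test_networkx_view_components(self, fixture_kgml_path):
        import networkx as nx

        g = to_networkx(read_kgml(fixture_kgml_path))
        assert nx.number_connected_components(g) == 1
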