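"""Ontology parsing, annotation filtering, propagation and category building."""

import networkx as nx
import numpy as np
import pytest

from gcea import (
    CategoryTable,
    build_category_table,
    load_mapping,
    parse_gaf,
    parse_obo,
    propagate_annotations,
)
from gcea.ontology import Category, GafParseError, OboParseError

from conftest import gaf_line


class TestParseObo:
    def test_chain_terms_and_isa_edges(self, toy_obo):
        g = parse_obo(toy_obo)
        assert len(g.terms) == 6
        isa = g.isa_subgraph()
        assert isa.number_of_edges() == 4
        assert set(isa.successors("GO:0000004")) == {"GO:0000002", "GO:0000003"}

    def test_obsolete_term_flagged_and_not_propagated(self, toy_obo):
        g = parse_obo(toy_obo)
        assert g.is_obsolete("GO:0000006")
        assert not g.is_obsolete("GO:0000001")
        assert "GO:0000006" not in g.isa_subgraph()

    def test_part_of_not_treated_as_isa(self, tmp_path):
        p = tmp_path / "po.obo"
        p.write_text(
            "format-version: 1.2\nontology: go\n\n"
            "[Term]\nid: GO:1\nname: a\nnamespace: biological_process\n\n"
            "[Term]\nid: GO:2\nname: b\nnamespace: biological_process\n"
            "relationship: part_of GO:1\n"
        )
        g = parse_obo(p)
        assert g.isa_subgraph().number_of_edges() == 0
        assert g.isa_subgraph(include_part_of=True).number_of_edges() == 1

    def test_malformed_stanza_names_line(self, tmp_path):
        p = tmp_path / "bad.obo"
        p.write_text(
            "format-version: 1.2\nontology: go\n\n[Term]\nid: GO:1\nthisislineseven\n"
        )
        with pytest.raises(OboParseError, match="line 6"):
            parse_obo(p)

    def test_cyclic_isa_rejected(self, tmp_path):
        p = tmp_path / "cyc.obo"
        p.write_text(
            "format-version: 1.2\nontology: go\n\n"
            "[Term]\nid: GO:1\nname: a\nis_a: GO:2\n\n"
            "[Term]\nid: GO:2\nname: b\nis_a: GO:1\n"
        )
        with pytest.raises(OboParseError, match="cycle"):
            parse_obo(p)


class TestParseGaf:
    def test_not_and_nd_rows_excluded(self, toy_gaf):
        ann = parse_gaf(toy_gaf)
        assert len(ann) == 3
        assert set(ann.records["gene_id"]) == {"geneA", "geneB", "geneE"}

    def test_header_only_file_is_empty(self, tmp_path):
        p = tmp_path / "empty.gaf"
        p.write_text("!gaf-version: 2.1\n")
        assert len(parse_gaf(p)) == 0

    def test_wrong_column_count_names_row(self, tmp_path):
        p = tmp_path / "bad.gaf"
        p.write_text("!gaf-version: 2.1\n" + gaf_line("g", "GO:1") + "\na\tb\tc\n")
        with pytest.raises(GafParseError, match="row 3"):
            parse_gaf(p)


class TestPropagation:
    def test_chain_transitive_closure(self, toy_obo, tmp_path):
        g = parse_obo(toy_obo)
        p = tmp_path / "one.gaf"
        p.write_text("!g\n" + gaf_line("geneA", "GO:0000004") + "\n")
        prop = propagate_annotations(g, parse_gaf(p))
        # diamond: leaf -> mid1, mid2 -> root; root exactly once
        terms = list(prop.records["term_id"])
        assert sorted(terms) == ["GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"]

    def test_propagation_is_idempotent_and_deduplicated(self, toy_obo, tmp_path):
        g = parse_obo(toy_obo)
        p = tmp_path / "two.gaf"
        p.write_text(
            "!g\n" + gaf_line("geneA", "GO:0000004") + "\n" + gaf_line("geneA", "GO:0000002") + "\n"
        )
        prop = propagate_annotations(g, parse_gaf(p))
        assert not prop.records.duplicated(["gene_id", "term_id"]).any()
        again = propagate_annotations(g, prop)
        assert prop.records[["gene_id", "term_id"]].equals(again.records[["gene_id", "term_id"]])

    def test_random_dags_match_reachability_oracle(self, tmp_path, toy_obo):
        """Propagated gene sets equal brute-force reachability on random DAGs,
        and every category is a subset of each of its ancestors."""
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = 12
            # random DAG: edges only from higher to lower index
            dag = nx.DiGraph()
            dag.add_nodes_from(range(n))
            for child in range(1, n):
                for parent in rng.choice(child, size=min(child, 2), replace=False):
                    dag.add_edge(child, int(parent))
            lines = ["format-version: 1.2", "ontology: go", ""]
            for i in range(n):
                lines += [f"[Term]", f"id: GO:{i:07d}", f"name: t{i}",
                          "namespace: biological_process"]
                lines += [f"is_a: GO:{j:07d}" for j in dag.successors(i)]
                lines.append("")
            obo = tmp_path / f"dag{trial}.obo"
            obo.write_text("\n".join(lines))
            genes = [f"gene{k}" for k in range(8)]
            annotated = {gene: int(rng.integers(n)) for gene in genes}
            gaf = tmp_path / f"dag{trial}.gaf"
            gaf.write_text("!g\n" + "\n".join(
                gaf_line(gene, f"GO:{t:07d}") for gene, t in annotated.items()) + "\n")
            g = parse_obo(obo)
            prop = propagate_annotations(g, parse_gaf(gaf))
            # oracle: BFS reachability per annotated start node
            got = {
                (gene, term)
                for gene, term in prop.records[["gene_id", "term_id"]].itertuples(index=False)
            }
            want = set()
            for gene, start in annotated.items():
                reach = {start} | nx.descendants(dag, start)
                want |= {(gene, f"GO:{t:07d}") for t in reach}
            assert got == want
            # subset property through the category table
            table = build_category_table(prop, genes, graph=g, size_min=1, size_max=100)
            members = {c.category_id: c.genes for c in table}
            for cid, gset in members.items():
                node = int(cid.split(":")[1])
                for anc in nx.descendants(dag, node):
                    anc_id = f"GO:{anc:07d}"
                    if anc_id in members:
                        assert gset <= members[anc_id]

    def test_unknown_term_annotation_dropped(self, toy_obo, tmp_path):
        g = parse_obo(toy_obo)
        p = tmp_path / "unk.gaf"
        p.write_text("!g\n" + gaf_line("geneA", "GO:9999999") + "\n")
        prop = propagate_annotations(g, parse_gaf(p))
        assert len(prop) == 0


class TestCategoryTable:
    def _annotations(self, toy_obo, tmp_path, genes, term="GO:0000002"):
        g = parse_obo(toy_obo)
        p = tmp_path / "many.gaf"
        p.write_text("!g\n" + "\n".join(gaf_line(x, term) for x in genes) + "\n")
        return g, propagate_annotations(g, parse_gaf(p))

    def test_size_filter_applies_after_universe_intersection(self, toy_obo, tmp_path):
        genes = [f"gene{i}" for i in range(25)]
        g, prop = self._annotations(toy_obo, tmp_path, genes)
        # 25 annotated but only 15 measured -> included at s = 15 with [10, 200]
        table = build_category_table(prop, genes[:15], graph=g, size_min=10, size_max=200)
        assert table["GO:0000002"].size == 15
        # only 9 measured -> excluded
        table9 = build_category_table(prop, genes[:9], graph=g, size_min=10, size_max=200)
        assert "GO:0000002" not in table9.category_ids

    def test_no_filtering_with_loose_bounds(self, toy_obo, tmp_path):
        g, prop = self._annotations(toy_obo, tmp_path, ["geneA"])
        table = build_category_table(prop, ["geneA"], graph=g, size_min=1, size_max=10**6)
        assert all(c.size == 1 for c in table)

    def test_namespace_filter(self, toy_obo, tmp_path):
        g = parse_obo(toy_obo)
        p = tmp_path / "mf.gaf"
        p.write_text("!g\n" + gaf_line("geneA", "GO:0000005") + "\n")
        prop = propagate_annotations(g, parse_gaf(p))
        bp = build_category_table(prop, ["geneA"], graph=g, size_min=1, size_max=10)
        assert len(bp) == 0
        mf = build_category_table(prop, ["geneA"], graph=g, namespace="molecular_function",
                                  size_min=1, size_max=10)
        assert mf.category_ids == ["GO:0000005"]

    def test_empty_universe_rejected(self, toy_obo, tmp_path):
        g, prop = self._annotations(toy_obo, tmp_path, ["geneA"])
        with pytest.raises(ValueError, match="universe"):
            build_category_table(prop, [], graph=g)

    def test_mapping_join_and_duplicate_source_error(self, toy_obo, tmp_path):
        g, prop = self._annotations(toy_obo, tmp_path, ["geneA", "geneB"])
        mp = tmp_path / "map.tsv"
        mp.write_text("mgi\tncbi\ngeneA\t101\n")
        mapping = load_mapping(mp)
        table = build_category_table(prop, ["101"], graph=g, size_min=1, size_max=10,
                                     mapping=mapping)
        assert table["GO:0000002"].genes == frozenset({"101"})  # geneB unmapped, dropped
        bad = tmp_path / "dup.tsv"
        bad.write_text("mgi\tncbi\ngeneA\t101\ngeneA\t102\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_mapping(bad)

    def test_serialization_deterministic_and_lossless(self, tmp_path):
        table = CategoryTable([
            Category("GO:2", "beta", frozenset({"g2", "g1"})),
            Category("GO:1", "alpha", frozenset({"g3"})),
        ])
        j1, j2 = tmp_path / "a.json", tmp_path / "b.json"
        table.to_json(j1)
        CategoryTable(list(table)).to_json(j2)
        assert j1.read_bytes() == j2.read_bytes()
        assert [c.genes for c in CategoryTable.from_json(j1)] == [c.genes for c in table]
        gmt = tmp_path / "a.gmt"
        table.to_gmt(gmt)
        back = CategoryTable.from_gmt(gmt)
        assert back.category_ids == table.category_ids
        assert [c.genes for c in back] == [c.genes for c in table]
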