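"""PTM-to-skeleton matching, summary collapse, coloring, overlays, highlights."""

import pytest

from ptmnav.model import PathwaySkeleton, SkeletonNode
from ptmnav.projection import (
    ColorScale,
    KinaseSubstrateRow,
    KinaseSubstrateTable,
    PTMRecord,
    REGULATION_COLORS,
    NO_VALUE_COLOR,
    highlight_kinases,
    make_color,
    overlay_kinase_edges,
    parse_site,
    project_dataset,
)


def skeleton_with_duplicate_mtor():
    nodes = [
        SkeletonNode("n1", "gene_protein", "MTOR", ("P42345",), ("MTOR",), 100.0, 100.0),
        SkeletonNode("n2", "gene_protein", "MTOR", ("P42345",), ("MTOR",), 400.0, 300.0),
        SkeletonNode("n3", "gene_protein", "RPS6KA1", ("Q15418",), ("RPS6KA1",), 250.0, 200.0),
        SkeletonNode("n4", "gene_protein", "SOS1", ("Q07889",), ("SOS1",), 250.0, 60.0),
    ]
    return PathwaySkeleton("toy", "toy", "hsa", "custom", nodes, [])


def record(**kw):
    defaults = dict(experiment="exp1", peptide_key="pep", regulation="up")
    defaults.update(kw)
    return PTMRecord(**defaults)


class TestMatching:
    def test_record_matching_duplicated_protein_projects_twice(self):
        sk = skeleton_with_duplicate_mtor()
        graph = project_dataset([record(gene_names=("MTOR",), residue="S", position=2478)], sk)
        assert len(graph.ptm_nodes) == 2
        assert {p.skeleton_node_id for p in graph.ptm_nodes} == {"n1", "n2"}

    def test_accession_only_and_gene_only_records_both_match(self):
        sk = skeleton_with_duplicate_mtor()
        by_acc = record(uniprot_accessions=("Q15418",))
        by_gene = record(gene_names=("rps6ka1",))  # case-insensitive
        graph = project_dataset([by_acc, by_gene], sk)
        assert {p.skeleton_node_id for p in graph.ptm_nodes} == {"n3"}
        assert len(graph.ptm_nodes) == 2

    def test_isoform_suffix_stripped(self):
        sk = skeleton_with_duplicate_mtor()
        graph = project_dataset([record(uniprot_accessions=("Q07889-2",))], sk)
        assert [p.skeleton_node_id for p in graph.ptm_nodes] == ["n4"]

    def test_unmatched_record_reported(self):
        sk = skeleton_with_duplicate_mtor()
        graph = project_dataset([record(gene_names=("NOTHERE",))], sk)
        assert graph.ptm_nodes == []
        assert len(graph.unmatched) == 1

    def test_collapse_produces_summary_counts(self):
        sk = skeleton_with_duplicate_mtor()
        data = [record(gene_names=("SOS1",), regulation="up") for _ in range(3)]
        data += [record(gene_names=("SOS1",), regulation="down") for _ in range(2)]
        graph = project_dataset(data, sk, collapse=True)
        counts = {(s.skeleton_node_id, s.regulation): s.count for s in graph.summary_nodes}
        assert counts == {("n4", "up"): 3, ("n4", "down"): 2}
        assert sum(s.count for s in graph.summary_nodes) == len(graph.ptm_nodes)


class TestColors:
    def test_regulation_palette(self):
        scale = ColorScale()
        assert make_color(record(regulation="down"), scale) == REGULATION_COLORS["down"]
        assert make_color(record(regulation="up"), scale) == REGULATION_COLORS["up"]
        assert make_color(record(regulation="not"), scale) == REGULATION_COLORS["not"]

    def test_potency_domain_endpoints_get_endpoint_colors(self):
        # pEC50 range seen in a single-inhibitor dose-response projection
        sk = skeleton_with_duplicate_mtor()
        data = [
            record(gene_names=("SOS1",), pec50=6.37),
            record(gene_names=("RPS6KA1",), pec50=7.41),
            record(gene_names=("MTOR",), pec50=7.0),
        ]
        graph = project_dataset(data, sk, ColorScale(mode="potency"))
        assert graph.scale.domain_min == 6.37 and graph.scale.domain_max == 7.41
        colors = {p.record.pec50: p.color for p in graph.ptm_nodes}
        assert colors[6.37] == graph.scale.color_low
        assert colors[7.41] == graph.scale.color_high
        assert colors[7.0] not in (graph.scale.color_low, graph.scale.color_high)

    def test_degenerate_domain_gives_midpoint_color(self):
        scale = ColorScale(mode="fold_change", domain_min=1.0, domain_max=1.0,
                           color_low="#000000", color_high="#ffffff")
        assert make_color(record(fold_change=1.0), scale) == "#808080"

    def test_missing_value_renders_no_value_gray(self):
        scale = ColorScale(mode="fold_change", domain_min=-2.0, domain_max=2.0)
        assert make_color(record(fold_change=None), scale) == NO_VALUE_COLOR


class TestOverlay:
    def test_annotated_pair_present_yields_edge(self):
        sk = skeleton_with_duplicate_mtor()
        data = [record(gene_names=("SOS1",), residue="S", position=1134)]
        graph = project_dataset(data, sk)
        table = KinaseSubstrateTable([KinaseSubstrateRow("RPS6KA1", "SOS1", "S", 1134)])
        overlay_kinase_edges(graph, table)
        assert len(graph.overlay_edges) == 1
        assert graph.overlay_edges[0].kinase_node_id == "n3"

    def test_kinase_absent_from_skeleton_no_edge(self):
        sk = skeleton_with_duplicate_mtor()
        graph = project_dataset([record(gene_names=("SOS1",), residue="S", position=1134)], sk)
        table = KinaseSubstrateTable([KinaseSubstrateRow("NOKIN", "SOS1", "S", 1134)])
        overlay_kinase_edges(graph, table)
        assert graph.overlay_edges == []
        assert graph.unmatched_overlay_rows == 1

    def test_two_kinases_same_site_two_edges(self):
        sk = skeleton_with_duplicate_mtor()
        graph = project_dataset([record(gene_names=("SOS1",), residue="S", position=1134)], sk)
        table = KinaseSubstrateTable(
            [KinaseSubstrateRow("RPS6KA1", "SOS1", "S", 1134),
             KinaseSubstrateRow("MTOR", "SOS1", "S", 1134)]
        )
        overlay_kinase_edges(graph, table)
        # MTOR appears on two skeleton nodes -> 2 edges, plus RPS6KA1 -> 1
        assert len(graph.overlay_edges) == 3


class TestHighlights:
    def test_passing_kinase_marked_with_direction(self):
        sk = skeleton_with_duplicate_mtor()
        graph = project_dataset([], sk)
        highlight_kinases(graph, [("RPS6KA1", -1.2, 0.01, "down")])
        assert graph.highlights == {"n3": "down"}

    def test_score_inside_cut_not_marked(self):
        sk = skeleton_with_duplicate_mtor()
        graph = project_dataset([], sk)
        highlight_kinases(graph, [("RPS6KA1", -0.3, 0.01, "down")])
        assert graph.highlights == {}

    def test_unknown_kinase_reported(self):
        sk = skeleton_with_duplicate_mtor()
        graph = project_dataset([], sk)
        highlight_kinases(graph, [("GHOSTK", -2.0, 0.001, "down")])
        assert graph.unmatched_kinases == ["GHOSTK"]


class TestSiteParsing:
    @pytest.mark.parametrize("text,expected", [("S1134", ("S", 1134)), ("t246", ("T", 246)), ("Y187", ("Y", 187))])
    def test_parse_site(self, text, expected):
        assert parse_site(text) == expected

    @pytest.mark.parametrize("bad", ["1134", "S", "S0", "Sx"])
    def test_parse_site_rejects(self, bad):
        with pytest.raises(ValueError):
            parse_site(bad)
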