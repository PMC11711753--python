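"""Force layout determinism/collision guarantees and SVG rendering."""

import math
import xml.etree.ElementTree as ET

import pytest

from ptmnav import fixtures as fx
from ptmnav.layout_svg import (
    LayoutError,
    LayoutParams,
    RenderOptions,
    hull_points,
    layout_ptm_nodes,
    render_svg,
)
from ptmnav.model import PathwaySkeleton, SkeletonNode
from ptmnav.projection import ColorScale, PTMRecord, project_dataset

from conftest import brute_force_hull


def one_node_skeleton():
    return PathwaySkeleton(
        "p", nodes=[SkeletonNode("n1", "gene_protein", "AKT1", ("P31749",), ("AKT1",), 100.0, 100.0)], edges=[]
    )


def projected(n_ptms, collapse=False):
    sk = one_node_skeleton()
    data = [
        PTMRecord("e", f"pep{i}", "up", gene_names=("AKT1",), residue="S", position=100 + i)
        for i in range(n_ptms)
    ]
    return project_dataset(data, sk, ColorScale(), collapse=collapse)


class TestLayout:
    def test_single_ptm_sits_at_spring_equilibrium(self):
        graph = layout_ptm_nodes(projected(1), LayoutParams(seed=1))
        ptm = graph.ptm_nodes[0]
        dist = math.hypot(ptm.x - 100.0, ptm.y - 100.0)
        assert dist == pytest.approx(LayoutParams().rest_length, abs=1e-3)

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_collision_radius_respected(self, n):
        params = LayoutParams(seed=3)
        graph = layout_ptm_nodes(projected(n), params)
        pts = [(p.x, p.y) for p in graph.ptm_nodes]
        for i in range(n):
            for j in range(i + 1, n):
                d = math.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
                assert d >= params.collision_radius - 1e-6

    def test_same_seed_bit_identical_coordinates(self):
        params = LayoutParams(seed=11)
        a = layout_ptm_nodes(projected(6), params)
        b = layout_ptm_nodes(projected(6), params)
        assert [(p.x, p.y) for p in a.ptm_nodes] == [(p.x, p.y) for p in b.ptm_nodes]

    def test_skeleton_coordinates_untouched(self):
        graph = layout_ptm_nodes(projected(4), LayoutParams(seed=2))
        node = graph.base.node_map()["n1"]
        assert (node.x, node.y) == (100.0, 100.0)

    def test_energy_non_increasing_over_final_iterations(self):
        graph = layout_ptm_nodes(projected(7), LayoutParams(seed=5))
        trace = graph.layout_trace["n1"]
        tail = trace[-10:]
        assert all(a >= b - 1e-12 for a, b in zip(tail, tail[1:]))

    def test_summary_nodes_are_laid_out_too(self):
        graph = layout_ptm_nodes(projected(5, collapse=True), LayoutParams(seed=1))
        assert all(s.x is not None for s in graph.summary_nodes)


class TestHull:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_small_point_sets(self, seed):
        import random

        rng = random.Random(seed)
        pts = [(rng.uniform(0, 100), rng.uniform(0, 100)) for _ in range(rng.randint(3, 8))]
        ours = {tuple(p) for p in hull_points(pts)}
        assert ours == brute_force_hull(pts)


class TestRenderSvg:
    def test_requires_layout_first(self):
        with pytest.raises(LayoutError, match="layout"):
            render_svg(projected(2))

    def test_output_parses_as_xml_with_stable_ids(self):
        graph = layout_ptm_nodes(projected(3), LayoutParams(seed=1))
        svg = render_svg(graph, RenderOptions(show_site_labels=True))
        root = ET.fromstring(svg)
        ids = {el.get("id") for el in root.iter() if el.get("id")}
        assert "node-n1" in ids
        assert {"ptm-ptm0", "ptm-ptm1", "ptm-ptm2"} <= ids
        assert "sitelabel-ptm0" in ids

    def test_empty_dataset_renders_only_skeleton(self):
        graph = layout_ptm_nodes(project_dataset([], one_node_skeleton()), LayoutParams())
        root = ET.fromstring(render_svg(graph))
        assert not [el for el in root.iter() if (el.get("id") or "").startswith("ptm-")]
        assert [el for el in root.iter() if el.get("id") == "node-n1"]

    def test_group_hull_polygon_matches_brute_force(self, kgml_fixture):
        sk = kgml_fixture.skeleton
        graph = layout_ptm_nodes(project_dataset([], sk), LayoutParams())
        root = ET.fromstring(render_svg(graph))
        polys = [el for el in root.iter() if (el.get("id") or "").startswith("hull-")]
        groups = [n for n in sk.nodes if n.node_type == "group"]
        assert len(polys) == len(groups)
        from ptmnav.layout_svg import NODE_W, NODE_H

        node_map = sk.node_map()
        for poly, group in zip(polys, sorted(groups, key=lambda g: g.node_id)):
            corners = []
            for mid in group.members:
                n = node_map[mid]
                for dx in (-NODE_W / 2, NODE_W / 2):
                    for dy in (-NODE_H / 2, NODE_H / 2):
                        corners.append((round(n.x + dx, 2), round(n.y + dy, 2)))
            expected = brute_force_hull(corners)
            got = {
                tuple(float(v) for v in pair.split(","))
                for pair in poly.get("points").split()
            }
            assert got == expected

    def test_edge_styles_distinguish_visual_classes(self, kgml_fixture):
        graph = layout_ptm_nodes(project_dataset([], kgml_fixture.skeleton), LayoutParams())
        svg = render_svg(graph)
        root = ET.fromstring(svg)
        lines = {el.get("id"): el for el in root.iter() if (el.get("id") or "").startswith("edge-")}
        by_class = {}
        for edge in kgml_fixture.skeleton.edges:
            el = lines.get(f"edge-{edge.edge_id}")
            if el is not None:
                by_class.setdefault(edge.visual_class, el)
        styles = {
            cls: (el.get("stroke-dasharray"), el.get("marker-end"))
            for cls, el in by_class.items()
        }
        assert len(set(styles.values())) == len(styles)  # pairwise distinct

    def test_anchor_edges_not_rendered(self):
        graph = layout_ptm_nodes(projected(2), LayoutParams())
        assert len(graph.anchor_edges) == 2
        root = ET.fromstring(render_svg(graph))
        edge_els = [el for el in root.iter() if (el.get("id") or "").startswith("edge-")]
        assert edge_els == []  # skeleton has no edges; anchors stay invisible
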