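"""Deterministic force placement of PTM nodes and static SVG export.

PTM/summary nodes carry no coordinates of their own; they are placed by a
small physics simulation around their reference skeleton node: a spring
pulls each satellite toward its reference at a rest distance, and satellites
of the same reference repel each other so labels stay legible.  The
integrator is plain gradient descent on the total potential with
backtracking line search, which makes the energy monotonically
non-increasing and the whole layout bit-reproducible for a fixed seed (the
seed only sets the initial angular placement).  If residual overlaps remain
after the iteration budget, satellites are projected onto a circle around
the reference that is wide enough to honor the collision radius.

Rendering emits plain SVG 1.1: rectangles/ellipses for skeleton nodes,
convex-hull polygons for groups, the four visual edge classes with distinct
dash patterns and markers, colored PTM satellites with optional
residue+position labels, and kinase-substrate overlay arrows.  The
PTM-to-skeleton anchor edges exist only for the force model and are never
drawn.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .projection import HIGHLIGHT_COLORS, ProjectedGraph

# skeleton node box geometry (px)
NODE_W, NODE_H = 60.0, 24.0
PTM_RX, PTM_RY = 9.0, 6.0

NODE_FILL = {
    "gene_protein": "#c7e9c0",
    "compound": "#fdd0a2",
    "pathway": "#c6dbef",
    "misc": "#eeeeee",
}

#: dash pattern / marker per visual edge class; string-exact and part of the
#: stable rendering contract.
EDGE_STYLE = {
    "activation": {"stroke": "#333333", "dasharray": None, "marker": "arrow"},
    "inhibition": {"stroke": "#333333", "dasharray": None, "marker": "tbar"},
    "binding_association": {"stroke": "#333333", "dasharray": "4,3", "marker": None},
    "indirect": {"stroke": "#333333", "dasharray": "7,4", "marker": "arrow"},
    "other": {"stroke": "#666666", "dasharray": None, "marker": None},
}


@dataclass(frozen=True)
class LayoutParams:
    spring_strength: float = 0.05
    repulsion_strength: float = 400.0
    collision_radius: float = 14.0
    rest_length: float = 28.0
    iterations: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.collision_radius <= 0:
            raise ValueError("collision_radius must be > 0")


class LayoutError(RuntimeError):
    pass


def _group_energy(pos: np.ndarray, center: np.ndarray, p: LayoutParams) -> float:
    d = np.hypot(*(pos - center).T)
    e = 0.5 * p.spring_strength * float(np.sum((d - p.rest_length) ** 2))
    n = len(pos)
    for i in range(n):
        for j in range(i + 1, n):
            r = math.hypot(*(pos[i] - pos[j]))
            e += p.repulsion_strength / max(r, 1e-9)
    return e


def _group_gradient(pos: np.ndarray, center: np.ndarray, p: LayoutParams) -> np.ndarray:
    grad = np.zeros_like(pos)
    rel = pos - center
    d = np.hypot(rel[:, 0], rel[:, 1])
    d_safe = np.maximum(d, 1e-9)
    grad += p.spring_strength * ((d - p.rest_length) / d_safe)[:, None] * rel
    n = len(pos)
    for i in range(n):
        for j in range(i + 1, n):
            diff = pos[i] - pos[j]
            r = max(math.hypot(*diff), 1e-9)
            g = -p.repulsion_strength / r**3 * diff
            grad[i] += g
            grad[j] -= g
    return grad


def layout_ptm_nodes(graph: ProjectedGraph, params: LayoutParams | None = None) -> ProjectedGraph:
    """Assign coordinates to every PTM/summary node; skeleton coordinates
    are never touched.

    Same graph + same params (incl. seed) give bit-identical coordinates.
    After the run, no two satellites of one reference node are closer than
    ``collision_radius`` (tolerance 1e-6); the per-reference energy history
    is stored in ``graph.layout_trace``.
    """
    params = params or LayoutParams()
    node_xy = {
        n.node_id: (n.x, n.y) for n in graph.base.nodes if n.x is not None and n.y is not None
    }
    groups: dict[str, list] = {}
    for display in graph.display_nodes():
        groups.setdefault(display.skeleton_node_id, []).append(display)

    graph.layout_trace = {}
    for ref_id, members in groups.items():
        cx, cy = node_xy.get(ref_id, (0.0, 0.0))
        center = np.array([cx, cy], dtype=float)
        n = len(members)
        # seeded initial angular placement on the rest circle
        theta0 = 2.0 * math.pi * ((params.seed % 997) / 997.0)
        angles = theta0 + 2.0 * math.pi * np.arange(n) / n
        pos = center + params.rest_length * np.stack([np.cos(angles), np.sin(angles)], axis=1)

        energy = _group_energy(pos, center, params)
        trace = [energy]
        step = 1.0
        for _ in range(params.iterations):
            grad = _group_gradient(pos, center, params)
            accepted = False
            for _try in range(12):
                cand = pos - step * grad
                cand_e = _group_energy(cand, center, params)
                if cand_e <= energy:
                    pos, energy, accepted = cand, cand_e, True
                    step *= 1.1
                    break
                step *= 0.5
            trace.append(energy)
            if not accepted:
                # converged: gradient step cannot lower the energy further
                continue
        graph.layout_trace[ref_id] = trace

        pos = _enforce_collision(pos, center, params)
        for member, (x, y) in zip(members, pos):
            member.x, member.y = float(x), float(y)
    return graph


def _enforce_collision(pos: np.ndarray, center: np.ndarray, p: LayoutParams) -> np.ndarray:
    n = len(pos)
    if n < 2:
        return pos
    ok = all(
        math.hypot(*(pos[i] - pos[j])) >= p.collision_radius - 1e-6
        for i in range(n)
        for j in range(i + 1, n)
    )
    if ok:
        return pos
    # project onto a circle wide enough that adjacent chords respect the
    # collision radius, keeping the angular order the force run produced
    radius = max(p.rest_length, p.collision_radius / (2.0 * math.sin(math.pi / n)) + 1e-6)
    rel = pos - center
    order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]), kind="stable")
    out = pos.copy()
    for rank, idx in enumerate(order):
        ang = 2.0 * math.pi * rank / n
        out[idx] = center + radius * np.array([math.cos(ang), math.sin(ang)])
    return out


# ---------------------------------------------------------------------------
# Convex hulls


def hull_points(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices in counter-clockwise order (degenerate inputs
    fall back to the point set itself)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return pts
    try:
        hull = ConvexHull(pts)
    except Exception:
        # collinear input: return the two extremes
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        return pts[[order[0], order[-1]]]
    return pts[hull.vertices]


def _member_corners(graph: ProjectedGraph, member_ids) -> np.ndarray:
    node_map = graph.base.node_map()
    corners = []
    for mid in member_ids:
        node = node_map.get(mid)
        if node is None or node.x is None or node.y is None:
            continue
        for dx in (-NODE_W / 2, NODE_W / 2):
            for dy in (-NODE_H / 2, NODE_H / 2):
                corners.append((node.x + dx, node.y + dy))
    return np.array(corners) if corners else np.empty((0, 2))


# ---------------------------------------------------------------------------
# SVG export


@dataclass(frozen=True)
class RenderOptions:
    show_site_labels: bool = False
    width: int | None = None
    height: int | None = None
    font_family: str = "Helvetica, Arial, sans-serif"


def render_svg(graph: ProjectedGraph, options: RenderOptions | None = None) -> str:
    """Render a laid-out projected graph as an SVG 1.1 document (text).

    Every visible node, edge, hull polygon and label becomes one element
    with a stable id derived from the graph ids.  Anchor edges are omitted.
    Raises LayoutError if PTM/summary nodes lack coordinates (run
    :func:`layout_ptm_nodes` first).
    """
    options = options or RenderOptions()
    for display in graph.display_nodes():
        if display.x is None or display.y is None:
            raise LayoutError(
                "PTM nodes have no coordinates; run layout_ptm_nodes before render_svg"
            )

    placed = [n for n in graph.base.nodes if n.x is not None and n.y is not None]
    xs = [n.x for n in placed] + [d.x for d in graph.display_nodes()]
    ys = [n.y for n in placed] + [d.y for d in graph.display_nodes()]
    pad = 60.0
    min_x, min_y = (min(xs) if xs else 0.0) - pad, (min(ys) if ys else 0.0) - pad
    width = options.width or int((max(xs) if xs else 0.0) + pad - min_x)
    height = options.height or int((max(ys) if ys else 0.0) + pad - min_y)

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": str(width),
            "height": str(height),
            "viewBox": f"{min_x:.2f} {min_y:.2f} {width} {height}",
            "font-family": options.font_family,
        },
    )
    _defs(svg)

    node_map = graph.base.node_map()
    edge_map = graph.base.edge_map()
    endpoint_xy: dict[str, tuple[float, float]] = {
        n.node_id: (n.x, n.y) for n in placed
    }
    # edges may terminate on edges: use the midpoint of the target edge,
    # resolving chains iteratively
    for _ in range(len(graph.base.edges)):
        changed = False
        for edge in graph.base.edges:
            if edge.edge_id in endpoint_xy:
                continue
            src, tgt = endpoint_xy.get(edge.source), endpoint_xy.get(edge.target)
            if src is not None and tgt is not None:
                endpoint_xy[edge.edge_id] = ((src[0] + tgt[0]) / 2, (src[1] + tgt[1]) / 2)
                changed = True
        if not changed:
            break

    hulls = ET.SubElement(svg, "g", {"id": "group-hulls"})
    for node in graph.base.nodes:
        if node.node_type != "group":
            continue
        corners = _member_corners(graph, node.members)
        if len(corners) == 0:
            continue
        hull = hull_points(corners)
        points = " ".join(f"{x:.2f},{y:.2f}" for x, y in hull)
        ET.SubElement(
            hulls,
            "polygon",
            {
                "id": f"hull-{node.node_id}",
                "points": points,
                "fill": "#f0f0f5",
                "stroke": "#aaaacc",
                "stroke-width": "1",
            },
        )

    edges_g = ET.SubElement(svg, "g", {"id": "edges"})
    for edge in graph.base.edges:
        src = endpoint_xy.get(edge.source)
        tgt = endpoint_xy.get(edge.target)
        if src is None or tgt is None:
            continue
        style = EDGE_STYLE[edge.visual_class]
        attrs = {
            "id": f"edge-{edge.edge_id}",
            "x1": f"{src[0]:.2f}",
            "y1": f"{src[1]:.2f}",
            "x2": f"{tgt[0]:.2f}",
            "y2": f"{tgt[1]:.2f}",
            "stroke": style["stroke"],
            "stroke-width": "1.5",
        }
        if style["dasharray"]:
            attrs["stroke-dasharray"] = style["dasharray"]
        if style["marker"]:
            attrs["marker-end"] = f"url(#{style['marker']})"
        ET.SubElement(edges_g, "line", attrs)

    overlay_g = ET.SubElement(svg, "g", {"id": "overlay-edges"})
    display_xy = {d_id(d): (d.x, d.y) for d in graph.display_nodes()}
    for ov in graph.overlay_edges:
        src = endpoint_xy.get(ov.kinase_node_id)
        tgt = display_xy.get(ov.ptm_node_id)
        if src is None or tgt is None:
            continue
        ET.SubElement(
            overlay_g,
            "line",
            {
                "id": f"edge-{ov.edge_id}",
                "x1": f"{src[0]:.2f}",
                "y1": f"{src[1]:.2f}",
                "x2": f"{tgt[0]:.2f}",
                "y2": f"{tgt[1]:.2f}",
                "stroke": "#e377c2",
                "stroke-width": "1.2",
                "stroke-dasharray": "2,2",
                "marker-end": "url(#arrow)",
            },
        )

    nodes_g = ET.SubElement(svg, "g", {"id": "nodes"})
    for node in placed:
        fill = NODE_FILL.get(node.node_type, NODE_FILL["misc"])
        if node.node_type == "compound":
            ET.SubElement(
                nodes_g,
                "ellipse",
                {
                    "id": f"node-{node.node_id}",
                    "cx": f"{node.x:.2f}",
                    "cy": f"{node.y:.2f}",
                    "rx": f"{NODE_W / 3:.2f}",
                    "ry": f"{NODE_H / 2:.2f}",
                    "fill": fill,
                    "stroke": "#555555",
                },
            )
        else:
            ET.SubElement(
                nodes_g,
                "rect",
                {
                    "id": f"node-{node.node_id}",
                    "x": f"{node.x - NODE_W / 2:.2f}",
                    "y": f"{node.y - NODE_H / 2:.2f}",
                    "width": f"{NODE_W:.2f}",
                    "height": f"{NODE_H:.2f}",
                    "rx": "4",
                    "fill": fill,
                    "stroke": "#555555",
                },
            )
        if node.node_id in graph.highlights:
            ET.SubElement(
                nodes_g,
                "circle",
                {
                    "id": f"highlight-{node.node_id}",
                    "cx": f"{node.x:.2f}",
                    "cy": f"{node.y:.2f}",
                    "r": f"{NODE_W / 2 + 6:.2f}",
                    "fill": "none",
                    "stroke": HIGHLIGHT_COLORS[graph.highlights[node.node_id]],
                    "stroke-width": "2.5",
                },
            )
        if node.label:
            label = ET.SubElement(
                nodes_g,
                "text",
                {
                    "id": f"label-{node.node_id}",
                    "x": f"{node.x:.2f}",
                    "y": f"{node.y + 4:.2f}",
                    "text-anchor": "middle",
                    "font-size": "11",
                },
            )
            label.text = node.label

    ptm_g = ET.SubElement(svg, "g", {"id": "peptide-layer"})
    for display in graph.display_nodes():
        did = d_id(display)
        ET.SubElement(
            ptm_g,
            "ellipse" if not _is_summary(display) else "circle",
            _ptm_attrs(display, did),
        )
        if _is_summary(display):
            count = ET.SubElement(
                ptm_g,
                "text",
                {
                    "id": f"count-{did}",
                    "x": f"{display.x:.2f}",
                    "y": f"{display.y + 3:.2f}",
                    "text-anchor": "middle",
                    "font-size": "9",
                    "fill": "#ffffff",
                },
            )
            count.text = str(display.count)
        elif options.show_site_labels and display.record.sites:
            label = ET.SubElement(
                ptm_g,
                "text",
                {
                    "id": f"sitelabel-{did}",
                    "x": f"{display.x:.2f}",
                    "y": f"{display.y - PTM_RY - 2:.2f}",
                    "text-anchor": "middle",
                    "font-size": "8",
                },
            )
            label.text = display.record.site_label()

    return ET.tostring(svg, encoding="unicode", xml_declaration=True)


def d_id(display) -> str:
    return getattr(display, "ptm_node_id", None) or display.summary_node_id


def _is_summary(display) -> bool:
    return hasattr(display, "summary_node_id")


def _ptm_attrs(display, did: str) -> dict:
    if _is_summary(display):
        return {
            "id": f"ptm-{did}",
            "cx": f"{display.x:.2f}",
            "cy": f"{display.y:.2f}",
            "r": f"{PTM_RX:.2f}",
            "fill": display.color,
            "stroke": "#333333",
        }
    return {
        "id": f"ptm-{did}",
        "cx": f"{display.x:.2f}",
        "cy": f"{display.y:.2f}",
        "rx": f"{PTM_RX:.2f}",
        "ry": f"{PTM_RY:.2f}",
        "fill": display.color,
        "stroke": "#333333",
    }


def _defs(svg: ET.Element) -> None:
    defs = ET.SubElement(svg, "defs")
    arrow = ET.SubElement(
        defs,
        "marker",
        {
            "id": "arrow",
            "viewBox": "0 0 10 10",
            "refX": "9",
            "refY": "5",
            "markerWidth": "7",
            "markerHeight": "7",
            "orient": "auto-start-reverse",
        },
    )
    ET.SubElement(arrow, "path", {"d": "M 0 0 L 10 5 L 0 10 z", "fill": "#333333"})
    tbar = ET.SubElement(
        defs,
        "marker",
        {
            "id": "tbar",
            "viewBox": "0 0 10 10",
            "refX": "5",
            "refY": "5",
            "markerWidth": "7",
            "markerHeight": "7",
            "orient": "auto",
        },
    )
    ET.SubElement(tbar, "path", {"d": "M 4 0 L 6 0 L 6 10 L 4 10 z", "fill": "#333333"})
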