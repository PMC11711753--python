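"""Project a regulated-PTM dataset onto a pathway skeleton.

Each regulated modified peptide is matched against the skeleton's
gene/protein nodes by UniProt accession (isoform suffixes stripped) and/or
gene name (case-insensitive); a record that matches several skeleton nodes
yields one PTM node per match, since canonical diagrams often draw the same
protein more than once.  Matched peptides become small satellite nodes tied
to their reference node by an invisible anchor edge (needed only for
layout), optionally collapsed into one summary node per regulation category
carrying the peptide count.

Coloring supports three schemes: categorical regulation (up/down/not),
continuous by log2 fold change, and continuous by potency (pEC50) for
dose-resolved data.  Continuous domains are computed over *matched* records
only, after projection.

Kinase-substrate annotations overlay as extra kinase -> PTM-node edges, and
kinase-activity results (e.g. from KSEA) can flag skeleton nodes as
significantly up-, down-, or unknown-direction regulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

from .model import PathwaySkeleton, SkeletonNode

# fixed categorical palette (configurable per call)
REGULATION_COLORS = {"up": "#d62728", "down": "#1f77b4", "not": "#999999"}
NO_VALUE_COLOR = "#bbbbbb"
HIGHLIGHT_COLORS = {"up": "#d62728", "down": "#1f77b4", "unknown": "#9467bd"}


@dataclass(frozen=True)
class PTMRecord:
    """One regulated modified peptide in one experiment."""

    experiment: str
    peptide_key: str
    regulation: str  # up | down | not
    uniprot_accessions: tuple[str, ...] = ()
    gene_names: tuple[str, ...] = ()
    residue: str | None = None
    position: int | None = None
    sites: tuple[tuple[str, int], ...] = ()  # all (residue, position) pairs
    fold_change: float | None = None
    p_adj: float | None = None
    pec50: float | None = None
    details: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.regulation not in ("up", "down", "not"):
            raise ValueError(f"regulation must be up/down/not, got {self.regulation!r}")
        if self.position is not None and self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        object.__setattr__(self, "uniprot_accessions", tuple(self.uniprot_accessions))
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        sites = tuple(tuple(s) for s in self.sites)
        if not sites and self.residue is not None and self.position is not None:
            sites = ((self.residue, self.position),)
        object.__setattr__(self, "sites", sites)
        object.__setattr__(self, "details", tuple(tuple(d) for d in self.details))

    def site_label(self) -> str:
        return "/".join(f"{r}{p}" for r, p in self.sites)


@dataclass(frozen=True)
class ColorScale:
    mode: str = "regulation"  # regulation | fold_change | potency
    domain_min: float | None = None
    domain_max: float | None = None
    color_low: str = "#1f77b4"
    color_high: str = "#d62728"
    palette: tuple[tuple[str, str], ...] = tuple(REGULATION_COLORS.items())

    def __post_init__(self):
        if self.mode not in ("regulation", "fold_change", "potency"):
            raise ValueError(f"unknown color mode {self.mode!r}")
        if (
            self.domain_min is not None
            and self.domain_max is not None
            and self.domain_min > self.domain_max
        ):
            raise ValueError("domain_min must be <= domain_max")


@dataclass
class PTMNode:
    ptm_node_id: str
    record: PTMRecord
    skeleton_node_id: str
    color: str
    x: float | None = None
    y: float | None = None


@dataclass
class SummaryNode:
    summary_node_id: str
    skeleton_node_id: str
    regulation: str
    count: int
    color: str
    x: float | None = None
    y: float | None = None


@dataclass
class OverlayEdge:
    edge_id: str
    kinase_node_id: str
    ptm_node_id: str
    kinase: str


@dataclass
class ProjectedGraph:
    base: PathwaySkeleton
    scale: ColorScale
    ptm_nodes: list[PTMNode] = field(default_factory=list)
    summary_nodes: list[SummaryNode] = field(default_factory=list)
    anchor_edges: list[tuple[str, str]] = field(default_factory=list)  # (ptm, skeleton)
    overlay_edges: list[OverlayEdge] = field(default_factory=list)
    highlights: dict[str, str] = field(default_factory=dict)  # node_id -> direction
    unmatched: list[PTMRecord] = field(default_factory=list)
    unmatched_overlay_rows: int = 0
    unmatched_kinases: list[str] = field(default_factory=list)
    layout_trace: dict[str, list[float]] = field(default_factory=dict)

    def display_nodes(self):
        """PTM or summary nodes, whichever representation is active."""
        return self.summary_nodes if self.summary_nodes else self.ptm_nodes


# ---------------------------------------------------------------------------
# Kinase-substrate annotation table


@dataclass(frozen=True)
class KinaseSubstrateRow:
    kinase: str
    substrate: str  # accession or gene name
    residue: str
    position: int


@dataclass
class KinaseSubstrateTable:
    rows: list[KinaseSubstrateRow] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, source: Union[str, Path, IO[str]]) -> "KinaseSubstrateTable":
        """Load a 3-column TSV: kinase, substrate accession/gene, site ("S1134")."""
        if isinstance(source, (str, Path)):
            lines = Path(source).read_text().splitlines()
        else:
            lines = source.read().splitlines()
        rows = []
        for line_no, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"kinase-substrate TSV line {line_no}: expected 3 columns")
            residue, position = parse_site(parts[2])
            rows.append(KinaseSubstrateRow(parts[0], parts[1], residue, position))
        return cls(rows)

    def substrates_of(self, kinase: str) -> list[KinaseSubstrateRow]:
        k = kinase.casefold()
        return [r for r in self.rows if r.kinase.casefold() == k]

    def kinases(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r.kinase not in seen:
                seen.append(r.kinase)
        return seen


def parse_site(site: str) -> tuple[str, int]:
    """Split a site string like "S1134" into ("S", 1134)."""
    site = site.strip()
    if len(site) < 2 or not site[0].isalpha():
        raise ValueError(f"cannot parse site {site!r} (expected residue letter + position)")
    residue, pos = site[0].upper(), site[1:]
    if not pos.isdigit() or int(pos) < 1:
        raise ValueError(f"cannot parse site {site!r} (position must be a positive integer)")
    return residue, int(pos)


# ---------------------------------------------------------------------------
# Matching


def strip_isoform(accession: str) -> str:
    return accession.split("-", 1)[0]


def _node_match(record: PTMRecord, node: SkeletonNode) -> bool:
    """Union semantics: an accession hit or a gene-name hit suffices."""
    rec_accs = {strip_isoform(a) for a in record.uniprot_accessions}
    node_accs = {strip_isoform(a) for a in node.uniprot_accessions}
    if rec_accs & node_accs:
        return True
    rec_genes = {g.casefold() for g in record.gene_names}
    node_genes = {g.casefold() for g in node.gene_names}
    return bool(rec_genes & node_genes)


def match_record(record: PTMRecord, skeleton: PathwaySkeleton) -> list[str]:
    """All skeleton node ids a record projects onto (may be several)."""
    return [
        n.node_id
        for n in skeleton.nodes
        if n.node_type == "gene_protein" and _node_match(record, n)
    ]


# ---------------------------------------------------------------------------
# Coloring


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    c = color.lstrip("#")
    return int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16)


def _rgb_to_hex(rgb: tuple[float, float, float]) -> str:
    return "#%02x%02x%02x" % tuple(int(round(v)) for v in rgb)


def _interpolate(low: str, high: str, t: float) -> str:
    lo, hi = _hex_to_rgb(low), _hex_to_rgb(high)
    return _rgb_to_hex(tuple(l + (h - l) * t for l, h in zip(lo, hi)))


def make_color(record: PTMRecord, scale: ColorScale) -> str:
    """Resolve one record's display color under a color scale.

    Categorical mode uses the fixed regulation palette.  Continuous modes
    interpolate linearly between the endpoint colors over
    [domain_min, domain_max]; the domain endpoints map *exactly* onto the
    endpoint colors.  A record lacking the relevant value renders in a
    designated no-value gray, and a degenerate (zero-width) domain yields
    the midpoint color.
    """
    if scale.mode == "regulation":
        return dict(scale.palette).get(record.regulation, NO_VALUE_COLOR)
    value = record.fold_change if scale.mode == "fold_change" else record.pec50
    if value is None or scale.domain_min is None or scale.domain_max is None:
        return NO_VALUE_COLOR
    if scale.domain_max == scale.domain_min:
        return _interpolate(scale.color_low, scale.color_high, 0.5)
    t = (value - scale.domain_min) / (scale.domain_max - scale.domain_min)
    if value == scale.domain_min:
        return scale.color_low
    if value == scale.domain_max:
        return scale.color_high
    return _interpolate(scale.color_low, scale.color_high, min(max(t, 0.0), 1.0))


def fit_domain(records: Iterable[PTMRecord], scale: ColorScale) -> ColorScale:
    """Resolve the continuous color domain from matched records only."""
    if scale.mode == "regulation" or (scale.domain_min is not None and scale.domain_max is not None):
        return scale
    attr = "fold_change" if scale.mode == "fold_change" else "pec50"
    values = [getattr(r, attr) for r in records if getattr(r, attr) is not None]
    if not values:
        return scale
    return ColorScale(
        mode=scale.mode,
        domain_min=min(values),
        domain_max=max(values),
        color_low=scale.color_low,
        color_high=scale.color_high,
        palette=scale.palette,
    )


# ---------------------------------------------------------------------------
# Projection


def project_dataset(
    dataset: Sequence[PTMRecord],
    skeleton: PathwaySkeleton,
    scale: ColorScale | None = None,
    collapse: bool = False,
) -> ProjectedGraph:
    """Match every record onto the skeleton and build the projected graph.

    One PTM node is created per (record, matched node) pair.  With
    ``collapse=True`` per-record nodes are replaced by one summary node per
    (skeleton node, regulation category) carrying the collapsed count.
    Unmatched records are reported on the returned graph, never dropped
    silently.
    """
    scale = scale or ColorScale()
    matches: list[tuple[PTMRecord, str]] = []
    unmatched: list[PTMRecord] = []
    for record in dataset:
        node_ids = match_record(record, skeleton)
        if not node_ids:
            unmatched.append(record)
        for node_id in node_ids:
            matches.append((record, node_id))

    resolved = fit_domain([r for r, _ in matches], scale)
    graph = ProjectedGraph(base=skeleton, scale=resolved, unmatched=unmatched)

    for i, (record, node_id) in enumerate(matches):
        ptm_id = f"ptm{i}"
        graph.ptm_nodes.append(
            PTMNode(
                ptm_node_id=ptm_id,
                record=record,
                skeleton_node_id=node_id,
                color=make_color(record, resolved),
            )
        )
        graph.anchor_edges.append((ptm_id, node_id))

    if collapse:
        counts: dict[tuple[str, str], int] = {}
        for ptm in graph.ptm_nodes:
            key = (ptm.skeleton_node_id, ptm.record.regulation)
            counts[key] = counts.get(key, 0) + 1
        graph.summary_nodes = [
            SummaryNode(
                summary_node_id=f"summary_{node_id}_{regulation}",
                skeleton_node_id=node_id,
                regulation=regulation,
                count=count,
                color=dict(resolved.palette).get(regulation, NO_VALUE_COLOR),
            )
            for (node_id, regulation), count in sorted(counts.items())
        ]
        graph.anchor_edges = [
            (s.summary_node_id, s.skeleton_node_id) for s in graph.summary_nodes
        ]
    return graph


def overlay_kinase_edges(graph: ProjectedGraph, table: KinaseSubstrateTable) -> ProjectedGraph:
    """Add kinase -> PTM-node edges for annotated kinase-substrate pairs.

    A table row contributes an edge iff its kinase matches a gene_protein
    node of the skeleton *and* its substrate site matches a projected PTM
    node (any site of a multiply-modified peptide counts).  Unmatched rows
    are skipped and counted.
    """
    kinase_nodes: dict[str, list[str]] = {}
    for node in graph.base.nodes:
        if node.node_type != "gene_protein":
            continue
        for gene in node.gene_names:
            kinase_nodes.setdefault(gene.casefold(), []).append(node.node_id)
        if node.label:
            kinase_nodes.setdefault(node.label.casefold(), []).append(node.node_id)

    n_unmatched = 0
    counter = len(graph.overlay_edges)
    for row in table.rows:
        node_ids = kinase_nodes.get(row.kinase.casefold(), [])
        hit = False
        for ptm in graph.ptm_nodes:
            if not _substrate_match(row, ptm.record):
                continue
            for node_id in dict.fromkeys(node_ids):
                graph.overlay_edges.append(
                    OverlayEdge(
                        edge_id=f"ks{counter}",
                        kinase_node_id=node_id,
                        ptm_node_id=ptm.ptm_node_id,
                        kinase=row.kinase,
                    )
                )
                counter += 1
                hit = True
        if not hit:
            n_unmatched += 1
    graph.unmatched_overlay_rows += n_unmatched
    return graph


def _substrate_match(row: KinaseSubstrateRow, record: PTMRecord) -> bool:
    sub = row.substrate.casefold()
    names = {strip_isoform(a).casefold() for a in record.uniprot_accessions}
    names |= {g.casefold() for g in record.gene_names}
    if sub not in names:
        return False
    return any(r == row.residue and p == row.position for r, p in record.sites)


def highlight_kinases(
    graph: ProjectedGraph,
    activities: Iterable[tuple[str, float, float, str]],
    score_cut: float = 0.5,
    fdr_cut: float = 0.1,
) -> ProjectedGraph:
    """Flag skeleton nodes whose kinase passed the activity filter.

    A kinase qualifies when |score| >= score_cut (inclusive) and
    fdr < fdr_cut (exclusive); the defaults mirror the conventional
    |score| >= 0.5 at 10% FDR cut for KSEA-style activity inference.
    Directions color as up=red, down=blue, unknown=purple at render time.
    """
    by_name: dict[str, list[str]] = {}
    for node in graph.base.nodes:
        if node.node_type != "gene_protein":
            continue
        for gene in node.gene_names:
            by_name.setdefault(gene.casefold(), []).append(node.node_id)
        if node.label:
            by_name.setdefault(node.label.casefold(), []).append(node.node_id)

    for kinase, score, fdr, direction in activities:
        if math.isnan(score) or abs(score) < score_cut or not (fdr < fdr_cut):
            continue
        node_ids = by_name.get(kinase.casefold())
        if not node_ids:
            graph.unmatched_kinases.append(kinase)
            continue
        if direction not in HIGHLIGHT_COLORS:
            direction = "unknown"
        for node_id in node_ids:
            graph.highlights[node_id] = direction
    return graph
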