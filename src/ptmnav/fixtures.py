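"""Synthetic inputs for every other module: pathway XML in both dialects,
random skeletons, kinase-substrate tables, PSSMs, signature sets, and PTM
datasets with planted signal.

Nothing here touches the network; fixtures are fully deterministic under
their seed, and each generated pathway ships with its ground-truth skeleton
so the readers are tested against *structure*, not byte layout.  The
dataset generator mirrors the statistical shape of kinase-inhibitor
perturbation experiments: substrates of one planted kinase receive a common
log2 fold-change shift over Gaussian noise while all remaining peptides
stay null, and an optional potency mode assigns pEC50 values from a narrow
band to the regulated peptides, emulating a single-target dose-response
screen.
"""

from __future__ import annotations

import math
import random
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import numpy as np

from .enrichment import PSSM, AMINO_ACIDS, Signature, site_key
from .kgml import IdMappingTable, KGML_RELATION_SUBTYPES, map_kegg_types
from .gpml import GPML_EDGE_TYPES, map_gpml_types
from .model import PathwaySkeleton, SkeletonEdge, SkeletonNode
from .projection import KinaseSubstrateRow, KinaseSubstrateTable, PTMRecord


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    # pathway side
    n_nodes: int = 12
    n_edges: int = 14
    n_groups: int = 1
    n_reactions: int = 1  # reactions (KGML) or anchored interactions (GPML)
    # dataset side
    n_peptides: int = 500
    fraction_up: float = 0.1
    fraction_down: float = 0.1
    planted_kinase: str = "KIN1"
    effect_shift: float = -1.5  # log2 units
    noise_sd: float = 0.3
    potency_band: tuple[float, float] | None = None  # e.g. (6.4, 7.4)

    def __post_init__(self):
        if not (0 <= self.fraction_up <= 1 and 0 <= self.fraction_down <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.fraction_up + self.fraction_down > 1:
            raise ValueError("fraction_up + fraction_down must be <= 1")
        if not math.isfinite(self.effect_shift):
            raise ValueError("effect_shift must be finite")


@dataclass
class FixturePathway:
    xml: str
    skeleton: PathwaySkeleton  # ground truth
    mapping: IdMappingTable


# ---------------------------------------------------------------------------
# Shared node planning


@dataclass(frozen=True)
class _NodePlan:
    index: int
    kind: str  # gene | compound | map | label(misc, GPML only)
    label: str
    accession: str | None
    x: float
    y: float


def _plan_nodes(spec: SyntheticSpec, rng: random.Random, with_label: bool) -> list[_NodePlan]:
    if spec.n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    kinds = ["gene", "gene"]
    extras = ["compound", "map"] + (["label"] if with_label else [])
    for extra in extras:
        if len(kinds) < spec.n_nodes:
            kinds.append(extra)
    while len(kinds) < spec.n_nodes:
        kinds.append("gene" if rng.random() < 0.8 else "compound")
    rng.shuffle(kinds)
    plans = []
    gene_i = comp_i = 0
    for i, kind in enumerate(kinds):
        x, y = 100.0 + 130.0 * (i % 4), 80.0 + 100.0 * (i // 4)
        if kind == "gene":
            plans.append(_NodePlan(i, kind, f"GENE{gene_i}", f"P{10000 + gene_i}", x, y))
            gene_i += 1
        elif kind == "compound":
            plans.append(_NodePlan(i, kind, f"C{20000 + comp_i}", None, x, y))
            comp_i += 1
        elif kind == "map":
            plans.append(_NodePlan(i, kind, "Other pathway", None, x, y))
        else:
            plans.append(_NodePlan(i, kind, f"note {i}", None, x, y))
    return plans


def _plan_edges(spec: SyntheticSpec, rng: random.Random, n_endpoints: int, subtypes: list[str]):
    possible = [(i, j) for i in range(n_endpoints) for j in range(n_endpoints) if i != j]
    if spec.n_edges > len(possible):
        raise ValueError(
            f"infeasible spec: {spec.n_edges} edges exceed complete graph on {n_endpoints} nodes"
        )
    pairs = rng.sample(possible, spec.n_edges)
    return [(i, j, rng.choice(subtypes)) for i, j in pairs]


def _mapping_for(plans: list[_NodePlan], kegg_org: str | None) -> IdMappingTable:
    table = IdMappingTable()
    for plan in plans:
        if plan.accession is None:
            continue
        gene_num = 1000 + int(plan.label.removeprefix("GENE"))
        keys = [str(gene_num)]
        if kegg_org:
            keys.append(f"{kegg_org}:{gene_num}")
        for key in keys:
            table.to_uniprot[key] = [plan.accession]
        table.uniprot_to_gene[plan.accession] = plan.label
    return table


# ---------------------------------------------------------------------------
# KGML fixture

_KGML_SUBTYPES = [
    "activation",
    "inhibition",
    "repression",
    "binding/association",
    "phosphorylation",
    "indirect effect",
]


def _make_kgml(spec: SyntheticSpec, rng: random.Random) -> FixturePathway:
    plans = _plan_nodes(spec, rng, with_label=False)
    mapping = _mapping_for(plans, kegg_org="syn")
    edges = _plan_edges(spec, rng, len(plans), _KGML_SUBTYPES)

    gene_plans = [p for p in plans if p.kind == "gene"]
    groups: list[list[_NodePlan]] = []
    pool = list(gene_plans)
    for _ in range(spec.n_groups):
        if len(pool) < 2:
            raise ValueError("not enough gene nodes for the requested groups")
        members = rng.sample(pool, 2)
        for m in members:
            pool.remove(m)
        groups.append(members)

    reactions: list[tuple[list[_NodePlan], list[_NodePlan], bool]] = []
    candidates = [p for p in plans if p.kind in ("gene", "compound")]
    used_first: set[int] = set()
    for _ in range(spec.n_reactions):
        k_s = min(rng.choice([1, 2]), max(1, len(candidates) - 1))
        for _try in range(50):
            chosen = rng.sample(candidates, k_s + 1)
            # the KGML reaction element id references its first substrate's
            # entry; keep those distinct so reactions do not collide
            if chosen[0].index not in used_first:
                break
        else:
            raise ValueError("not enough entries for the requested reactions")
        used_first.add(chosen[0].index)
        reactions.append((chosen[:k_s], chosen[k_s:], rng.random() < 0.5))

    root = ET.Element(
        "pathway",
        {"name": f"path:syn{spec.seed % 100000:05d}", "org": "syn",
         "number": f"{spec.seed % 100000:05d}", "title": "Synthetic pathway"},
    )
    entry_id = {}
    next_id = 1
    for plan in plans:
        entry_id[plan.index] = next_id
        kegg_type = {"gene": "gene", "compound": "compound", "map": "map"}[plan.kind]
        if plan.kind == "gene":
            name = f"syn:{1000 + int(plan.label.removeprefix('GENE'))}"
            gname = plan.label
        elif plan.kind == "compound":
            name = f"cpd:{plan.label}"
            gname = plan.label
        else:
            name = "path:syn99999"
            gname = f"TITLE:{plan.label}"
        entry = ET.SubElement(root, "entry", {"id": str(next_id), "name": name, "type": kegg_type})
        ET.SubElement(
            entry, "graphics",
            {"name": gname, "x": str(plan.x), "y": str(plan.y), "type": "rectangle"},
        )
        next_id += 1
    group_entry_ids = []
    for members in groups:
        entry = ET.SubElement(root, "entry", {"id": str(next_id), "name": "undefined", "type": "group"})
        ET.SubElement(entry, "graphics", {"type": "rectangle"})
        for m in members:
            ET.SubElement(entry, "component", {"id": str(entry_id[m.index])})
        group_entry_ids.append(next_id)
        next_id += 1
    for i, j, subtype in edges:
        rel = ET.SubElement(
            root, "relation",
            {"entry1": str(entry_id[i]), "entry2": str(entry_id[j]), "type": "PPrel"},
        )
        ET.SubElement(rel, "subtype", {"name": subtype, "value": "?"})
    # a reaction element's id must reference an entry; reuse its first substrate
    for n, (subs, prods, reversible) in enumerate(reactions):
        rx = ET.SubElement(
            root, "reaction",
            {"id": str(entry_id[subs[0].index]), "name": f"rn:R{n:05d}",
             "type": "reversible" if reversible else "irreversible"},
        )
        for s in subs:
            ET.SubElement(rx, "substrate", {"id": str(entry_id[s.index]), "name": f"x:{s.label}"})
        for p in prods:
            ET.SubElement(rx, "product", {"id": str(entry_id[p.index]), "name": f"x:{p.label}"})

    xml = ET.tostring(root, encoding="unicode", xml_declaration=True)

    # ground truth
    nodes = []
    for plan in plans:
        node_type, _ = map_kegg_types({"gene": "gene", "compound": "compound", "map": "map"}[plan.kind])
        nodes.append(
            SkeletonNode(
                node_id=f"n{plan.index}",
                node_type=node_type,
                label=plan.label,
                uniprot_accessions=(plan.accession,) if plan.accession else (),
                gene_names=(plan.label,) if plan.accession else (),
                x=plan.x,
                y=plan.y,
            )
        )
    for g, members in enumerate(groups):
        nodes.append(
            SkeletonNode(
                node_id=f"g{g}", node_type="group",
                members=tuple(f"n{m.index}" for m in members),
            )
        )
    truth_edges = [
        SkeletonEdge(
            edge_id=f"e{k}", source=f"n{i}", target=f"n{j}",
            relation_types=frozenset({KGML_RELATION_SUBTYPES[subtype]}),
        )
        for k, (i, j, subtype) in enumerate(edges)
    ]
    k = len(truth_edges)
    for subs, prods, reversible in reactions:
        types = frozenset({"reaction", "reversible"} if reversible else {"reaction"})
        for s in subs:
            for p in prods:
                truth_edges.append(
                    SkeletonEdge(
                        edge_id=f"e{k}", source=f"n{s.index}", target=f"n{p.index}",
                        relation_types=types,
                    )
                )
                k += 1
    skeleton = PathwaySkeleton(
        pathway_id=f"syn{spec.seed % 100000:05d}",
        name="Synthetic pathway",
        organism="syn",
        source_db="kegg",
        nodes=nodes,
        edges=truth_edges,
    )
    return FixturePathway(xml=xml, skeleton=skeleton, mapping=mapping)


# ---------------------------------------------------------------------------
# GPML fixture

_GPML_ARROWHEADS = ["Arrow", "TBar", "mim-binding", "mim-catalysis", "Line", "mim-stimulation"]


def _make_gpml(spec: SyntheticSpec, rng: random.Random) -> FixturePathway:
    plans = _plan_nodes(spec, rng, with_label=True)
    mapping = _mapping_for(plans, kegg_org=None)
    connectable = [p for p in plans if p.kind != "label"]
    edges = _plan_edges(spec, rng, len(connectable), _GPML_ARROWHEADS)

    gene_plans = [p for p in plans if p.kind == "gene"]
    groups: list[list[_NodePlan]] = []
    pool = list(gene_plans)
    for _ in range(spec.n_groups):
        if len(pool) < 2:
            raise ValueError("not enough gene nodes for the requested groups")
        members = rng.sample(pool, 2)
        for m in members:
            pool.remove(m)
        groups.append(members)
    group_of = {m.index: g for g, members in enumerate(groups) for m in members}

    # anchored interactions: a node -> anchor placed on a regular edge
    if spec.n_reactions > 0 and not edges:
        raise ValueError("anchors need at least one regular edge")
    anchors = []
    for a in range(spec.n_reactions):
        base = rng.randrange(len(edges))
        src = rng.choice(connectable)
        anchors.append((a, base, src))

    ns = "http://pathvisio.org/GPML/2013a"
    root = ET.Element(
        "Pathway",
        {"xmlns": ns, "Name": "Synthetic GPML pathway", "Organism": "Homo sapiens"},
    )
    wp_id = f"WP{9000 + spec.seed % 1000}"
    ET.SubElement(root, "Xref", {"Database": "WikiPathways", "ID": wp_id})
    for plan in plans:
        attrs = {"TextLabel": plan.label, "GraphId": f"id{plan.index}"}
        if plan.index in group_of:
            attrs["GroupRef"] = f"grp{group_of[plan.index]}"
        if plan.kind == "label":
            el = ET.SubElement(root, "Label", attrs)
            ET.SubElement(el, "Graphics", {"CenterX": str(plan.x), "CenterY": str(plan.y)})
        else:
            attrs["Type"] = {"gene": "GeneProduct", "compound": "Metabolite", "map": "Pathway"}[plan.kind]
            el = ET.SubElement(root, "DataNode", attrs)
            ET.SubElement(el, "Graphics", {"CenterX": str(plan.x), "CenterY": str(plan.y)})
            if plan.kind == "gene":
                gene_num = 1000 + int(plan.label.removeprefix("GENE"))
                ET.SubElement(el, "Xref", {"Database": "Entrez Gene", "ID": str(gene_num)})
    for g in range(len(groups)):
        ET.SubElement(root, "Group", {"GroupId": f"grp{g}", "GraphId": f"grpnode{g}"})
    for k, (i, j, arrowhead) in enumerate(edges):
        inter = ET.SubElement(root, "Interaction", {"GraphId": f"edge{k}"})
        gfx = ET.SubElement(inter, "Graphics")
        ET.SubElement(gfx, "Point", {"X": "0", "Y": "0", "GraphRef": f"id{connectable[i].index}"})
        pt = {"X": "0", "Y": "0", "GraphRef": f"id{connectable[j].index}"}
        if arrowhead != "Line":
            pt["ArrowHead"] = arrowhead
        ET.SubElement(gfx, "Point", pt)
        for a, base, _src in anchors:
            if base == k:
                ET.SubElement(gfx, "Anchor", {"GraphId": f"anchor{a}", "Position": "0.5"})
    for a, base, src in anchors:
        inter = ET.SubElement(root, "Interaction", {"GraphId": f"aedge{a}"})
        gfx = ET.SubElement(inter, "Graphics")
        ET.SubElement(gfx, "Point", {"X": "0", "Y": "0", "GraphRef": f"id{src.index}"})
        ET.SubElement(gfx, "Point", {"X": "0", "Y": "0", "GraphRef": f"anchor{a}", "ArrowHead": "Arrow"})

    xml = ET.tostring(root, encoding="unicode", xml_declaration=True)

    nodes = []
    for plan in plans:
        gpml_kind = {"gene": "GeneProduct", "compound": "Metabolite", "map": "Pathway", "label": "Label"}[plan.kind]
        node_type, _ = map_gpml_types(gpml_kind)
        nodes.append(
            SkeletonNode(
                node_id=f"n{plan.index}",
                node_type=node_type,
                label=plan.label,
                uniprot_accessions=(plan.accession,) if plan.accession else (),
                gene_names=(plan.label,) if plan.accession else (),
                x=plan.x,
                y=plan.y,
            )
        )
    for g, members in enumerate(groups):
        nodes.append(
            SkeletonNode(
                node_id=f"g{g}", node_type="group",
                members=tuple(f"n{m.index}" for m in members),
            )
        )
    truth_edges = [
        SkeletonEdge(
            edge_id=f"e{k}",
            source=f"n{connectable[i].index}",
            target=f"n{connectable[j].index}",
            relation_types=frozenset({GPML_EDGE_TYPES[arrowhead]}),
        )
        for k, (i, j, arrowhead) in enumerate(edges)
    ]
    for a, base, src in anchors:
        truth_edges.append(
            SkeletonEdge(
                edge_id=f"ae{a}", source=f"n{src.index}", target=f"e{base}",
                relation_types=frozenset({GPML_EDGE_TYPES["Arrow"]}),
            )
        )
    skeleton = PathwaySkeleton(
        pathway_id=wp_id,
        name="Synthetic GPML pathway",
        organism="Homo sapiens",
        source_db="wikipathways",
        nodes=nodes,
        edges=truth_edges,
    )
    return FixturePathway(xml=xml, skeleton=skeleton, mapping=mapping)


def make_fixture_pathway(spec: SyntheticSpec, dialect: str) -> FixturePathway:
    """Emit a synthetic pathway XML document plus its ground-truth skeleton
    and matching offline id-mapping table.  Deterministic under the seed
    (same seed -> byte-identical XML)."""
    rng = random.Random(spec.seed)
    if dialect == "kgml":
        return _make_kgml(spec, rng)
    if dialect == "gpml":
        return _make_gpml(spec, rng)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Structure signatures (for graph comparison independent of id schemes)


def structure_signature(skeleton: PathwaySkeleton):
    """Canonical, id-independent structural fingerprint of a skeleton.

    Node ids are replaced by labels (unique in fixtures), groups by their
    sorted member labels, and edge endpoints resolve recursively so that
    edge-on-edge references survive renaming.  Two skeletons parsed from
    different serializations of the same structure compare equal.
    """
    label_of = {}
    for node in skeleton.nodes:
        if node.node_type == "group":
            continue
        label_of[node.node_id] = (node.node_type, node.label, node.uniprot_accessions, node.x, node.y)
    group_keys = tuple(
        sorted(
            tuple(sorted(label_of[m][1] for m in node.members))
            for node in skeleton.nodes
            if node.node_type == "group"
        )
    )
    edge_by_id = skeleton.edge_map()
    memo: dict[str, object] = {}

    def endpoint_key(ref: str):
        if ref in label_of:
            return ("node", label_of[ref][1])
        return ("edge", edge_key(ref))

    def edge_key(edge_id: str):
        if edge_id not in memo:
            edge = edge_by_id[edge_id]
            memo[edge_id] = (
                endpoint_key(edge.source),
                endpoint_key(edge.target),
                tuple(sorted(edge.relation_types)),
                edge.visual_class,
            )
        return memo[edge_id]

    edge_keys = tuple(sorted(repr(edge_key(e.edge_id)) for e in skeleton.edges))
    node_keys = tuple(sorted(repr(v) for v in label_of.values()))
    return (node_keys, group_keys, edge_keys)


# ---------------------------------------------------------------------------
# Random valid skeletons (round-trip / validation fuzzing)


def make_random_skeleton(
    seed: int, n_nodes: int = 8, n_edges: int = 10, edge_on_edge: bool = True, n_groups: int = 1
) -> PathwaySkeleton:
    """A random validation-passing skeleton, optionally with edges that
    terminate on other edges."""
    rng = random.Random(seed)
    nodes = []
    for i in range(n_nodes):
        node_type = rng.choice(["gene_protein", "gene_protein", "gene_protein", "compound", "pathway", "misc"])
        acc = (f"P{40000 + i}",) if node_type == "gene_protein" else ()
        nodes.append(
            SkeletonNode(
                node_id=f"n{i}", node_type=node_type, label=f"N{i}",
                uniprot_accessions=acc,
                gene_names=(f"GN{i}",) if acc else (),
                x=round(rng.uniform(0, 800), 2), y=round(rng.uniform(0, 600), 2),
            )
        )
    if not any(n.node_type == "gene_protein" for n in nodes):
        nodes[0] = replace(nodes[0], node_type="gene_protein", uniprot_accessions=("P40000",), gene_names=("GN0",))
    for g in range(n_groups):
        members = rng.sample([n.node_id for n in nodes[:n_nodes]], min(3, n_nodes))
        nodes.append(SkeletonNode(node_id=f"grp{g}", node_type="group", members=tuple(members)))

    subtype_pool = sorted(set(KGML_RELATION_SUBTYPES.values()))
    edges: list[SkeletonEdge] = []
    for k in range(n_edges):
        src = f"n{rng.randrange(n_nodes)}"
        if edge_on_edge and edges and rng.random() < 0.3:
            target = rng.choice(edges).edge_id
        else:
            target = f"n{rng.randrange(n_nodes)}"
            if target == src:
                target = f"n{(int(target[1:]) + 1) % n_nodes}"
        types = frozenset(rng.sample(subtype_pool, rng.choice([1, 1, 2])))
        edges.append(SkeletonEdge(edge_id=f"e{k}", source=src, target=target, relation_types=types))
    return PathwaySkeleton(
        pathway_id=f"rand{seed}", name=f"random skeleton {seed}", organism="syn",
        source_db="custom", nodes=nodes, edges=edges,
    )


# ---------------------------------------------------------------------------
# Kinase-substrate tables, datasets, signatures, PSSMs


def make_kinase_substrate_table(
    seed: int = 0, n_kinases: int = 5, substrates_per_kinase: int = 10
) -> KinaseSubstrateTable:
    """Kinases KIN1..KINn with disjoint synthetic substrate gene sets."""
    rng = random.Random(seed)
    rows = []
    for k in range(1, n_kinases + 1):
        for j in range(substrates_per_kinase):
            rows.append(
                KinaseSubstrateRow(
                    kinase=f"KIN{k}",
                    substrate=f"SUB{k}_{j}",
                    residue=rng.choice("STY"),
                    position=rng.randrange(10, 1500),
                )
            )
    return KinaseSubstrateTable(rows)


def make_synthetic_dataset(
    spec: SyntheticSpec,
    skeleton: PathwaySkeleton | None = None,
    ks_table: KinaseSubstrateTable | None = None,
    experiment: str = "synthetic",
) -> tuple[list[PTMRecord], dict]:
    """PTM dataset with a planted kinase-inhibition signal.

    Substrates of ``spec.planted_kinase`` (from ``ks_table``) receive fold
    changes ``effect_shift + N(0, noise_sd)``; all other peptides are null
    ``N(0, noise_sd)``.  Regulation labels derive from the global fold-change
    quantiles given ``fraction_up``/``fraction_down``.  If a skeleton is
    given, null peptides cycle through its gene names so they project.  In
    potency mode, regulated peptides get pEC50 values spaced evenly across
    ``potency_band`` (band endpoints included exactly).
    """
    ks_table = ks_table or make_kinase_substrate_table(spec.seed)
    planted_rows = ks_table.substrates_of(spec.planted_kinase)
    if not planted_rows:
        raise ValueError(f"planted kinase {spec.planted_kinase!r} absent from the table")
    rng = np.random.default_rng(spec.seed)
    py_rng = random.Random(spec.seed + 1)

    skeleton_genes = [
        g for n in (skeleton.nodes if skeleton else []) for g in n.gene_names
    ]

    rows: list[dict] = []
    for row in planted_rows:
        rows.append(
            {
                "gene": row.substrate,
                "residue": row.residue,
                "position": row.position,
                "fc": spec.effect_shift + rng.normal(0.0, spec.noise_sd),
                "planted": True,
            }
        )
    n_null = max(spec.n_peptides - len(rows), 0)
    for i in range(n_null):
        if skeleton_genes and i < len(skeleton_genes) * 3:
            gene = skeleton_genes[i % len(skeleton_genes)]
        else:
            gene = f"NUL{i}"
        rows.append(
            {
                "gene": gene,
                "residue": py_rng.choice("STY"),
                "position": py_rng.randrange(10, 1500),
                "fc": float(rng.normal(0.0, spec.noise_sd)),
                "planted": False,
            }
        )

    n = len(rows)
    n_up = int(round(spec.fraction_up * n))
    n_down = int(round(spec.fraction_down * n))
    order = sorted(range(n), key=lambda i: -rows[i]["fc"])
    regulation = ["not"] * n
    for i in order[:n_up]:
        regulation[i] = "up"
    for i in order[n - n_down :]:
        regulation[i] = "down"

    regulated_idx = [i for i in range(n) if regulation[i] != "not"]
    pec50 = {}
    if spec.potency_band is not None and regulated_idx:
        low, high = spec.potency_band
        values = np.linspace(low, high, len(regulated_idx)) if len(regulated_idx) > 1 else [low]
        for i, v in zip(regulated_idx, values):
            pec50[i] = float(v)

    records = []
    for i, row in enumerate(rows):
        records.append(
            PTMRecord(
                experiment=experiment,
                peptide_key=f"{row['gene']}_{row['residue']}{row['position']}",
                regulation=regulation[i],
                gene_names=(row["gene"],),
                residue=row["residue"],
                position=row["position"],
                fold_change=round(float(row["fc"]), 6),
                pec50=pec50.get(i),
            )
        )
    truth = {
        "planted_kinase": spec.planted_kinase,
        "planted_peptides": [i for i, row in enumerate(rows) if row["planted"]],
    }
    return records, truth


def dataset_profile(records) -> list[tuple[str, float]]:
    """(site_key, fold change) pairs for KSEA / set enrichment input."""
    profile = []
    for r in records:
        if r.fold_change is None or not r.sites:
            continue
        name = r.gene_names[0] if r.gene_names else (r.uniprot_accessions[0] if r.uniprot_accessions else r.peptide_key)
        res, pos = r.sites[0]
        profile.append((site_key(name, res, pos), r.fold_change))
    return profile


def make_signature_db(
    seed: int, keys: list[str], n_signatures: int = 20, size: int = 10
) -> list[Signature]:
    """Random unsigned signatures drawn from a key universe."""
    rng = random.Random(seed)
    return [
        Signature.from_keys(f"SIG{i}", rng.sample(keys, min(size, len(keys))))
        for i in range(n_signatures)
    ]


def make_pssms(seed: int = 0, n_kinases: int = 6, positions: range = range(-5, 5)) -> list[PSSM]:
    """Per-kinase PSSMs with one strongly preferred residue per position
    (phospho-acceptor position fixed to S/T preference)."""
    rng = random.Random(seed)
    pssms = []
    for k in range(1, n_kinases + 1):
        weights: dict[int, dict[str, float]] = {}
        for pos in positions:
            preferred = "S" if pos == 0 else rng.choice(AMINO_ACIDS)
            row = {aa: 1.0 for aa in AMINO_ACIDS}
            row[preferred] = 12.0
            row[rng.choice(AMINO_ACIDS.replace(preferred, ""))] = 3.0
            weights[pos] = row
        pssms.append(PSSM(f"KIN{k}", weights))
    return pssms


def sample_peptide(pssm: PSSM, rng: random.Random) -> str:
    """Sample a flanking sequence from a PSSM's positional preferences."""
    seq = []
    for pos in pssm.positions:
        row = pssm.weights[pos]
        aas = sorted(row)
        total = sum(row[a] for a in aas)
        r = rng.random() * total
        acc = 0.0
        pick = aas[-1]
        for aa in aas:
            acc += row[aa]
            if r <= acc:
                pick = aa
                break
        seq.append(pick)
    return "".join(seq)


def random_peptide(window: int, rng: random.Random) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(window))


def make_background(pssms, n: int = 400, seed: int = 0) -> dict[str, np.ndarray]:
    """Background score distributions: n random peptides scored per kinase."""
    rng = random.Random(seed)
    window = pssms[0].window
    peptides = [random_peptide(window, rng) for _ in range(n)]
    return {pssm.kinase: np.array([pssm.score(p) for p in peptides]) for pssm in pssms}


def make_motif_dataset(
    seed: int,
    pssms,
    planted_kinase: str,
    n_peptides: int = 200,
    n_up: int = 40,
    n_planted: int = 30,
    n_down: int = 20,
) -> list[tuple[str, str]]:
    """Motif dataset where most up-regulated peptides carry the planted
    kinase's motif and everything else is random."""
    rng = random.Random(seed)
    planted = next(p for p in pssms if p.kinase == planted_kinase)
    window = planted.window
    peptides = []
    for i in range(n_up):
        seq = sample_peptide(planted, rng) if i < n_planted else random_peptide(window, rng)
        peptides.append((seq, "up"))
    for _ in range(n_down):
        peptides.append((random_peptide(window, rng), "down"))
    while len(peptides) < n_peptides:
        peptides.append((random_peptide(window, rng), "not"))
    rng.shuffle(peptides)
    return peptides
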