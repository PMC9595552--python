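"""KEGG KGML pathway model: parse, manipulate, expand and write pathway maps.

KEGG pathway maps collapse functionally homologous genes — alternative enzymes
catalyzing the same reaction — into a single node whose KGML ``name`` attribute
lists every gene. :func:`expand_nodes` materialises one child node per gene so
that per-gene expression and localization layers can be displayed, and
:func:`layout_expanded` stacks the children vertically under the parent's
graphics box. Expanded children are written back to KGML as ordinary ``entry``
elements carrying a ``funhop_parent`` attribute (standard KGML has no nesting),
which keeps the output loadable by generic KGML consumers and makes
read-after-write lossless.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from lxml import etree

log = logging.getLogger(__name__)

KNOWN_ENTRY_TYPES = {"gene", "compound", "map", "group", "ortholog", "enzyme", "other"}

#: KGML attributes handled explicitly; anything else is preserved verbatim.
_ENTRY_ATTRS = {"id", "name", "type", "link"}
_GRAPHICS_ATTRS = {"name", "x", "y", "width", "height", "type", "fgcolor", "bgcolor"}
_REACTION_ATTRS = {"id", "name", "type"}
_RELATION_ATTRS = {"entry1", "entry2", "type"}
_PATHWAY_ATTRS = {"name", "org", "number", "title", "image", "link"}

PARENT_ATTR = "funhop_parent"


@dataclass
class Graphics:
    """Graphics block of a KGML entry (pixel coordinates of the map image)."""

    name: str | None = None
    x: float | None = None
    y: float | None = None
    width: float | None = None
    height: float | None = None
    gtype: str | None = None
    fgcolor: str | None = None
    bgcolor: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class Entry:
    """One KGML entry: a gene node, compound, map link or group.

    ``gene_ids`` holds the whitespace-split ``name`` attribute for gene
    entries (KEGG identifiers such as ``hsa:50``). After expansion a
    multi-gene entry carries one single-gene child per gene in
    ``expanded_children``; the parent keeps its full gene list.
    """

    entry_id: str
    entry_type: str
    gene_ids: list[str] = field(default_factory=list)
    link: str | None = None
    graphics: Graphics | None = None
    components: list[str] = field(default_factory=list)
    expanded_children: list["Entry"] = field(default_factory=list)
    parent_id: str | None = None
    extra: dict = field(default_factory=dict)
    # per-gene annotation layer (symbol, DE score, color, localization)
    attrs: dict = field(default_factory=dict)

    @property
    def display_label(self) -> str:
        if self.graphics is not None and self.graphics.name:
            return self.graphics.name.split(",")[0].strip().rstrip(".")
        return self.gene_ids[0] if self.gene_ids else self.entry_id

    @property
    def is_gene(self) -> bool:
        return self.entry_type in ("gene", "ortholog")

    @property
    def is_expanded(self) -> bool:
        return bool(self.expanded_children)


@dataclass
class Reaction:
    """A KGML reaction: substrates -> products, catalyzed by a gene entry."""

    reaction_id: str
    entry_id: str
    substrates: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    reversible: bool = False
    extra: dict = field(default_factory=dict)


@dataclass
class Relation:
    entry1: str
    entry2: str
    relation_type: str
    subtypes: list[tuple[str, str]] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


@dataclass
class PathwayGraph:
    """In-memory KGML pathway: entries plus the reactions/relations wiring."""

    pathway_id: str
    title: str = ""
    entries: dict[str, Entry] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def gene_entries(self) -> list[Entry]:
        return [e for e in self.entries.values() if e.is_gene]

    def gene_nodes(self):
        """Yield ``(entry, node, gene_id)`` for every displayable gene row.

        ``node`` is the expanded child when the entry is expanded, otherwise
        the entry itself; downstream layers (DE overlay, splitting) operate on
        these rows uniformly.
        """
        for entry in self.gene_entries():
            if entry.is_expanded:
                for child in entry.expanded_children:
                    yield entry, child, child.gene_ids[0]
            else:
                for gid in entry.gene_ids:
                    yield entry, entry, gid

    def all_gene_ids(self) -> list[str]:
        """Multiset of KEGG gene identifiers over all gene entries."""
        out: list[str] = []
        for e in self.gene_entries():
            out.extend(e.gene_ids)
        return out

    def validate(self) -> None:
        ids = set(self.entries)
        if len(ids) != len(self.entries):  # pragma: no cover - dict enforces
            raise ValueError("duplicate entry ids")
        for rel in self.relations:
            for end in (rel.entry1, rel.entry2):
                if end not in ids:
                    raise ValueError(
                        f"relation endpoint {end!r} not an entry of {self.pathway_id}"
                    )
        for rxn in self.reactions:
            if rxn.entry_id not in ids:
                raise ValueError(
                    f"reaction {rxn.reaction_id!r} catalyzed by missing entry "
                    f"{rxn.entry_id!r}"
                )
            if not rxn.substrates or not rxn.products:
                raise ValueError(f"reaction {rxn.reaction_id!r} lacks substrates/products")


# ---------------------------------------------------------------------------
# parsing


def _split_known(attrib: dict, known: set[str]) -> dict:
    return {k: v for k, v in attrib.items() if k not in known}


def _parse_graphics(el) -> Graphics:
    a = el.attrib

    def num(key):
        return float(a[key]) if key in a else None

    return Graphics(
        name=a.get("name"),
        x=num("x"),
        y=num("y"),
        width=num("width"),
        height=num("height"),
        gtype=a.get("type"),
        fgcolor=a.get("fgcolor"),
        bgcolor=a.get("bgcolor"),
        extra=_split_known(a, _GRAPHICS_ATTRS),
    )


def read_kgml(path: str | Path) -> PathwayGraph:
    """Parse a KGML pathway file.

    Unknown entry types are kept with a warning; previously expanded children
    (entries with a ``funhop_parent`` attribute) are re-attached to their
    parent so that expansion round-trips.

    Raises :class:`ValueError` naming the offending line on malformed XML.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed KGML in {path} (line {exc.lineno}): {exc.msg}") from exc
    root = tree.getroot()
    if root.tag != "pathway":
        raise ValueError(f"{path}: root element is <{root.tag}>, expected <pathway>")

    graph = PathwayGraph(
        pathway_id=root.get("name", "").removeprefix("path:") or path.stem,
        title=root.get("title", ""),
        extra=_split_known(root.attrib, _PATHWAY_ATTRS) | {
            k: root.attrib[k] for k in ("org", "number", "image", "link") if k in root.attrib
        },
    )
    deferred_children: list[Entry] = []
    for el in root.iter("entry"):
        a = el.attrib
        etype = a.get("type", "other")
        if etype not in KNOWN_ENTRY_TYPES:
            warnings.warn(f"unknown entry type {etype!r} kept verbatim", stacklevel=2)
        name = a.get("name", "")
        entry = Entry(
            entry_id=a["id"],
            entry_type=etype,
            gene_ids=name.split() if etype in ("gene", "ortholog") else [],
            link=a.get("link"),
            extra=_split_known(a, _ENTRY_ATTRS | {PARENT_ATTR}),
            parent_id=a.get(PARENT_ATTR),
        )
        if not entry.gene_ids and etype not in ("gene", "ortholog") and name:
            entry.extra.setdefault("name", name)
        g = el.find("graphics")
        if g is not None:
            entry.graphics = _parse_graphics(g)
        for comp in el.iter("component"):
            entry.components.append(comp.get("id"))
        if entry.parent_id is not None:
            deferred_children.append(entry)
        else:
            if entry.entry_id in graph.entries:
                raise ValueError(f"duplicate entry id {entry.entry_id!r} in {path}")
            graph.entries[entry.entry_id] = entry
    for child in deferred_children:
        parent = graph.entries.get(child.parent_id)
        if parent is None:
            warnings.warn(
                f"expanded child {child.entry_id} references missing parent "
                f"{child.parent_id}; kept as top-level entry",
                stacklevel=2,
            )
            child.parent_id = None
            graph.entries[child.entry_id] = child
        else:
            parent.expanded_children.append(child)

    for el in root.iter("reaction"):
        a = el.attrib
        graph.reactions.append(
            Reaction(
                reaction_id=a.get("name", a.get("id", "")),
                entry_id=a.get("id", ""),
                substrates=[s.get("id") for s in el.iter("substrate")],
                products=[p.get("id") for p in el.iter("product")],
                reversible=a.get("type") == "reversible",
                extra=_split_known(a, _REACTION_ATTRS),
            )
        )
    for el in root.iter("relation"):
        a = el.attrib
        graph.relations.append(
            Relation(
                entry1=a["entry1"],
                entry2=a["entry2"],
                relation_type=a.get("type", ""),
                subtypes=[(s.get("name"), s.get("value")) for s in el.iter("subtype")],
                extra=_split_known(a, _RELATION_ATTRS),
            )
        )
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# writing


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


def _graphics_el(parent_el, g: Graphics) -> None:
    el = etree.SubElement(parent_el, "graphics")
    if g.name is not None:
        el.set("name", g.name)
    if g.fgcolor is not None:
        el.set("fgcolor", g.fgcolor)
    if g.bgcolor is not None:
        el.set("bgcolor", g.bgcolor)
    if g.gtype is not None:
        el.set("type", g.gtype)
    for key, val in (("x", g.x), ("y", g.y), ("width", g.width), ("height", g.height)):
        if val is not None:
            el.set(key, _fmt(val))
    for k, v in g.extra.items():
        el.set(k, v)


def _entry_el(root, entry: Entry) -> None:
    el = etree.SubElement(root, "entry")
    el.set("id", entry.entry_id)
    name = " ".join(entry.gene_ids) if entry.gene_ids else entry.extra.get("name", "undefined")
    el.set("name", name)
    el.set("type", entry.entry_type)
    if entry.link is not None:
        el.set("link", entry.link)
    if entry.parent_id is not None:
        el.set(PARENT_ATTR, entry.parent_id)
    for k, v in entry.extra.items():
        if k != "name":
            el.set(k, v)
    if entry.graphics is not None:
        _graphics_el(el, entry.graphics)
    for comp in entry.components:
        etree.SubElement(el, "component").set("id", comp)


def write_kgml(graph: PathwayGraph, path: str | Path) -> None:
    """Serialise a pathway back to KGML.

    ``read_kgml(write_kgml(g))`` is structurally identical to ``g``: entry
    ids, gene lists, graphics, reactions, relations and expanded children all
    survive the round trip. Unknown attributes captured at parse time are
    emitted verbatim.
    """
    graph.validate()
    root = etree.Element("pathway")
    pid = graph.pathway_id
    root.set("name", pid if pid.startswith("path:") else f"path:{pid}")
    if "org" in graph.extra:
        root.set("org", graph.extra["org"])
    if "number" in graph.extra:
        root.set("number", graph.extra["number"])
    root.set("title", graph.title)
    for k, v in graph.extra.items():
        if k not in ("org", "number"):
            root.set(k, v)
    for entry in graph.entries.values():
        _entry_el(root, entry)
        for child in entry.expanded_children:
            _entry_el(root, child)
    for rel in graph.relations:
        el = etree.SubElement(root, "relation")
        el.set("entry1", rel.entry1)
        el.set("entry2", rel.entry2)
        el.set("type", rel.relation_type)
        for k, v in rel.extra.items():
            el.set(k, v)
        for name, value in rel.subtypes:
            sub = etree.SubElement(el, "subtype")
            sub.set("name", name)
            sub.set("value", value)
    for rxn in graph.reactions:
        el = etree.SubElement(root, "reaction")
        el.set("id", rxn.entry_id)
        el.set("name", rxn.reaction_id)
        el.set("type", "reversible" if rxn.reversible else "irreversible")
        for k, v in rxn.extra.items():
            el.set(k, v)
        for sid in rxn.substrates:
            etree.SubElement(el, "substrate").set("id", sid)
        for pid_ in rxn.products:
            etree.SubElement(el, "product").set("id", pid_)
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# expansion


def flatten_groups(graph: PathwayGraph) -> PathwayGraph:
    """Dissolve KGML group entries into their member entries (in place).

    Relations touching a group are re-targeted to each member; the group entry
    itself is removed. Members already exist as ordinary entries in KGML, so
    no entry content is lost.
    """
    groups = [e for e in graph.entries.values() if e.entry_type == "group"]
    for grp in groups:
        members = [m for m in grp.components if m in graph.entries]
        new_relations: list[Relation] = []
        for rel in graph.relations:
            touched = {rel.entry1, rel.entry2} & {grp.entry_id}
            if not touched:
                new_relations.append(rel)
                continue
            for m in members:
                clone = copy.deepcopy(rel)
                if clone.entry1 == grp.entry_id:
                    clone.entry1 = m
                if clone.entry2 == grp.entry_id:
                    clone.entry2 = m
                new_relations.append(clone)
        graph.relations = new_relations
        graph.reactions = [r for r in graph.reactions if r.entry_id != grp.entry_id]
        del graph.entries[grp.entry_id]
    return graph


def expand_nodes(graph: PathwayGraph) -> PathwayGraph:
    """Expand every multi-gene entry into one single-gene child per gene.

    Children get synthetic ids ``<parentid>_<n>`` and inherit the parent's
    graphics and connectivity (the parent entry, which carries the reactions
    and relations, remains in the graph). Single-gene entries are untouched
    and the operation is idempotent. Returns a new graph.
    """
    out = copy.deepcopy(graph)
    flatten_groups(out)
    n_expanded = 0
    for entry in out.gene_entries():
        if entry.is_expanded or len(entry.gene_ids) <= 1:
            continue
        for i, gid in enumerate(entry.gene_ids, start=1):
            child = Entry(
                entry_id=f"{entry.entry_id}_{i}",
                entry_type=entry.entry_type,
                gene_ids=[gid],
                link=entry.link,
                parent_id=entry.entry_id,
                graphics=copy.deepcopy(entry.graphics),
            )
            if child.graphics is not None:
                child.graphics.name = gid
            entry.expanded_children.append(child)
        n_expanded += 1
    log.info("expanded %d multi-gene entries in %s", n_expanded, graph.pathway_id)
    return out


def layout_expanded(graph: PathwayGraph) -> PathwayGraph:
    """Stack each entry's expanded children vertically from the parent box.

    Child *i* (0-based) keeps the parent's x, width and height and is placed
    at ``y = parent.y + i * height``, giving non-overlapping boxes within a
    stack. Deterministic given child order. Returns a new graph.
    """
    out = copy.deepcopy(graph)
    for entry in out.gene_entries():
        g = entry.graphics
        if g is None or not entry.is_expanded:
            continue
        for i, child in enumerate(entry.expanded_children):
            if child.graphics is None:
                child.graphics = copy.deepcopy(g)
            child.graphics.x = g.x
            child.graphics.y = (g.y or 0) + i * (g.height or 17)
            child.graphics.width = g.width
            child.graphics.height = g.height
    return out


# ---------------------------------------------------------------------------
# graph views & Cytoscape-oriented exports


def to_networkx(graph: PathwayGraph) -> nx.Graph:
    """Undirected entry-level view of the reaction+relation wiring.

    Nodes are entry ids; edges link relation endpoints and each reaction's
    catalyzing entry to its substrate and product compounds. This is the view
    used for connected-component diagnostics.
    """
    g = nx.Graph()
    for eid, entry in graph.entries.items():
        g.add_node(eid, entry_type=entry.entry_type, label=entry.display_label)
    for rel in graph.relations:
        g.add_edge(rel.entry1, rel.entry2, kind="relation", relation_type=rel.relation_type)
    for rxn in graph.reactions:
        for cid in rxn.substrates + rxn.products:
            if cid in graph.entries:
                g.add_edge(rxn.entry_id, cid, kind="reaction", reaction=rxn.reaction_id)
    return g


def write_graphml(graph: PathwayGraph, path: str | Path) -> None:
    """Export the pathway (expanded children included) as GraphML.

    Expanded children appear as their own nodes connected to the parent's
    neighbours, so Cytoscape shows per-gene connectivity.
    """
    g = nx.Graph()
    for entry in graph.entries.values():
        nodes = entry.expanded_children if entry.is_expanded else [entry]
        for node in nodes:
            g.add_node(
                node.entry_id,
                entry_type=node.entry_type,
                label=node.attrs.get("symbol", node.display_label),
                genes=" ".join(node.gene_ids),
                **{
                    k: v
                    for k, v in node.attrs.items()
                    if isinstance(v, (str, int, float)) and k != "symbol"
                },
            )

    def endpoints(eid: str) -> list[str]:
        entry = graph.entries.get(eid)
        if entry is None:
            return []
        return [c.entry_id for c in entry.expanded_children] or [eid]

    for rel in graph.relations:
        for a in endpoints(rel.entry1):
            for b in endpoints(rel.entry2):
                g.add_edge(a, b, kind="relation")
    for rxn in graph.reactions:
        for a in endpoints(rxn.entry_id):
            for cid in rxn.substrates + rxn.products:
                if cid in graph.entries:
                    g.add_edge(a, cid, kind="reaction", reaction=rxn.reaction_id)
    nx.write_graphml(g, str(path))


def node_attribute_table(graph: PathwayGraph, path: str | Path | None = None):
    """Per-gene-row attribute table for Cytoscape import.

    Columns: node id, KEGG gene id, gene symbol, localization, DE score and
    color. Returns a :class:`pandas.DataFrame`; writes TSV when ``path``
    given.
    """
    import pandas as pd

    rows = []
    for _entry, node, gid in graph.gene_nodes():
        rows.append(
            {
                "node_id": node.entry_id,
                "kegg_id": gid,
                "symbol": node.attrs.get("symbol", ""),
                "localization": node.attrs.get("localization", ""),
                "score": node.attrs.get("score", ""),
                "color": node.attrs.get("color", ""),
            }
        )
    df = pd.DataFrame(rows, columns=["node_id", "kegg_id", "symbol", "localization", "score", "color"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
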