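"""Split expanded pathways into mitochondrial and non-mitochondrial variants.

Given a per-gene consensus compartment, every gene row of an expanded pathway
is routed to the mitochondrial variant (consensus = mitochondria) or to the
non-mitochondrial variant (any other known compartment: cytoplasm, nucleus or
secretory, pooled to mirror the binary mitochondrial/non-mitochondrial view).
Entries emptied of all their genes are removed together with their incident
relations; reactions whose catalyzing entry vanished are flagged as broken
links — the visual "holes" a compartment-restricted pathway may develop.
Compounds and map links are retained in both variants.

Genes whose consensus is unknown are, by default, kept in *both* variants and
flagged, so that missing localization data never silently breaks a path; pass
``unknown_policy="drop"`` to exclude them instead.
"""

from __future__ import annotations

import copy
import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .kgml import Entry, PathwayGraph, to_networkx
from .localization import MITOCHONDRIA, UNKNOWN, usable

log = logging.getLogger(__name__)


def _category_lookup(consensus) -> dict[str, str]:
    if isinstance(consensus, pd.DataFrame):
        return dict(consensus["consensus"])
    return dict(consensus)


def gene_category(gid: str, categories: dict[str, str], idmap: dict[str, str]) -> str:
    """Consensus compartment of one KEGG gene id (unknown when unmapped)."""
    symbol = idmap.get(gid)
    if symbol is None:
        return UNKNOWN
    cat = categories.get(symbol, UNKNOWN)
    return cat if usable(cat) else UNKNOWN


def annotate_localization(
    graph: PathwayGraph, consensus, idmap: dict[str, str]
) -> PathwayGraph:
    """Record each gene node's consensus compartment in its attribute layer."""
    categories = _category_lookup(consensus)
    for _entry, node, gid in graph.gene_nodes():
        node.attrs["localization"] = gene_category(gid, categories, idmap)
    return graph


@dataclass
class SplitResult:
    """Outcome of a mitochondrial/non-mitochondrial pathway split."""

    original: PathwayGraph
    mito_variant: PathwayGraph
    nonmito_variant: PathwayGraph
    #: per variant: list of (gene id, reason) removed from that variant
    removed_genes: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    #: per variant: entry ids deleted because no gene remained
    orphaned_entries: dict[str, list[str]] = field(default_factory=dict)
    #: per variant: reaction ids removed because their catalyzing entry vanished
    broken_links: dict[str, list[str]] = field(default_factory=dict)
    #: connected-component count of original and each variant
    component_counts: dict[str, int] = field(default_factory=dict)


def _restrict(graph: PathwayGraph, keep: set[str], variant: str,
              result: SplitResult) -> PathwayGraph:
    """Variant of ``graph`` keeping only gene rows whose category is wanted."""
    out = copy.deepcopy(graph)
    removed: list[tuple[str, str]] = []
    orphaned: list[str] = []
    for entry in list(out.gene_entries()):
        if entry.is_expanded:
            kept_children = []
            for child in entry.expanded_children:
                gid = child.gene_ids[0]
                if gid in keep:
                    kept_children.append(child)
                else:
                    removed.append((gid, "other compartment"))
            entry.expanded_children = kept_children
            entry.gene_ids = [c.gene_ids[0] for c in kept_children]
        else:
            kept_ids = [g for g in entry.gene_ids if g in keep]
            removed.extend((g, "other compartment") for g in entry.gene_ids if g not in keep)
            entry.gene_ids = kept_ids
        if not entry.gene_ids:
            orphaned.append(entry.entry_id)
            del out.entries[entry.entry_id]
    out.relations = [
        r for r in out.relations
        if r.entry1 in out.entries and r.entry2 in out.entries
    ]
    broken = [r.reaction_id for r in out.reactions if r.entry_id not in out.entries]
    out.reactions = [r for r in out.reactions if r.entry_id in out.entries]
    result.removed_genes[variant] = removed
    result.orphaned_entries[variant] = orphaned
    result.broken_links[variant] = broken
    return out


def split_pathway(
    graph: PathwayGraph,
    consensus,
    idmap: dict[str, str],
    unknown_policy: str = "both",
) -> SplitResult:
    """Split an expanded pathway by consensus compartment.

    ``consensus`` is a consensus DataFrame (indexed by gene symbol, with a
    ``consensus`` column) or a plain ``symbol -> category`` mapping; ``idmap``
    translates KEGG gene ids to symbols. ``unknown_policy`` is ``"both"``
    (default: unknown-localization genes appear, flagged, in both variants)
    or ``"drop"``.
    """
    categories = _category_lookup(consensus)
    if not categories:
        raise ValueError("consensus table is empty")
    if unknown_policy not in ("both", "drop"):
        raise ValueError(f"unknown_policy must be 'both' or 'drop', got {unknown_policy!r}")

    annotate_localization(graph, categories, idmap)
    mito_keep: set[str] = set()
    nonmito_keep: set[str] = set()
    n_gaps = 0
    for _entry, _node, gid in graph.gene_nodes():
        cat = gene_category(gid, categories, idmap)
        if cat == MITOCHONDRIA:
            mito_keep.add(gid)
        elif usable(cat):
            nonmito_keep.add(gid)
        else:
            n_gaps += 1
            if unknown_policy == "both":
                mito_keep.add(gid)
                nonmito_keep.add(gid)
    if n_gaps:
        log.warning("split_pathway: %d gene rows without known consensus (%s policy)",
                    n_gaps, unknown_policy)

    result = SplitResult(original=graph, mito_variant=None, nonmito_variant=None)  # type: ignore[arg-type]
    result.mito_variant = _restrict(graph, mito_keep, "mito", result)
    result.nonmito_variant = _restrict(graph, nonmito_keep, "nonmito", result)
    for variant in ("mito", "nonmito"):
        result.removed_genes[variant] = [
            (g, "unknown localization dropped" if gene_category(g, categories, idmap) == UNKNOWN
             else reason)
            for g, reason in result.removed_genes[variant]
        ]
    result.mito_variant.pathway_id = f"{graph.pathway_id}.mito"
    result.nonmito_variant.pathway_id = f"{graph.pathway_id}.nonmito"
    result.component_counts = {
        "original": nx.number_connected_components(to_networkx(graph)),
        "mito": nx.number_connected_components(to_networkx(result.mito_variant)),
        "nonmito": nx.number_connected_components(to_networkx(result.nonmito_variant)),
    }
    return result


def connectivity_report(result: SplitResult) -> pd.DataFrame:
    """Connectivity diagnostics for a split.

    One row per graph (original, mito, nonmito) with the weakly-connected
    component count of the undirected reaction+relation view, plus the number
    of compound pairs that were connected in the original but fall apart in
    that variant — the broken-path signature.
    """
    graphs = {
        "original": result.original,
        "mito": result.mito_variant,
        "nonmito": result.nonmito_variant,
    }
    orig_nx = to_networkx(result.original)
    compounds = [e.entry_id for e in result.original.entries.values()
                 if e.entry_type == "compound"]
    orig_connected = {
        frozenset((a, b))
        for a, b in itertools.combinations(compounds, 2)
        if nx.has_path(orig_nx, a, b)
    }
    rows = []
    for name, graph in graphs.items():
        g = to_networkx(graph)
        broken_pairs = [
            tuple(sorted(pair))
            for pair in orig_connected
            if not (all(n in g for n in pair) and nx.has_path(g, *pair))
        ]
        rows.append(
            {
                "graph": name,
                "n_entries": len(graph.entries),
                "n_components": nx.number_connected_components(g) if len(g) else 0,
                "n_disconnected_compound_pairs": len(broken_pairs),
                "disconnected_compound_pairs": ";".join(
                    f"{a}-{b}" for a, b in sorted(broken_pairs)
                ),
            }
        )
    return pd.DataFrame(rows)


def _round_pct(x: float) -> int:
    # round half to even, so complementary percentages stay complementary
    # (47.5/52.5 -> 48/52) and the rounded pair sums to 100 at .5 ties
    return int(round(x))


@dataclass
class CompartmentFractions:
    """Mitochondrial vs non-mitochondrial share of a pathway's genes."""

    pathway_id: str
    n_mito: int
    n_nonmito: int
    n_unknown: int
    by_category: dict[str, int] = field(default_factory=dict)

    @property
    def n_known(self) -> int:
        return self.n_mito + self.n_nonmito

    @property
    def pct_mito(self) -> int:
        return _round_pct(100.0 * self.n_mito / self.n_known) if self.n_known else 0

    @property
    def pct_nonmito(self) -> int:
        return _round_pct(100.0 * self.n_nonmito / self.n_known) if self.n_known else 0


def compartment_fractions(
    graph: PathwayGraph, consensus, idmap: dict[str, str]
) -> CompartmentFractions:
    """Count unique pathway genes by compartment and report the mito split.

    Percentages use only genes with a known consensus as denominator and are
    rounded half to even; unknown-localization genes are reported
    separately. ``by_category`` keeps the per-compartment breakdown of the
    pooled non-mitochondrial count as a diagnostic.
    """
    categories = _category_lookup(consensus)
    genes = sorted(set(graph.all_gene_ids()))
    n_mito = n_nonmito = n_unknown = 0
    by_cat: dict[str, int] = {}
    for gid in genes:
        cat = gene_category(gid, categories, idmap)
        by_cat[cat] = by_cat.get(cat, 0) + 1
        if cat == MITOCHONDRIA:
            n_mito += 1
        elif usable(cat):
            n_nonmito += 1
        else:
            n_unknown += 1
    return CompartmentFractions(graph.pathway_id, n_mito, n_nonmito, n_unknown, by_cat)


def merge_variants(result: SplitResult) -> PathwayGraph:
    """Union of the two variants' entries (for consistency checks).

    With ``unknown_policy="drop"`` this reproduces the original expanded
    pathway minus the unknown-localization genes.
    """
    merged = copy.deepcopy(result.mito_variant)
    merged.pathway_id = result.original.pathway_id
    for eid, entry in result.nonmito_variant.entries.items():
        if eid not in merged.entries:
            merged.entries[eid] = copy.deepcopy(entry)
        else:
            mine = merged.entries[eid]
            if mine.is_expanded or entry.is_expanded:
                have = {c.entry_id for c in mine.expanded_children}
                for child in entry.expanded_children:
                    if child.entry_id not in have:
                        mine.expanded_children.append(copy.deepcopy(child))
                mine.expanded_children.sort(
                    key=lambda c: int(c.entry_id.rsplit("_", 1)[1])
                )
                mine.gene_ids = [c.gene_ids[0] for c in mine.expanded_children]
            else:
                for g in entry.gene_ids:
                    if g not in mine.gene_ids:
                        mine.gene_ids.append(g)
    seen_rel = {(r.entry1, r.entry2, r.relation_type) for r in merged.relations}
    for rel in result.nonmito_variant.relations:
        if (rel.entry1, rel.entry2, rel.relation_type) not in seen_rel:
            merged.relations.append(copy.deepcopy(rel))
    seen_rxn = {(r.reaction_id, r.entry_id) for r in merged.reactions}
    for rxn in result.nonmito_variant.reactions:
        if (rxn.reaction_id, rxn.entry_id) not in seen_rxn:
            merged.reactions.append(copy.deepcopy(rxn))
    return merged
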