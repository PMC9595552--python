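"""Dataset- and pathway-level summaries.

Three views of the combined localization + expression data:

* per-compartment counts of significantly up- and downregulated genes (the
  bar-chart view showing, e.g., mitochondrial enrichment of upregulation);
* per-source dataset statistics (size, mitochondrial share, overlap with the
  KEGG metabolic gene universe);
* a ranking of pathways by their mitochondrial gene fraction, used to pick
  pathways worth a compartment-split analysis.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

from .kgml import PathwayGraph
from .localization import CATEGORIES, MITOCHONDRIA, UNKNOWN, usable
from .split import compartment_fractions

log = logging.getLogger(__name__)

_COMPARTMENT_ORDER = list(CATEGORIES) + [UNKNOWN]


def regulation_by_compartment(
    de_filtered: pd.DataFrame, categories: dict[str, str]
) -> pd.DataFrame:
    """Count up/down regulated significant genes per compartment.

    ``de_filtered`` must already be filtered at the significance threshold;
    each gene is counted once, in its localization compartment (or
    ``unknown`` when it has none), split by regulation sign.
    """
    counts = {c: {"n_up": 0, "n_down": 0} for c in _COMPARTMENT_ORDER}
    for _, row in de_filtered.drop_duplicates("gene").iterrows():
        cat = categories.get(row["gene"], UNKNOWN)
        if not usable(cat):
            cat = UNKNOWN
        key = "n_up" if row["regulation"] > 0 else "n_down"
        counts[cat][key] += 1
    df = pd.DataFrame(
        [{"compartment": c, **counts[c]} for c in _COMPARTMENT_ORDER]
    ).set_index("compartment")
    return df


def source_summary(
    sources: dict[str, dict[str, str]], kegg_genes: list[str] | set[str]
) -> pd.DataFrame:
    """Per-source dataset statistics against a KEGG gene universe.

    Genes without a usable localization (unknown/uncertain) are excluded
    from all counts. ``pct_kegg`` is the share of the KEGG universe covered
    by the source; ``pct_mito`` and ``pct_kegg_mito`` are mitochondrial
    shares of the source and of its KEGG overlap respectively. Percentages
    are reported to one decimal.
    """
    kegg = set(kegg_genes)
    if not kegg:
        raise ValueError("KEGG gene list is empty")
    rows = []
    for name, cats in sources.items():
        known = {g: c for g, c in cats.items() if usable(c)}
        n_genes = len(known)
        n_mito = sum(1 for c in known.values() if c == MITOCHONDRIA)
        in_kegg = {g: c for g, c in known.items() if g in kegg}
        n_kegg = len(in_kegg)
        n_kegg_mito = sum(1 for c in in_kegg.values() if c == MITOCHONDRIA)
        rows.append(
            {
                "source": name,
                "n_genes": n_genes,
                "n_mito": n_mito,
                "pct_mito": round(100.0 * n_mito / n_genes, 1) if n_genes else 0.0,
                "n_kegg": n_kegg,
                "pct_kegg": round(100.0 * n_kegg / len(kegg), 1),
                "n_kegg_mito": n_kegg_mito,
                "pct_kegg_mito": round(100.0 * n_kegg_mito / n_kegg, 1) if n_kegg else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("source")


def rank_pathways(
    pathways: list[PathwayGraph], consensus, idmap: dict[str, str]
) -> pd.DataFrame:
    """Rank expanded pathways by mitochondrial gene fraction.

    Sorted descending by fraction, ties broken by total gene count
    descending then pathway id; pathways with no known-localization gene are
    excluded with a warning. Fractions come from
    :func:`funhop.split.compartment_fractions`, so the two views always
    agree.
    """
    rows = []
    for graph in pathways:
        frac = compartment_fractions(graph, consensus, idmap)
        if frac.n_known == 0:
            warnings.warn(
                f"pathway {graph.pathway_id} has no known-localization genes; excluded",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "pathway_id": graph.pathway_id,
                "title": graph.title,
                "n_genes": frac.n_known + frac.n_unknown,
                "n_known": frac.n_known,
                "n_mito": frac.n_mito,
                "mito_fraction": frac.n_mito / frac.n_known,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["pathway_id", "title", "n_genes", "n_known", "n_mito", "mito_fraction"],
    )
    df = df.sort_values(
        by=["mito_fraction", "n_genes", "pathway_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def fractions_table(
    pathways: list[PathwayGraph], consensus, idmap: dict[str, str]
) -> pd.DataFrame:
    """Mitochondrial/non-mitochondrial distribution table, one row per pathway."""
    rows = []
    for graph in pathways:
        f = compartment_fractions(graph, consensus, idmap)
        rows.append(
            {
                "pathway_id": f.pathway_id,
                "title": graph.title,
                "pct_mito": f.pct_mito,
                "n_mito": f.n_mito,
                "pct_nonmito": f.pct_nonmito,
                "n_nonmito": f.n_nonmito,
                "n_unknown": f.n_unknown,
            }
        )
    return pd.DataFrame(rows)


def plot_regulation_by_compartment(
    tables: dict[str, pd.DataFrame], path: str | Path
) -> None:
    """Bar-chart panels (one per localization source) of up/down counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(tables), figsize=(4 * len(tables), 3.2), squeeze=False)
    for ax, (name, table) in zip(axes[0], tables.items()):
        x = range(len(table.index))
        ax.bar([i - 0.2 for i in x], table["n_up"], width=0.4, label="up", color="#2166AC")
        ax.bar([i + 0.2 for i in x], table["n_down"], width=0.4, label="down", color="#E08214")
        ax.set_xticks(list(x))
        ax.set_xticklabels(table.index, rotation=45, ha="right", fontsize=8)
        ax.set_title(name)
    axes[0][0].set_ylabel("significant genes")
    axes[0][-1].legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pathway_ranking(ranking: pd.DataFrame, path: str | Path) -> None:
    """Scatter of mitochondrial fraction vs pathway size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ranking["n_genes"], ranking["mito_fraction"], s=18)
    ax.set_xlabel("genes in pathway")
    ax.set_ylabel("mitochondrial fraction")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
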