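"""Recompute published-scale statistics from user-downloaded inputs.

The original prostate-cancer study reported compartment distributions for
four KEGG pathways (TCA cycle hsa00020, glycolysis hsa00010, pyruvate
metabolism hsa00620 and alanine/aspartate/glutamate metabolism hsa00250), the
cytosol share among non-mitochondrial consensus calls, and cross-source
agreement statistics, all derivable from a per-gene individual-assignments
table plus the pathway KGML files. Neither input ships with this package:
KEGG licensing forbids redistribution and the assignment table is a journal
supplement. Users download them and point :func:`recompute_published_stats`
at the directory.

Expected layout (all plain text)::

    <dir>/localization_assignments.tsv   # gene, subcell, hpa, busca columns
    <dir>/hsa00020.xml  <dir>/hsa00010.xml  <dir>/hsa00620.xml  <dir>/hsa00250.xml
    <dir>/idmap.tsv                      # kegg_id <TAB> symbol

An ``.xlsx`` assignment table is accepted too (read via pandas/openpyxl).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .fixtures import read_idmap
from .kgml import expand_nodes, read_kgml
from .localization import (
    CYTOPLASM,
    agreement,
    build_consensus,
    mean_agreement,
    read_combined,
    usable,
)
from .split import compartment_fractions, split_pathway

PATHWAYS = ("hsa00020", "hsa00010", "hsa00620", "hsa00250")


def _load_assignments(path: Path):
    if path.suffix.lower() in (".xlsx", ".xls"):
        tmp = path.with_suffix(".converted.tsv")
        pd.read_excel(path).to_csv(tmp, sep="\t", index=False)
        return read_combined(tmp)
    return read_combined(path)


def recompute_published_stats(data_dir: str | Path) -> dict:
    """Recompute the published compartment and agreement statistics.

    Returns a dict with per-pathway mitochondrial counts/percentages, the
    cytosol share among non-mitochondrial consensus calls (percent), and the
    mitochondria-vs-rest agreement of the predictor against each
    experimental source (averaged) and between the experimental sources.
    Raises :class:`FileNotFoundError` listing whatever input is missing.
    """
    data_dir = Path(data_dir)
    assignments = None
    for name in ("localization_assignments.tsv", "localization_assignments.xlsx"):
        if (data_dir / name).exists():
            assignments = data_dir / name
            break
    missing = [] if assignments else ["localization_assignments.tsv"]
    missing += [f"{p}.xml" for p in PATHWAYS if not (data_dir / f"{p}.xml").exists()]
    if not (data_dir / "idmap.tsv").exists():
        missing.append("idmap.tsv")
    if missing:
        raise FileNotFoundError(
            f"published-data inputs missing from {data_dir}: {', '.join(missing)} "
            "(download the KGML files from KEGG and the assignment table from the "
            "journal supplement)"
        )

    subcell, hpa, busca = _load_assignments(assignments)
    consensus = build_consensus(subcell, hpa, busca)
    idmap = read_idmap(data_dir / "idmap.tsv")

    out: dict = {"pathways": {}, "agreement": {}}

    # agreement: predictor vs each experimental source, and between experiments
    busca_vs_subcell = agreement(busca, subcell, "busca_vs_subcell")
    busca_vs_hpa = agreement(busca, hpa, "busca_vs_hpa")
    sens, spec = mean_agreement([busca_vs_subcell, busca_vs_hpa])
    out["agreement"]["busca_vs_experimental"] = {"sensitivity": sens, "specificity": spec}
    hpa_vs_subcell = agreement(hpa, subcell, "hpa_vs_subcell")
    subcell_vs_hpa = agreement(subcell, hpa, "subcell_vs_hpa")
    sens2, spec2 = mean_agreement([hpa_vs_subcell, subcell_vs_hpa])
    out["agreement"]["experimental_cross"] = {"sensitivity": sens2, "specificity": spec2}

    # cytosol share among non-mitochondrial consensus calls
    known = consensus[consensus["consensus"].map(usable)]
    nonmito = known[known["consensus"] != "mitochondria"]
    out["cytosol_share_of_nonmito_pct"] = (
        100.0 * (nonmito["consensus"] == CYTOPLASM).mean() if len(nonmito) else float("nan")
    )

    # per-pathway compartment fractions + per-gene itemisation
    for pid in PATHWAYS:
        graph = expand_nodes(read_kgml(data_dir / f"{pid}.xml"))
        frac = compartment_fractions(graph, consensus, idmap)
        result = split_pathway(graph, consensus, idmap)
        per_gene = sorted(
            (idmap.get(gid, gid), consensus["consensus"].get(idmap.get(gid, ""), "unknown"))
            for gid in set(graph.all_gene_ids())
        )
        out["pathways"][pid] = {
            "n_mito": frac.n_mito,
            "n_nonmito": frac.n_nonmito,
            "pct_mito": frac.pct_mito,
            "pct_nonmito": frac.pct_nonmito,
            "n_unknown": frac.n_unknown,
            "component_counts": result.component_counts,
            "per_gene": per_gene,
        }
    return out
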