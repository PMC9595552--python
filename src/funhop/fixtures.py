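"""Synthetic pathway and evidence-table generators.

Everything the pipeline ingests can be generated here with known ground
truth: small KGML pathways (a linear compound/reaction chain with parallel
branches and multi-gene nodes), localization tables in the three source
dialects (SubCellBarCode per-cell-line calls, HPA multi-label locations,
BUSCA single predictions) with controllable noise, an id-mapping table and a
differential-expression table with per-compartment regulation odds. A single
seed fixes every output byte-identically.

The default noise levels emulate the real sources: a few percent of
SubCellBarCode genes end up tied between neighborhoods, around 15% of HPA
genes are uncertain, the experimental sources cover roughly 60% and 53% of
the gene universe while the sequence-based predictor covers essentially all
of it but disagrees with experiment for a minority of genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kgml import Entry, Graphics, PathwayGraph, Reaction
from .localization import CATEGORIES, MITOCHONDRIA, SUBCELL_CELL_LINES

#: source-vocabulary spellings of each simplified compartment
SUBCELL_VOCAB = {
    "mitochondria": "Mitochondria",
    "cytoplasm": "Cytosol",
    "nucleus": "Nuclear",
    "secretory": "Secretory",
}
HPA_VOCAB = {
    "mitochondria": ["Mitochondria"],
    "cytoplasm": ["Cytosol", "Actin filaments", "Centrosome"],
    "nucleus": ["Nucleoplasm", "Nucleoli", "Nuclear speckles"],
    "secretory": ["Plasma membrane", "Vesicles", "Golgi apparatus"],
}
BUSCA_VOCAB = {
    "mitochondria": ["mitochondrion"],
    "cytoplasm": ["cytoplasm"],
    "nucleus": ["nucleus"],
    "secretory": ["extracellular space", "plasma membrane", "endomembrane system"],
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset; the seed fixes all randomness."""

    n_compounds: int = 8
    n_gene_entries: int = 10
    genes_per_entry: tuple[int, int] = (1, 4)  # inclusive range per entry
    fraction_mito: float = 0.5
    # evidence noise
    subcell_coverage: float = 0.61
    hpa_coverage: float = 0.53
    busca_coverage: float = 0.98
    subcell_unassign_rate: float = 0.1  # per cell line
    subcell_conflict_rate: float = 0.04  # gene-level exact tie -> uncertain
    hpa_tie_rate: float = 0.15  # gene-level exact tie -> uncertain
    busca_disagree_rate: float = 0.1
    # differential expression
    fraction_significant: float = 0.3
    alpha: float = 0.05
    up_prob: dict = field(
        default_factory=lambda: {
            "mitochondria": 0.75,
            "cytoplasm": 0.5,
            "nucleus": 0.5,
            "secretory": 0.5,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 2 or self.n_gene_entries < 1:
            raise ValueError("need at least 2 compounds and 1 gene entry")
        for name in (
            "fraction_mito", "subcell_coverage", "hpa_coverage", "busca_coverage",
            "subcell_unassign_rate", "subcell_conflict_rate", "hpa_tie_rate",
            "busca_disagree_rate", "fraction_significant",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def noiseless(self) -> "FixtureSpec":
        """Copy with full coverage and zero noise: consensus == truth."""
        return replace(
            self,
            subcell_coverage=1.0,
            hpa_coverage=1.0,
            busca_coverage=1.0,
            subcell_unassign_rate=0.0,
            subcell_conflict_rate=0.0,
            hpa_tie_rate=0.0,
            busca_disagree_rate=0.0,
        )


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    # independent stream per generator so tables stay consistent with the pathway
    return np.random.default_rng([spec.seed % (2**31), stream])


def make_pathway(spec: FixtureSpec) -> tuple[PathwayGraph, pd.DataFrame, dict[str, str]]:
    """Generate a synthetic pathway with ground truth.

    The pathway is a linear chain of compounds joined by gene-entry-catalyzed
    reactions; gene entries beyond the chain length become parallel routes
    between the same compounds (branch structure). Returns ``(graph, truth,
    idmap)`` where ``truth`` records each gene's KEGG id, symbol and true
    compartment, and ``idmap`` maps KEGG ids to symbols.
    """
    spec.validate()
    rng = _rng(spec, 1)
    graph = PathwayGraph(
        pathway_id="syn00001",
        title="synthetic metabolic pathway",
        extra={"org": "syn", "number": "00001"},
    )
    n_links = spec.n_compounds - 1
    for i in range(spec.n_compounds):
        eid = str(i + 1)
        graph.entries[eid] = Entry(
            entry_id=eid,
            entry_type="compound",
            extra={"name": f"cpd:C{90000 + i}"},
            graphics=Graphics(
                name=f"C{90000 + i}", x=100.0 + 120 * i, y=400.0,
                width=8.0, height=8.0, gtype="circle",
            ),
        )
    truth_rows = []
    idmap: dict[str, str] = {}
    # seed-dependent id base so pathways from different seeds can be merged
    # into one analysis without gene-id collisions
    id_base = 9_000_000 + (spec.seed % 1000) * 9000
    gene_serial = 0
    for j in range(spec.n_gene_entries):
        eid = str(spec.n_compounds + j + 1)
        lo, hi = spec.genes_per_entry
        k = int(rng.integers(lo, hi + 1))
        gene_ids = []
        for _ in range(k):
            gene_serial += 1
            gid = f"hsa:{id_base + gene_serial}"
            symbol = f"GENE{id_base + gene_serial}"
            idmap[gid] = symbol
            if rng.random() < spec.fraction_mito:
                category = MITOCHONDRIA
            else:
                category = str(rng.choice([c for c in CATEGORIES if c != MITOCHONDRIA]))
            truth_rows.append(
                {"gene": symbol, "kegg_id": gid, "category": category, "entry_id": eid}
            )
            gene_ids.append(gid)
        s = j % n_links
        row = j // n_links
        graph.entries[eid] = Entry(
            entry_id=eid,
            entry_type="gene",
            gene_ids=gene_ids,
            graphics=Graphics(
                name=", ".join(gene_ids), x=130.0 + 120 * s, y=100.0 + 90.0 * row,
                width=46.0, height=17.0, gtype="rectangle",
            ),
        )
        graph.reactions.append(
            Reaction(
                reaction_id=f"rn:R{90000 + j}",
                entry_id=eid,
                substrates=[str(s + 1)],
                products=[str(s + 2)],
                reversible=False,
            )
        )
    graph.validate()
    truth = pd.DataFrame(truth_rows, columns=["gene", "kegg_id", "category", "entry_id"])
    return graph, truth, idmap


def _tie_partner(rng: np.random.Generator, category: str) -> str:
    return str(rng.choice([c for c in CATEGORIES if c != category]))


def make_localization_tables(
    spec: FixtureSpec, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit SubCell (long), HPA and BUSCA tables consistent with the truth.

    Noise knobs: per-source coverage, per-cell-line ``Unassign`` dropout,
    gene-level exact ties (-> uncertain after reduction) and a BUSCA
    disagreement rate. With zero noise the three-way consensus recovers the
    truth for every covered gene.
    """
    spec.validate()
    rng = _rng(spec, 2)
    subcell_rows, hpa_rows, busca_rows = [], [], []
    for _, g in truth.iterrows():
        gene, category = g["gene"], g["category"]
        if rng.random() < spec.subcell_coverage:
            if spec.subcell_conflict_rate and rng.random() < spec.subcell_conflict_rate:
                other = _tie_partner(rng, category)
                labels = [SUBCELL_VOCAB[category]] * 2 + [SUBCELL_VOCAB[other]] * 2 + ["Unassign"]
            else:
                labels = [
                    "Unassign" if rng.random() < spec.subcell_unassign_rate
                    else SUBCELL_VOCAB[category]
                    for _ in SUBCELL_CELL_LINES
                ]
            for cell_line, label in zip(SUBCELL_CELL_LINES, labels):
                subcell_rows.append(
                    {"gene": gene, "cell_line": cell_line, "neighborhood": label}
                )
        if rng.random() < spec.hpa_coverage:
            terms = list(rng.choice(HPA_VOCAB[category],
                                    size=int(rng.integers(1, len(HPA_VOCAB[category]) + 1)),
                                    replace=False))
            if spec.hpa_tie_rate and rng.random() < spec.hpa_tie_rate:
                other = _tie_partner(rng, category)
                k = min(len(terms), len(HPA_VOCAB[other]))
                terms = terms[:k] + list(
                    rng.choice(HPA_VOCAB[other], size=k, replace=False)
                )
            hpa_rows.append(
                {"gene": gene, "locations": ";".join(terms), "reliability": "Approved"}
            )
        if rng.random() < spec.busca_coverage:
            busca_cat = category
            if spec.busca_disagree_rate and rng.random() < spec.busca_disagree_rate:
                busca_cat = _tie_partner(rng, category)
            busca_rows.append(
                {
                    "sequence_id": gene,
                    "predicted_class": str(rng.choice(BUSCA_VOCAB[busca_cat])),
                    "score": round(float(rng.uniform(0.6, 1.0)), 3),
                }
            )
    subcell = pd.DataFrame(subcell_rows, columns=["gene", "cell_line", "neighborhood"])
    hpa = pd.DataFrame(hpa_rows, columns=["gene", "locations", "reliability"])
    busca = pd.DataFrame(busca_rows, columns=["sequence_id", "predicted_class", "score"])
    return subcell, hpa, busca


def make_de_table(spec: FixtureSpec, truth: pd.DataFrame) -> pd.DataFrame:
    """Synthetic DE table (gene, logFC, p_value) following the effect model.

    A ``fraction_significant`` share of genes draws p uniformly below the
    significance threshold, the rest uniformly above; regulation sign follows
    the per-compartment up-probability, so mitochondrial upregulation
    enrichment is recoverable at a known rate.
    """
    spec.validate()
    rng = _rng(spec, 3)
    rows = []
    for _, g in truth.iterrows():
        significant = rng.random() < spec.fraction_significant
        if significant:
            p = float(rng.uniform(1e-8, spec.alpha * 0.98))
        else:
            p = float(rng.uniform(spec.alpha, 1.0))
        up = rng.random() < spec.up_prob.get(g["category"], 0.5)
        magnitude = float(abs(rng.normal(1.5, 0.5))) + 0.05
        rows.append(
            {
                "gene": g["gene"],
                "logFC": round(magnitude if up else -magnitude, 4),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "logFC", "p_value"])


def make_toy_pathway() -> tuple[PathwayGraph, dict[str, str], dict[str, str]]:
    """Three-compound, two-gene micro-pathway for split demonstrations.

    ``C1 -(MGENE, mitochondrial)-> C2 -(CGENE, cytoplasmic)-> C3``: the
    mitochondrial variant keeps only the first reaction and the
    non-mitochondrial variant only the second, each breaking the chain into
    two components. Returns ``(graph, consensus_categories, idmap)``.
    """
    graph = PathwayGraph(pathway_id="syn00002", title="toy chain",
                         extra={"org": "syn", "number": "00002"})
    for i, cid in enumerate(("1", "2", "3")):
        graph.entries[cid] = Entry(
            entry_id=cid, entry_type="compound", extra={"name": f"cpd:C0000{i + 1}"},
            graphics=Graphics(name=f"C0000{i + 1}", x=100.0 + 150 * i, y=300.0,
                              width=8.0, height=8.0, gtype="circle"),
        )
    for eid, gid, x in (("4", "hsa:91001", 175.0), ("5", "hsa:91002", 325.0)):
        graph.entries[eid] = Entry(
            entry_id=eid, entry_type="gene", gene_ids=[gid],
            graphics=Graphics(name=gid, x=x, y=200.0, width=46.0, height=17.0,
                              gtype="rectangle"),
        )
    graph.reactions = [
        Reaction("rn:R91001", "4", substrates=["1"], products=["2"]),
        Reaction("rn:R91002", "5", substrates=["2"], products=["3"]),
    ]
    idmap = {"hsa:91001": "MGENE", "hsa:91002": "CGENE"}
    consensus = {"MGENE": "mitochondria", "CGENE": "cytoplasm"}
    return graph, consensus, idmap


def write_idmap(idmap: dict[str, str], path) -> None:
    pd.DataFrame(
        {"kegg_id": list(idmap), "symbol": list(idmap.values())}
    ).to_csv(path, sep="\t", index=False)


def read_idmap(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
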