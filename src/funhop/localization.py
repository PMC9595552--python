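"""Subcellular-localization ingestion, per-source reduction and consensus.

Three heterogeneous evidence sources are supported:

* **SubCellBarCode** — mass-spectrometry neighborhood calls per cell line
  (A431, MCF7, H322, U251, HCC827); ``Unassign`` rows carry no evidence.
* **Human Protein Atlas** — antibody-based multi-label locations drawn from a
  35-term vocabulary, simplified here to four compartments (mitochondria,
  cytoplasm, nucleus, secretory) via a bundled, user-overridable mapping.
* **BUSCA** — sequence-based prediction, one class per protein; extracellular
  and membrane classes are pooled with the secretory compartment.

Each source is reduced to one preferred compartment per gene by a plurality
vote (ties -> ``uncertain``; no evidence -> ``unknown``), then a three-way
consensus is taken: two agreeing usable votes win; otherwise BUSCA casts the
deciding vote, being the only source with full coverage; a single usable vote
stands on its own. Agreement between sources is scored as a
mitochondria-vs-rest confusion matrix (sensitivity/specificity).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

MITOCHONDRIA = "mitochondria"
CYTOPLASM = "cytoplasm"
NUCLEUS = "nucleus"
SECRETORY = "secretory"
UNCERTAIN = "uncertain"
UNKNOWN = "unknown"

CATEGORIES = (MITOCHONDRIA, CYTOPLASM, NUCLEUS, SECRETORY)
#: Full per-source vocabulary, including the two no-evidence states.
ALL_CATEGORIES = CATEGORIES + (UNCERTAIN, UNKNOWN)

SUBCELL_CELL_LINES = ("A431", "MCF7", "H322", "U251", "HCC827")


def usable(category: str | None) -> bool:
    """True when a category is an actual compartment call."""
    return category in CATEGORIES


def normalize_gene(symbol: str) -> str:
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# vocabulary mappings (plain-text data files, user-overridable)


def load_mapping(which: str | Path) -> dict[str, str]:
    """Load a ``label -> category`` table.

    ``which`` is one of ``"hpa"``, ``"busca"``, ``"subcell"`` for the bundled
    tables, or a path to a two-column TSV with the same layout.
    """
    bundled = {
        "hpa": "hpa_locations.tsv",
        "busca": "busca_classes.tsv",
        "subcell": "subcell_neighborhoods.tsv",
    }
    if str(which) in bundled:
        text = resources.files("funhop.data").joinpath(bundled[str(which)]).read_text()
    else:
        text = Path(which).read_text()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, category = line.split("\t")
        mapping[label.strip().lower()] = category.strip()
    return mapping


_HPA_MAP = load_mapping("hpa")
_BUSCA_MAP = load_mapping("busca")
_SUBCELL_MAP = load_mapping("subcell")


# ---------------------------------------------------------------------------
# per-source reduction


def plurality(labels: list[str]) -> str:
    """Strict-plurality vote over compartment labels.

    Unanimous or strictly-most-frequent label wins; a tie for the top count
    is ``uncertain``; an empty list is ``unknown``. Order-invariant.
    """
    if not labels:
        return UNKNOWN
    counts = Counter(labels).most_common()
    if len(counts) == 1 or counts[0][1] > counts[1][1]:
        return counts[0][0]
    return UNCERTAIN


def reduce_subcell(cell_line_labels: list[str]) -> str:
    """Preferred compartment from per-cell-line SubCellBarCode neighborhoods.

    ``Unassign`` cell lines are excluded first; the remaining labels are
    harmonized to the four-compartment vocabulary and plurality-voted. All
    cell lines unassigned -> ``unknown``.
    """
    harmonized = []
    for label in cell_line_labels:
        cat = _SUBCELL_MAP.get(str(label).strip().lower())
        if cat is None:
            warnings.warn(f"unknown SubCell neighborhood {label!r} dropped", stacklevel=2)
        elif cat != UNKNOWN:  # Unassign
            harmonized.append(cat)
    return plurality(harmonized)


def simplify_hpa(labels: list[str] | set[str]) -> list[str]:
    """Map HPA location terms to the simplified four-compartment vocabulary.

    Unmapped terms are dropped with a warning; an empty input is an error
    (an HPA row with no annotated location is malformed).
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty HPA label set")
    out = []
    for label in labels:
        cat = _HPA_MAP.get(str(label).strip().lower())
        if cat is None:
            warnings.warn(f"unmapped HPA location {label!r} dropped", stacklevel=2)
        else:
            out.append(cat)
    return out


def reduce_hpa(simplified: list[str]) -> str:
    """Plurality vote over simplified HPA compartments (tie -> uncertain)."""
    return plurality(list(simplified))


def map_busca(label: str) -> str:
    """Map one BUSCA predicted class to the four-compartment vocabulary.

    BUSCA has no uncertain state; an unrecognised class maps to ``unknown``
    with a warning.
    """
    cat = _BUSCA_MAP.get(str(label).strip().lower())
    if cat is None:
        warnings.warn(f"unknown BUSCA class {label!r} -> unknown", stacklevel=2)
        return UNKNOWN
    return cat


# ---------------------------------------------------------------------------
# consensus


def consensus_vote(
    subcell: str | None,
    hpa: str | None,
    busca: str | None,
    prefer_experimental: bool = False,
) -> tuple[str, str]:
    """Combine per-source compartments into ``(consensus, rule)``.

    Uncertain/unknown/missing votes are absent. Two or three agreeing usable
    votes decide (``unanimous``/``majority``). With no agreeing pair, a
    usable BUSCA prediction casts the deciding vote (``busca_casting_vote``)
    — unless ``prefer_experimental`` and exactly one experimental source is
    usable, in which case that source wins (``single_source``). A single
    usable vote stands (``single_source``); no usable vote -> ``unknown``.
    """
    sc = subcell if usable(subcell) else None
    hp = hpa if usable(hpa) else None
    bu = busca if usable(busca) else None
    votes = [v for v in (sc, hp, bu) if v is not None]
    counts = Counter(votes)
    if counts:
        top, n = counts.most_common(1)[0]
        if n >= 2:
            rule = "unanimous" if n == 3 else "majority"
            return top, rule
    experimental = [v for v in (sc, hp) if v is not None]
    if bu is not None:
        if prefer_experimental and len(experimental) == 1:
            return experimental[0], "single_source"
        # BUSCA is frequently the only source with any call at all
        return bu, "busca_casting_vote"
    if len(experimental) == 1:
        return experimental[0], "single_source"
    return UNKNOWN, "none"


def build_consensus(
    subcell: dict[str, str] | pd.Series,
    hpa: dict[str, str] | pd.Series,
    busca: dict[str, str] | pd.Series,
    prefer_experimental: bool = False,
) -> pd.DataFrame:
    """Per-gene consensus table from three per-source preferred compartments.

    Returns a DataFrame indexed by gene symbol with columns ``subcell``,
    ``hpa``, ``busca``, ``consensus`` and ``rule``. The consensus is never
    ``uncertain``: uncertainty in a source is simply an absent vote.
    """
    subcell = dict(subcell)
    hpa = dict(hpa)
    busca = dict(busca)
    genes = sorted(set(subcell) | set(hpa) | set(busca))
    rows = []
    for gene in genes:
        sc = subcell.get(gene, UNKNOWN)
        hp = hpa.get(gene, UNKNOWN)
        bu = busca.get(gene, UNKNOWN)
        final, rule = consensus_vote(sc, hp, bu, prefer_experimental=prefer_experimental)
        rows.append({"gene": gene, "subcell": sc, "hpa": hp, "busca": bu,
                     "consensus": final, "rule": rule})
    df = pd.DataFrame(rows, columns=["gene", "subcell", "hpa", "busca", "consensus", "rule"])
    df = df.set_index("gene")
    rule_counts = df["rule"].value_counts().to_dict()
    log.info("consensus rules: %s", rule_counts)
    return df


# ---------------------------------------------------------------------------
# agreement


@dataclass
class AgreementReport:
    """Mitochondria-vs-rest agreement between two localization sources."""

    comparison: str
    n_shared: int
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


def agreement(
    pred: dict[str, str],
    truth: dict[str, str],
    comparison: str = "",
) -> AgreementReport:
    """Score ``pred`` against ``truth`` with mitochondria as the positive class.

    Only genes with a usable compartment in *both* sources enter the
    confusion matrix. Raises :class:`ValueError` when no gene is shared.
    """
    shared = [g for g in truth if g in pred and usable(pred[g]) and usable(truth[g])]
    if not shared:
        raise ValueError(f"no shared usable genes for comparison {comparison!r}")
    tp = fp = tn = fn = 0
    for g in shared:
        p = pred[g] == MITOCHONDRIA
        t = truth[g] == MITOCHONDRIA
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return AgreementReport(comparison, len(shared), tp, fp, tn, fn)


def mean_agreement(reports: list[AgreementReport]) -> tuple[float, float]:
    """Mean (sensitivity, specificity) over a list of agreement reports."""
    if not reports:
        raise ValueError("no reports to average")
    sens = sum(r.sensitivity for r in reports) / len(reports)
    spec = sum(r.specificity for r in reports) / len(reports)
    return sens, spec


# ---------------------------------------------------------------------------
# table readers (TSV/CSV dialects of the three sources)


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def _find_col(df: pd.DataFrame, candidates: tuple[str, ...], what: str) -> str:
    lower = {c.lower().replace(" ", "_"): c for c in df.columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    raise ValueError(f"no {what} column found; looked for {candidates}, got {list(df.columns)}")


def reduce_subcell_table(df: pd.DataFrame) -> dict[str, str]:
    """Per-gene preferred compartment from a long SubCell table.

    Duplicate gene rows pool their labels before the per-cell-line vote.
    """
    gene_col = _find_col(df, ("gene", "protein", "symbol"), "gene")
    nb_col = _find_col(df, ("neighborhood", "localization", "location"), "neighborhood")
    pooled: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        pooled.setdefault(normalize_gene(row[gene_col]), []).append(str(row[nb_col]))
    return {g: reduce_subcell(labels) for g, labels in pooled.items()}


def reduce_hpa_table(df: pd.DataFrame) -> dict[str, str]:
    """Per-gene preferred compartment from an HPA multi-label table."""
    gene_col = _find_col(df, ("gene", "gene_name", "symbol"), "gene")
    loc_col = _find_col(df, ("locations", "subcellular_location", "location", "main_location"),
                        "locations")
    pooled: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        labels = [s for s in str(row[loc_col]).split(";") if s.strip()]
        pooled.setdefault(normalize_gene(row[gene_col]), []).extend(labels)
    return {
        g: reduce_hpa(simplify_hpa(labels)) if labels else UNKNOWN
        for g, labels in pooled.items()
    }


def reduce_busca_table(df: pd.DataFrame) -> dict[str, str]:
    """Per-gene compartment from a BUSCA prediction table."""
    gene_col = _find_col(df, ("gene", "sequence_id", "id", "symbol"), "gene")
    class_col = _find_col(df, ("predicted_class", "class", "localization", "prediction"),
                          "predicted class")
    return {normalize_gene(r[gene_col]): map_busca(r[class_col]) for _, r in df.iterrows()}


def read_subcell(path: str | Path) -> dict[str, str]:
    """Read a SubCellBarCode export (long: gene, cell_line, neighborhood).

    Returns the per-gene preferred compartment after the per-cell-line vote.
    """
    return reduce_subcell_table(_read_table(path))


def read_hpa(path: str | Path) -> dict[str, str]:
    """Read an HPA subcellular-location export (gene, ';'-separated locations).

    Returns the per-gene preferred compartment after simplification and the
    plurality vote.
    """
    return reduce_hpa_table(_read_table(path))


def read_busca(path: str | Path) -> dict[str, str]:
    """Read BUSCA output (sequence id = gene symbol, predicted class, score)."""
    return reduce_busca_table(_read_table(path))


def _coerce_category(value: str, source: str) -> str:
    """Tolerant per-source category normalisation for combined tables."""
    v = str(value).strip().lower()
    if v in ("", "nan", "na", "none"):
        return UNKNOWN
    if v in ALL_CATEGORIES:
        return v
    for mapping in (_SUBCELL_MAP, _HPA_MAP, _BUSCA_MAP):
        if v in mapping:
            return mapping[v]
    warnings.warn(f"unrecognised {source} category {value!r} -> unknown", stacklevel=2)
    return UNKNOWN


def read_combined(path: str | Path) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Read a combined per-source assignment table (gene, hpa, subcell, busca).

    This is the layout of a merged individual-assignments export; values may
    be in each source's own vocabulary or already simplified. Returns the
    three per-gene category dicts ready for :func:`build_consensus`.
    """
    df = _read_table(path)
    gene_col = _find_col(df, ("gene", "symbol", "gene_name"), "gene")
    cols = {c.lower(): c for c in df.columns}
    out = []
    for source in ("subcell", "hpa", "busca"):
        cands = [c for key, c in cols.items() if source in key]
        if not cands:
            raise ValueError(f"combined table lacks a {source} column")
        col = cands[0]
        out.append({
            normalize_gene(r[gene_col]): _coerce_category(r[col], source)
            for _, r in df.iterrows()
        })
    return out[0], out[1], out[2]
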