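"""Differential-expression overlay: signed p-value transform and node coloring.

Genes from a finished DE analysis (e.g. limma-voom output) are filtered at a
significance threshold and each p-value is turned into a signed display score

    score = log2(p) * (-10) * regulation

where ``regulation`` is +1 for upregulated genes (positive fold-change) and
-1 for downregulated genes. The score is positive for upregulation, negative
for downregulation, and its magnitude grows as p shrinks; it maps onto a
green (up) / red (down) color gradient on the expanded pathway nodes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .kgml import PathwayGraph

log = logging.getLogger(__name__)

NEUTRAL_COLOR = "#BFBFBF"
DEFAULT_CAP = 100.0
# gradient endpoints: pale -> saturated
_GREEN_LO, _GREEN_HI = (0xE0, 0xF5, 0xE0), (0x00, 0x80, 0x00)
_RED_LO, _RED_HI = (0xF5, 0xE0, 0xE0), (0xB2, 0x00, 0x00)


@dataclass
class DERecord:
    gene: str
    fold_change: float
    p_value: float

    @property
    def regulation(self) -> int:
        return 1 if self.fold_change >= 0 else -1

    @property
    def score(self) -> float:
        return transform_pvalue(self.p_value, self.regulation)


def transform_pvalue(p_value: float, regulation: int) -> float:
    """Signed display score ``log2(p) * (-10) * regulation``.

    Anchors: p=1 gives 0 regardless of direction; p=0.5 down gives -10.
    """
    if not (0 < p_value <= 1):
        raise ValueError(f"p-value must lie in (0, 1], got {p_value}")
    if regulation not in (1, -1):
        raise ValueError(f"regulation must be +1 or -1, got {regulation}")
    return math.log2(p_value) * (-10.0) * regulation


def read_de(
    path: str | Path,
    gene_col: str = "gene",
    lfc_col: str = "logFC",
    p_col: str = "p_value",
) -> pd.DataFrame:
    """Read a DE table (TSV/CSV) and attach regulation and score columns.

    Column names are configurable so adjusted-p or differently named fold
    change columns can be used without editing the file.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    for col in (gene_col, lfc_col, p_col):
        if col not in df.columns:
            raise ValueError(f"DE table {path} lacks column {col!r}; has {list(df.columns)}")
    out = pd.DataFrame(
        {
            "gene": df[gene_col].astype(str).str.strip().str.upper(),
            "logFC": df[lfc_col].astype(float),
            "p_value": df[p_col].astype(float),
        }
    )
    out["regulation"] = (out["logFC"] >= 0).map({True: 1, False: -1})
    out["score"] = [
        transform_pvalue(p, r) for p, r in zip(out["p_value"], out["regulation"])
    ]
    return out


def filter_de(de: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep records with ``p_value < alpha`` (strict), logging the rest."""
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    kept = de[de["p_value"] < alpha].copy()
    log.info("filter_de: kept %d of %d records at alpha=%g", len(kept), len(de), alpha)
    return kept


def _interp(lo: tuple, hi: tuple, t: float) -> str:
    rgb = [round(a + (b - a) * t) for a, b in zip(lo, hi)]
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def colorize(score: float | None, cap: float = DEFAULT_CAP) -> str:
    """Map a signed score to a hex color.

    Positive scores interpolate a green range, negative a red range, with
    intensity monotone in ``|score|`` up to ``cap``; zero or missing scores
    are neutral gray. Deterministic.
    """
    if score is None or score == 0 or (isinstance(score, float) and math.isnan(score)):
        return NEUTRAL_COLOR
    t = min(abs(score), cap) / cap
    if score > 0:
        return _interp(_GREEN_LO, _GREEN_HI, t)
    return _interp(_RED_LO, _RED_HI, t)


def annotate_graph(
    graph: PathwayGraph,
    de: pd.DataFrame,
    idmap: dict[str, str],
    cap: float = DEFAULT_CAP,
) -> PathwayGraph:
    """Attach symbol, DE score and color to every per-gene node (in place).

    ``idmap`` maps KEGG gene ids (``hsa:NNNN``) to gene symbols; ``de`` is a
    (typically already filtered) table with ``gene`` and ``score`` columns.
    Genes missing from the map or the DE table get the neutral color; the
    pathway topology is never altered.
    """
    scores = dict(zip(de["gene"], de["score"]))
    n_missing = 0
    for _entry, node, gid in graph.gene_nodes():
        symbol = idmap.get(gid)
        if symbol is None:
            n_missing += 1
        score = scores.get(symbol) if symbol else None
        node.attrs["symbol"] = symbol or ""
        if score is not None:
            node.attrs["score"] = float(score)
        node.attrs["color"] = colorize(score, cap=cap)
        if node.graphics is not None:
            node.graphics.bgcolor = node.attrs["color"]
    if n_missing:
        log.warning("annotate_graph: %d gene ids missing from id map", n_missing)
    return graph


def write_cytoscape_style(path: str | Path, cap: float = DEFAULT_CAP) -> None:
    """Write a small JSON style description mapping ``score`` to the gradient.

    Cytoscape users can recreate the continuous mapping from this file; the
    node fill colors are in any case baked into the exported attribute table.
    """
    style = {
        "title": "funhop-de-overlay",
        "mappings": [
            {
                "attribute": "score",
                "visual_property": "NODE_FILL_COLOR",
                "type": "continuous",
                "points": [
                    {"value": -cap, "color": _interp(_RED_LO, _RED_HI, 1.0)},
                    {"value": 0.0, "color": NEUTRAL_COLOR},
                    {"value": cap, "color": _interp(_GREEN_LO, _GREEN_HI, 1.0)},
                ],
            }
        ],
    }
    Path(path).write_text(json.dumps(style, indent=2))
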