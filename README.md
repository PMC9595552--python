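# funhop

Compartment-aware KEGG pathway analysis for Python: expand multi-gene
pathway nodes into per-gene rows, assign each gene product a consensus
subcellular localization from heterogeneous evidence, overlay signed
differential-expression scores, and split metabolic pathways into
mitochondrial and non-mitochondrial variants with connectivity diagnostics.

## Who this is for

Systems biologists analyzing metabolic regulation where *compartment*
matters — e.g. the interplay of cytosolic glycolysis and the mitochondrial
TCA cycle in cancer cells. Default KEGG maps display a single gene per
enzyme node even when several functional homologs catalyze the reaction,
and they ignore where each protein actually resides. Both simplifications
can hide the biology: a "broken" mitochondrial pathway may be perfectly
intact once the hidden mitochondrial homolog in a two-gene node is shown.

## What it computes

**Node expansion.** A KGML gene entry listing genes g₁…g_k becomes k child
nodes (ids `<parent>_<i>`, stacked vertically in the parent's graphics box),
conserving the gene multiset. Output stays valid KGML, loadable by
Cytoscape/KEGGScape and round-tripping losslessly through this package.

**Localization consensus.** Three evidence sources are each reduced to one
preferred compartment per gene in the vocabulary {mitochondria, cytoplasm,
nucleus, secretory, uncertain, unknown}:

* SubCellBarCode per-cell-line neighborhoods (A431, MCF7, H322, U251,
  HCC827): `Unassign` cell lines are excluded, the rest plurality-voted;
* Human Protein Atlas multi-label locations, simplified through a bundled
  35-term → 4-compartment mapping, then plurality-voted;
* BUSCA sequence-based predictions, with extracellular/membrane classes
  pooled into *secretory*.

The three votes merge per gene: two agreeing usable votes decide; with no
agreeing pair, the predictor (BUSCA, the only source with near-complete
coverage) casts the deciding vote; a lone usable vote stands. Agreement
between sources is scored as a mitochondria-vs-rest confusion matrix
(sensitivity/specificity).

**DE overlay.** For significant genes (p < α, default 0.05),

```
score = log2(p) · (−10) · regulation,   regulation = sign(logFC) ∈ {+1, −1}
```

so upregulated genes get positive scores on a green gradient and
downregulated genes negative scores on a red gradient; p = 0.5 down gives
−10, p = 0.05 up gives ≈ 43.2.

**Compartment split.** Per-gene nodes are routed to a mitochondrial or a
pooled non-mitochondrial variant; emptied entries are deleted, reactions
that lose their catalyzing entry are flagged as broken links, and
connected-component counts quantify how much each variant fragments.

## Worked example

`examples/04_split_pathway.py` splits the bundled three-compound toy chain
C1 →(mitochondrial enzyme)→ C2 →(cytoplasmic enzyme)→ C3:

```
consensus: {'MGENE': 'mitochondria', 'CGENE': 'cytoplasm'}
component counts: {'original': 1, 'mito': 2, 'nonmito': 2}
broken links per variant: {'mito': ['rn:R91002'], 'nonmito': ['rn:R91001']}

   graph  n_entries  n_components  n_disconnected_compound_pairs disconnected_compound_pairs
original          5             1                              0
    mito          4             2                              2                     1-3;2-3
 nonmito          4             2                              2                     1-2;1-3
```

The original chain is one connected piece. Each compartment variant keeps
only its own enzyme's reaction, so each splits into two components and two
compound pairs lose their path — the non-mitochondrial variant loses exactly
the mitochondrial step, the same signature a cytosolic glycolysis map shows
when the mitochondrial pyruvate → acetyl-CoA conversion is removed.

`examples/02_localization_consensus.py` runs the consensus on a synthetic
152-gene dataset with realistic noise and coverage:

```
decision rules used:
majority              83
unanimous             35
busca_casting_vote    34

predictor vs experimental (mitochondria as positive class): sensitivity 0.93,
specificity 0.94 over 89 shared genes
consensus matches the simulated ground truth for 92.8% of genes
```

Real inputs drop in unchanged: `funhop all --kgml hsa00020.xml --subcell
subcell.tsv --hpa hpa.tsv --busca busca.tsv --de de.tsv --idmap idmap.tsv
--outdir out/` writes expanded/overlay/variant KGMLs, the consensus table,
a split report and the summary tables.

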