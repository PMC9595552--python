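# Methods

## Problem and model

Metabolic pathway maps from KEGG are bipartite chains of compounds and
enzyme nodes. Two simplifications limit their use for compartment-level
questions: an enzyme node shows only the first of possibly many functional
homologs, and nodes carry no subcellular localization. This package (i)
expands every multi-gene node into per-gene rows, (ii) assigns each gene
product one of four compartments — mitochondria, cytoplasm, nucleus,
secretory — by consensus over heterogeneous evidence, (iii) overlays a
signed differential-expression score per gene, and (iv) derives a
mitochondrial and a pooled non-mitochondrial variant of each pathway,
reporting where the restriction breaks reaction chains.

The analysis assumes each protein resides predominantly in its assigned
compartment (no modelling of protein translocation or of metabolite
transport between compartments; split variants therefore *show* broken
paths rather than re-connecting them through transporters).

## KGML representation

`read_kgml`/`write_kgml` support KGML 0.7.x. Entries, reactions, relations
and graphics are modelled explicitly; attributes the model does not know
are preserved verbatim on a per-element `extra` dict, so the round trip is
lossless even for dialect extensions. Standard KGML cannot nest entries, so
expanded children are emitted as ordinary `<entry>` elements with synthetic
ids `<parent>_<i>` and a `funhop_parent` attribute; the reader re-attaches
them, which makes expansion idempotent across save/load cycles and keeps
output loadable by generic KGML consumers. Group entries are dissolved into
their member entries (relations re-targeted to each member) before
expansion. Expansion only ever reads genes listed in the KGML `name`
attribute; no external homolog database is consulted.

Children are laid out by stacking: child *i* keeps the parent's x, width
and height and sits at y + i·height. This is one deterministic choice among
many defensible ones; it guarantees non-overlap within a stack and leaves
global overlap avoidance to the drawing tool.

## Localization sources and consensus

Per-source reduction produces one of {mitochondria, cytoplasm, nucleus,
secretory, uncertain, unknown} per gene:

* **SubCellBarCode** (five cell lines): `Unassign` labels are evidence-free
  and excluded first; remaining neighborhoods (which map 1:1 onto the four
  compartments) are plurality-voted — unanimous or strictly-most-frequent
  wins, a top-count tie is *uncertain*, no remaining label is *unknown*.
  Voting on harmonized rather than raw neighborhood labels is a deliberate
  choice: cross-source consensus needs a shared vocabulary, and for
  SubCellBarCode the mapping is a bijection so the vote is unchanged.
* **Human Protein Atlas**: the 35-term location vocabulary is mapped
  through `data/hpa_locations.tsv` to the four compartments — HPA's own
  organelle-proteome grouping, except that mitochondria stay separate
  instead of being pooled with cytoplasm — then plurality-voted. The exact
  historical grouping at any given database release is not recoverable, so
  the table is data, not code, and user-overridable.
* **BUSCA**: one predicted class per protein, mapped through
  `data/busca_classes.tsv`; extracellular and membrane classes pool into
  *secretory*; plant-specific classes map to unknown. BUSCA has no
  uncertain state.

Consensus per gene treats uncertain/unknown as absent votes: two or three
agreeing usable votes decide (`majority`/`unanimous`); otherwise a usable
BUSCA vote decides (`busca_casting_vote`) — BUSCA is the only source with
near-complete coverage, so it is frequently the only voice; otherwise a
lone usable experimental vote stands (`single_source`); otherwise
*unknown*. The consensus itself is never *uncertain*. One consequence is
that a single experimental call disagreeing with BUSCA loses; where
curators trust consistent experimental evidence more (the classic case is a
cytosolic enzyme the predictor places in mitochondria because of an
N-terminal signal-like sequence), `prefer_experimental=True` flips exactly
this one-vs-one case. Two agreeing sources always beat the predictor.

Cross-source agreement is a binary mitochondria-vs-rest confusion matrix
over genes with usable calls in both sources; sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), with an averaging helper for source pairs.

## DE overlay

Scores are `log2(p)·(−10)·regulation` with regulation = sign(logFC);
filtering keeps `p < α` strictly (default α = 0.05). The p-value column is
used as provided — raw p-values by default, matching upstream
limma-voom-style output; pointing the reader at an adjusted-p column is a
one-argument change. Colors interpolate pale→saturated green (up) or red
(down) with |score| clamped at a configurable cap (default 100,
i.e. p ≈ 10⁻³); the endpoints are display choices with no statistical
meaning. Genes absent from the DE table or the id map render neutral gray.
Pathway genes are matched to DE/localization tables by gene symbol through
an explicit two-column KEGG-id ↔ symbol mapping supplied by the user (and
generated alongside synthetic fixtures); symbols are
case/whitespace-normalized before joins.

## Compartment split

Gene rows with consensus *mitochondria* go to the mitochondrial variant;
rows with any other known compartment to the pooled non-mitochondrial
variant (the per-compartment breakdown of the pool is kept as a
diagnostic). Entries emptied of genes are deleted with their incident
relations; reactions whose catalyzing entry vanished are removed and
recorded as broken links. Compounds and map links stay in both variants so
broken paths remain visible as stranded compounds.

Genes with *unknown* consensus are kept in both variants (flagged) by
default, so missing annotation never silently fabricates a broken path;
`unknown_policy="drop"` restores a strict partition (the property the test
suite checks: variant gene sets disjoint, union = known-localization
genes).

Connectivity is measured on the undirected entry graph (relation endpoints
plus reaction entry–compound edges): component counts for original and
variants, and the list of compound pairs connected in the original but not
in a variant. "Fragments into n pieces" is inherently a visual, undirected
notion, hence the undirected view.

Compartment fractions count unique genes; percentages use known-consensus
genes as denominator and round half to even — the tie-to-even rule is what
keeps complementary pairs complementary (47.5/52.5 → 48/52) and matches
published compartment tables of this kind; `n_unknown` is reported
separately.

## Synthetic data

`FixtureSpec`/`make_pathway` generate a linear compound chain with
gene-entry-catalyzed reactions; gene entries beyond the chain length become
parallel routes, giving branch structure. Gene compartments are drawn with
probability `fraction_mito` for mitochondria, uniform otherwise. Evidence
tables copy the real dialects (long SubCell table with the five cell-line
names, semicolon-separated HPA multi-labels, single BUSCA class with a
score), so real exports drop in unchanged. Default noise emulates the real
sources: experimental coverage 0.61 (SubCell) and 0.53 (HPA) of the gene
universe versus 0.98 for the predictor, ~4% SubCell ties, ~15% HPA ties,
10% per-cell-line `Unassign` dropout, 10% predictor disagreement. The DE
model draws p uniformly below α for a `fraction_significant` share of genes
(default 0.3) and uniformly above α otherwise, with regulation sign
following per-compartment up-probabilities (default 0.75 for mitochondria,
0.5 elsewhere — a deliberately mitochondria-up-enriched regime).

What the generator does *not* emulate: correlated errors between sources,
gene-family structure, realistic pathway topology (cycles, shared
cofactors), p-value/effect-size dependence, or multi-compartment proteins.
Passing recovery tests therefore demonstrates correctness of the voting,
splitting and counting machinery under controlled conditions, not
performance on real annotation conflicts.

All randomness flows from a single integer seed through independent
sub-streams per generator, so pathway, evidence and DE tables are mutually
consistent and byte-reproducible.

## Numerical and degenerate-input choices

* `transform_pvalue` rejects p ≤ 0, p > 1 and regulation ∉ {±1}.
* Plurality voting is order-invariant (counting, no positional tie-break).
* Agreement with zero shared usable genes is an error, not a NaN report.
* An empty consensus table fails the split loudly.
* Pathways with no known-localization genes are excluded from rankings
  with a warning; ranking ties break by gene count then pathway id, using a
  stable sort.
* Problem sizes in the test and acceptance runs (pathways of ~10–30
  compounds, 20–500 gene entries, 200 random split fixtures) are chosen to
  exercise every code path with comfortable statistical power while keeping
  a full run in seconds.

## Known limitations

* Expanded children logically share the parent's connectivity; KGML output
  does not duplicate relation elements per child (GraphML export does),
  so KGML-level consumers see per-gene nodes but parent-level edges.
* The recomputation of published prostate-cancer statistics
  (`funhop.published`) needs externally downloaded inputs (KEGG licensing
  forbids bundling KGML; the assignment table is a journal supplement) and
  published pathway counts may drift by a gene or two across KEGG releases
  and reflect the original study's manual XML edits.
* No metabolite-transport modelling: split variants report broken paths;
  deciding whether a transporter rescues a path is future work.
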