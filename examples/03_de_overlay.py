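"""Overlay signed differential-expression scores on an expanded pathway.

Each significant gene's p-value becomes score = log2(p) * (-10) * regulation
(positive and green for upregulation, negative and red for downregulation);
the node attribute table is what Cytoscape imports.
"""

from funhop import (
    FixtureSpec,
    annotate_graph,
    expand_nodes,
    filter_de,
    make_de_table,
    make_pathway,
    node_attribute_table,
    transform_pvalue,
)

spec = FixtureSpec(seed=7)
graph, truth, idmap = make_pathway(spec)
graph = expand_nodes(graph)

de = make_de_table(spec, truth)
de["regulation"] = (de["logFC"] >= 0).map({True: 1, False: -1})
de["score"] = [transform_pvalue(p, r) for p, r in zip(de["p_value"], de["regulation"])]
filtered = filter_de(de, alpha=0.05)
print(f"{len(filtered)} of {len(de)} genes significant at p < 0.05")
print(f"example: p = 0.05 upregulated -> score {transform_pvalue(0.05, 1):.2f}; "
      f"p = 0.5 downregulated -> score {transform_pvalue(0.5, -1):.1f}")

annotate_graph(graph, filtered, idmap)
table = node_attribute_table(graph)
colored = table[table["color"] != "#BFBFBF"]
print(f"{len(colored)} of {len(table)} gene nodes colored "
      "(gray nodes are non-significant or unmapped)")
print(colored.head(5).to_string(index=False))
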