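"""Build the network wiring diagram from an ontology plus annotations.

Generates a small synthetic ontology (a depth-4 tree of 40 terms with
genes annotated to the leaves), prunes it, and lays it out for model
construction. The printed counts show the layered structure: every
retained term has either annotated genes or a retained child, and
children always precede parents in the evaluation order.
"""

from pathvnn.ontology import build_layout
from pathvnn.synthetic import generate_ontology

graph, annotation, leaf_genes = generate_ontology(
    depth=4, branching=3, n_genes=120, genes_per_term=5, seed=0)
layout = build_layout(graph, annotation, min_genes=1, propagate=True)

print(f"ontology: {len(graph.terms)} terms, {len(graph.edges)} is_a edges, "
      f"root {graph.root}")
print(f"layout:   {len(layout.order)} retained terms, "
      f"{len(layout.leaves())} leaves, root depth {layout.depth[layout.root]}")
first = layout.order[0]
print(f"first term in evaluation order: {first} "
      f"(depth {layout.depth[first]}, "
      f"{len(layout.gene_index['mutation'][first])} mutation genes)")
# the root is evaluated last and, with propagation, sees every gene
print(f"root mutation genes: "
      f"{len(layout.gene_index['mutation'][layout.root])} "
      f"(union over all descendants)")
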