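"""Build a label space from annotations: evidence filtering, propagation up
the ontology DAG, information content, and term selection."""

import pandas as pd

from strucfun import (OntologyGraph, filter_by_evidence, information_content,
                      propagate_annotations, select_terms)

# a miniature is_a hierarchy (child -> parent), root excluded from labels
graph = OntologyGraph.from_edges([
    ("GO:binding.ion.ca", "GO:binding.ion"),
    ("GO:binding.ion", "GO:binding"),
    ("GO:binding", "GO:0003674"),
    ("GO:catalysis", "GO:0003674"),
])

rows = []
for i in range(80):
    rows.append((f"p{i}", "GO:binding.ion.ca", "IDA"))
for i in range(60):
    rows.append((f"q{i}", "GO:catalysis", "IDA"))
for i in range(40):
    rows.append((f"r{i}", "GO:catalysis", "IEA"))  # electronic-only, dropped
table = pd.DataFrame(rows, columns=["protein_id", "term_id", "evidence"])

exp_only = filter_by_evidence(table, "exp")
print(f"evidence filter (experimental only): {len(table)} -> {len(exp_only)} rows")

propagated = propagate_annotations(exp_only, graph)
print(f"DAG propagation: {len(exp_only)} -> {len(propagated)} rows "
      "(ancestors added up to, excluding, the namespace root)")

space = select_terms(propagated, min_count=50, max_count=5000)
print("selected terms:", space.terms)
print("information content (bits):",
      {t: round(space.ic[t], 2) for t in space.terms})
print("a term seen in half the corpus carries",
      information_content(0.5), "bit")
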