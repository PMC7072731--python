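"""Hypergeometric term enrichment of a query gene set.

Generates an annotation universe with one planted enriched term and tests
the query against every term, mirroring GO/KEGG over-representation
analysis of predicted ubiquinone-binding proteins.
"""

from ubp_pred import enrich
from ubp_pred.synthetic import generate_annotation_universe

annotations, query, planted = generate_annotation_universe(
    seed=2, n_genes=200, n_terms=40, query_size=20, planted_term_overlap=15
)
results = enrich(query, annotations, cutoff=0.05)

print(f"universe N={annotations.universe_size}, query n={len(query)}, "
      f"{len(results)} terms with overlap >= 1")
print("top 3 terms by P-value:")
for r in results[:3]:
    mark = "*" if r.significant else " "
    print(f" {mark} {r.term:10s}  M={r.M:3d}  m={r.m:3d}  P={r.p_value:.3g}")
print(f"planted term recovered first: {results[0].term == planted}")
# P is the probability of an overlap at least as large as observed under
# sampling without replacement; '*' marks terms below the 0.05 cutoff.
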