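"""Hypergeometric over-representation analysis with a planted term.

Generates random annotation terms over a 400-gene universe, plants one
term whose members deliberately overlap a query set, and shows that the
over-representation test ranks the planted term first with a p-value
far below the biological-process threshold of 0.01.
"""

import numpy as np

from netpharm import synthetic
from netpharm.enrich import ALPHA_BIOLOGICAL_PROCESS, AnnotationTerm, enrich
from netpharm.symbols import TargetSet

genes = [f"G{i:04d}" for i in range(400)]
rng = np.random.default_rng(5)
query = frozenset(rng.choice(genes, size=30, replace=False))

terms = synthetic.gen_gmt_terms(genes, n_terms=15, term_size=40, seed=5,
                                planted_query=query)

result = enrich(TargetSet("query", query),
                [AnnotationTerm(*t) for t in terms],
                TargetSet("universe", frozenset(genes)),
                alpha=ALPHA_BIOLOGICAL_PROCESS)

cols = ["term_id", "k", "K", "n", "N", "p_value", "significant"]
print(result[cols].head(5).to_string(index=False))
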