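"""From compound-target assertions to a consensus target set.

Generates a synthetic herb-formula dataset at the scale of a typical
multi-compound preparation (29 chromatographically identified
constituents, ~800 disease genes), takes the union of every compound's
putative targets, and intersects it with the disease target list.  The
generator plants the overlap, so the consensus count is known exactly.
"""

from netpharm import synthetic
from netpharm.network import intersect_targets, union_compound_targets
from netpharm.symbols import TargetSet

spec = synthetic.SyntheticSpec(rng_seed=1)
ct = synthetic.gen_compound_target_map(spec)
disease = TargetSet("disease", synthetic.gen_disease_targets(spec))

union = union_compound_targets(ct)
consensus = intersect_targets(union, disease)

print(f"compound-target assertions : {len(ct)}")
print(f"distinct compounds         : {ct['compound_id'].nunique()}")
print(f"union of putative targets  : {len(union)}")
print(f"disease targets            : {len(disease)}")
print(f"consensus targets          : {len(consensus)}")
print("first five consensus symbols:", sorted(consensus.symbols)[:5])
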