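"""End-to-end run: synthetic inputs through the whole workflow.

Writes a complete synthetic input set to a temporary directory, runs
every stage (consensus targets, C-T network, topology, MCODE, hub
consensus, PPI filtering, enrichment, NCA), and prints the counts
recorded in the run manifest.  The same run is available from the shell
as ``netpharm simulate`` followed by ``netpharm run``.
"""

import json
import tempfile
from pathlib import Path

from netpharm import io, synthetic
from netpharm.pipeline import PipelineConfig, run_pipeline

spec = synthetic.SyntheticSpec(rng_seed=1)
root = Path(tempfile.mkdtemp(prefix="netpharm_demo_"))

io.write_compound_target_table(synthetic.gen_compound_target_map(spec),
                               root / "compound_targets.tsv")
io.write_gene_list(synthetic.gen_disease_targets(spec),
                   root / "disease_targets.txt")
consensus = synthetic.planted_symbols(spec)
io.write_scored_edges(synthetic.gen_ppi_edges(consensus, 0.1, seed=1),
                      root / "ppi_edges.tsv")
io.write_gmt(synthetic.gen_gmt_terms(synthetic.universe_symbols(spec), 20, 40,
                                     seed=1, planted_query=consensus),
             root / "annotations.gmt")
io.write_concentrations(
    synthetic.gen_concentration_profiles(synthetic.PKTruth(), 6, seed=1),
    root / "concentrations.csv")

config = PipelineConfig(
    compound_targets=str(root / "compound_targets.tsv"),
    disease_targets=str(root / "disease_targets.txt"),
    ppi_edges=str(root / "ppi_edges.tsv"),
    gmt_bp=str(root / "annotations.gmt"),
    concentrations=str(root / "concentrations.csv"),
    out_dir=str(root / "results"),
    min_ppi_score=0.8,
)
manifest = run_pipeline(config)

print(f"outputs in {config.out_dir}")
print(json.dumps(manifest["counts"], indent=2))
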