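"""Run the whole analysis on the default synthetic cohort.

Generates every input file (103-gene network evidence, 549 cells across 14
sample groups), then: network construction -> per-sample binarization ->
per-cell attractor search -> per-group consensus.  Outputs land under a
run directory as plain CSV/TSV/JSON.
"""

import tempfile
from pathlib import Path

from scboolnet import PipelineConfig, run_pipeline, write_fixture

tmp = Path(tempfile.mkdtemp(prefix="scboolnet_example_"))
paths = write_fixture(tmp / "inputs", seed=1)

config = PipelineConfig(
    expression=str(paths["expression"]),
    annotations=str(paths["annotations"]),
    outdir=str(tmp / "run"), seed=1,
    pathway_lists={k.removeprefix("pathway_"): str(v)
                   for k, v in paths.items() if k.startswith("pathway_")},
    cell_line_expression=str(paths["cell_line_expression"]),
    control_columns=("CONTROL_LINE",),
    de_table=str(paths["de_status"]),
    interactome=str(paths["interactome"]),
    tf_table=str(paths["tf_table"]),
    sign_table=str(paths["sign_table"]),
    low_expression_threshold=1.0,
    reference_sample="TUMOR_LINE",
    seed_genes=("HSP90AB1", "YWHAB", "VIM", "CSNK2B", "TK1"),
)
result = run_pipeline(config)

print(f"network: {result.network.n} genes; "
      f"cells analyzed: {result.report['n_cells']}")
print("per-sample attractor shares (% of cells, summing to 100):")
for sample, pcts in list(result.report["sample_percentages"].items())[:4]:
    parts = ", ".join(f"{k} {v:.1f}%" for k, v in pcts.items())
    print(f"  {sample}: {parts}")
print(f"groups with consensus calls: {len(result.consensus)}")
print(f"outputs: {sorted(p.name for p in result.paths.values())}")
# Each sample's shares split its cells by the cell type whose trajectory
# reached an attractor, plus the share where the step budget ran out.
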