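"""Full three-stage pipeline on a small synthetic panel with known truth.

Generates paired methylation/expression tables for 20 cell lines and 15
genes (15% with a planted decreasing methylation-expression relationship),
runs reduction -> association -> ranking, and prints the ranked genes next
to the generator's ground truth.
"""

import tempfile
from pathlib import Path

from epireg import RunConfig, generate_panel, run_pipeline

with tempfile.TemporaryDirectory() as td:
    meth, expr, truth = generate_panel(Path(td) / "in", n_lines=20, n_genes=15,
                                       noise_sd=3.0, seed=8)
    config = RunConfig(meth_path=str(meth), expr_path=str(expr),
                       outdir=str(Path(td) / "out"), m_perm=500, seed=8)
    result = run_pipeline(config)

print(f"{result.n_sites} CpG sites -> {result.n_regions} proximity regions "
      f"-> {result.n_clusters} methylation clusters")
print(f"{result.n_associations} methylation-expression associations; "
      f"{len(result.ranked)} genes at p < {config.alpha}")
print()
print(f"{'gene':10s} {'R':>8s} {'p':>8s}  planted?")
for rg in result.ranked:
    planted = "yes" if rg.gene in truth.regulated_genes else "no"
    print(f"{rg.gene:10s} {rg.R:8.4f} {rg.p_value:8.4f}  {planted}")
print()
print("R near 1 with p = 0 marks a strong decreasing expression-vs-")
print("methylation fit; the planted genes should lead the table.")
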