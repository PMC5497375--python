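"""Run the whole pipeline on a synthetic dataset with planted pivot genes.

Pivots are planted with a small private co-expression neighbourhood plus a
minority of interactions into a GO-enriched module — the crosstalk regime
in which an MCL partition leaves the hub outside every functional module,
so the hypergeometric pivot test can flag it.
"""

import pandas as pd

from pivotnet import run_pipeline
from pivotnet.pipeline import PipelineConfig, SyntheticBlock

config = PipelineConfig(
    out_dir="scratch/example_pipeline",
    seed=1,
    synthetic=SyntheticBlock(
        n_genes=1000,
        modules=[[12, 0.9]] * 6,   # six 12-gene co-expression modules
        n_pivots=3,                 # three planted crosstalk genes
        pivot_companions=8,         # each with a private 8-gene neighbourhood
        de_spec={"4cell|8cell": [10, 3.0]},
    ),
)

manifest = run_pipeline(config)

print("stage record counts:")
for key, value in manifest["counts"].items():
    print(f"  {key:30s} {value}")
print("detected pivot genes:", ", ".join(manifest["pivots"]))
print()
report = pd.read_csv("scratch/example_pipeline/pivot_report.tsv", sep="\t")
print(report.to_string(index=False))
print()
print("Each pivot row shows how many of the hub's network neighbours fall "
      "inside the enriched module (k_module), the hypergeometric p of that "
      "concentration, and the correlated/anti-correlated split of its edges "
      "into the module. Planted pivots are named PVT*.")
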