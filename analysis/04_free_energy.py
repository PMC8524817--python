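#!/usr/bin/env python
"""Folding free energies by structural type.

Evaluates every annotated structure under the embedded nearest-neighbor
table and aggregates mean delta G per structural class.  Also recomputes
the per-class means of the packaged published free-energy survey, which
the cohort-level ordering should mirror (variable-arm variants most
stable, acceptor-less variants least stable).
"""

import pandas as pd

from cptrna.pipeline import RunConfig, run_pipeline
from cptrna.reference import load_reference_mfe_records
from cptrna.thermo import aggregate_mfe_by_type

CONFIG = RunConfig(output_dir="results/run54", seed=1)


def main() -> None:
    run_pipeline(CONFIG, stages=("annotate", "mfe"))
    summary = pd.read_csv("results/run54/mfe_summary.tsv", sep="\t", comment="#")
    print("cohort mean delta G by type:")
    for r in summary.itertuples():
        print(f"  {r.structural_type:8s} n={r.n:4d}  {r.mean_delta_g} kcal/mol")
    print("published survey means (recomputed from per-tRNA values):")
    for st, (n, mean) in aggregate_mfe_by_type(load_reference_mfe_records()).items():
        print(f"  {str(st):8s} n={n:4d}  {mean} kcal/mol")
    print("outputs: results/run54/mfe.tsv results/run54/mfe_summary.tsv")


if __name__ == "__main__":
    main()
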