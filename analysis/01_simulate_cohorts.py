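#!/usr/bin/env python
"""Generate the three synthetic cohorts and summarize their structure.

Draws one bulk cohort (n=300 tumors, three transcriptional programs), one
single-cell cohort (2,000 cells, five cell types) and one immunotherapy
cohort (n=150) under the default study design, writes compact summary
tables under results/ and the full matrices under scratch/cohorts/ (large,
regenerable).
"""

import argparse
from pathlib import Path

import pandas as pd

from fersig.io import write_results
from fersig.simulate import (
    SimConfig,
    simulate_bulk_cohort,
    simulate_icb_cohort,
    simulate_single_cell_cohort,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--scratch", type=Path, default=Path("scratch/cohorts"))
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed)
    X, clinical, mutations, ferro, truth = simulate_bulk_cohort(cfg)
    sc, sc_truth = simulate_single_cell_cohort(cfg)
    icb_X, icb_clinical, icb_truth = simulate_icb_cohort(cfg)

    sizes = truth.cluster_labels.value_counts().sort_index()
    print(f"bulk cohort: {X.shape[0]} genes x {X.shape[1]} samples")
    print("planted cluster sizes:",
          {truth.cluster_names[k]: int(v) for k, v in sizes.items()})
    print(f"ferroptosis list: {len(ferro.all_genes())} genes "
          f"({ {r: len(m) for r, m in ferro.sets.items()} })")
    print(f"single cell: {sc.shape[0]} genes x {sc.shape[1]} cells; "
          f"types: {sc_truth.cell_types.value_counts().to_dict()}")
    resp = icb_clinical.table["response"].mean()
    print(f"ICB cohort: n={icb_X.shape[1]}, response rate {resp:.1%}")

    write_results({
        "bulk_truth_labels": truth.cluster_labels.to_frame(),
        "bulk_clinical": clinical,
        "cluster_sizes": sizes.rename("n").to_frame(),
        "cell_type_counts": sc_truth.cell_types.value_counts().rename("n").to_frame(),
    }, args.out / "01_simulate")

    # full matrices are large and deterministic; keep them out of results/
    write_results({
        "expression": X,
        "mutations": mutations,
        "ferroptosis": ferro,
        "icb_expression": icb_X,
        "icb_clinical": icb_clinical,
    }, args.scratch)
    print(f"summaries in {args.out / '01_simulate'}; matrices in {args.scratch}")


if __name__ == "__main__":
    main()
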