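#!/usr/bin/env python
"""EMT/MET induction in silico: 20-fold over/under-expression of SLUG
and miR-200.

Each perturbed ensemble is judged in the control ensemble's
z-coordinates, so shifts in phenotype fractions and PD-L1 level are
visible rather than being re-normalized away.

Finding: SLUG overexpression (EMT induction) nearly empties the
epithelial compartment and raises mean PD-L1; miR-200 overexpression
(MET induction) does the opposite - PD-L1 status follows the EMT axis
causally in the model, and the effects reverse sign with the
perturbation.

Outputs: results/perturbations/perturbation_fractions.tsv
"""

import argparse

from emtpdl1 import EnsembleConfig, PhenotypeThresholds, RunConfig, run_full_analysis


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/perturbations")
    args = ap.parse_args()

    config = RunConfig(
        network="core_emt_pdl1",
        output_dir=args.out,
        seed=args.seed,
        replicates=3,
        ensemble=EnsembleConfig(num_models=2000, num_initial_conditions=100),
        thresholds=PhenotypeThresholds(),
        perturbations=[("SLUG", "OE", 20.0), ("SLUG", "DE", 20.0),
                       ("miR200", "OE", 20.0), ("miR200", "DE", 20.0)],
    )
    run_full_analysis(config)

    import pandas as pd

    pert = pd.read_csv(f"{args.out}/perturbation_fractions.tsv", sep="\t", comment="#")
    table = pert.groupby(["node", "mode"])[["Epithelial", "Hybrid", "Mesenchymal",
                                            "mean_pdl1_z"]].mean().round(3)
    print(table)


if __name__ == "__main__":
    main()
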