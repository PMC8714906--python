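#!/usr/bin/env python
"""Stochastic dynamics of a representative tristable parameter set.

Selects, from a fresh ensemble, the best-separated parameter set whose
three coexisting states classify as (epithelial, PD-L1 low), (hybrid,
PD-L1 high) and (mesenchymal, PD-L1 high); simulates Euler-Maruyama
trajectories; builds the pseudo-potential U = -log(P) over the
(EM score, PD-L1 z) plane; and counts state-switching events at
elevated noise.

Finding: the landscape shows exactly three valleys matching the
deterministic states, and with stronger noise single cells hop
spontaneously between the epithelial/PD-L1-low and the PD-L1-high
states - immune evasion is switch-like along the EMT axis.

Outputs: results/stochastic/landscape_minima.tsv (valleys), printed
switching summary.
"""

import argparse
from pathlib import Path

from emtpdl1.pipeline import tristable_landscape_stage


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/stochastic")
    args = ap.parse_args()

    stage = tristable_landscape_stage(args.seed)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    stage["minima"].to_csv(out / "landscape_minima.tsv", sep="\t", index=False)
    print(f"representative model index: {stage['model_index']} (round {stage['round']})")
    print(stage["minima"][["em", "pdl1", "probability", "em_label", "pdl1_high"]])
    print(f"valleys: {stage['n_valleys']}, phenotypes as expected: {stage['labels_ok']}")
    print(f"switching events at elevated noise: {stage['n_switches']}")


if __name__ == "__main__":
    main()
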