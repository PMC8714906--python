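#!/usr/bin/env python
"""Stemness-extended network: does immune evasion travel with stemness?

Simulates the nine-node network (core plus OCT4, miR-145, LIN28,
let-7), computes the stemness score SN = (LIN28 + OCT4 - let7 -
miR145)/4 and its stem-like window [-0.5, 0.5], and crosses stemness
status with EM phenotype and PD-L1 status.

Finding: hybrid E/M states are about twice as likely as epithelial or
mesenchymal ones to fall in the stemness window, and the EM-PD-L1
coupling is conserved; but conditioning on stemness status alone
barely moves the probability of being PD-L1 high - stemness and
immune evasion co-occur in hybrids without one predicting the other.

Outputs: results/stemness/*.tsv, printed conditional table.
"""

import argparse
from pathlib import Path

from scipy import stats

import emtpdl1 as ep


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/stemness")
    args = ap.parse_args()

    net = ep.builtin_network("stemness_extended")
    cfg = ep.EnsembleConfig(num_models=2000, num_initial_conditions=100, seed=args.seed)
    res = ep.run_ensemble(net, config=cfg)
    tab = ep.annotate_solutions(res.solutions, scores=(ep.EM_SCORE, ep.SN_SCORE))

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    tab.to_csv(out / "solutions.tsv", sep="\t", index=False)

    rho_em = stats.spearmanr(tab["em_score"], tab["pdl1_z"]).statistic
    print(f"EM ~ PD-L1 Spearman (conserved trend): {rho_em:.3f}")
    for cond, given in (("pdl1_high", "em_label"), ("stem_like", "em_label"),
                        ("pdl1_high", "stem_like")):
        t = ep.conditional_probability(tab, cond, given)
        t.to_csv(out / f"p_{cond}_given_{given}.tsv", sep="\t")
        print(f"P({cond} | {given}):")
        print(t["probability"].round(3))


if __name__ == "__main__":
    main()
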