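#!/usr/bin/env python
"""Transcriptomic scoring machinery exercised on synthetic data.

Generates (i) an EMT induction/withdrawal time course with a built-in
saturating PD-L1 response and (ii) 27 cohorts with 30 genes planted to
correlate with a PD-L1 anchor; then runs the 2D epithelial/mesenchymal
activity scoring, the replicated-correlation signature derivation, and
the linear-vs-saturating association fit.

Finding: the mesenchymal activity axis tracks the latent EMT level,
the signature rule recovers all planted genes with essentially no
false positives, and the Michaelis-Menten form beats the straight line
on adjusted R^2 exactly when the generator's half-saturation constant
is small - the scoring stage detects the saturating EMT-to-PD-L1
relation when it is there.

Outputs: results/expression/*.tsv
"""

import argparse
from pathlib import Path

import numpy as np
from scipy import stats

import emtpdl1 as ep
from emtpdl1.scoring import GeneSet


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/expression")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    cfg = ep.GeneratorConfig(seed=args.seed)
    matrix, ann = ep.generate_emt_timecourse(cfg)
    matrix.to_csv(out / "timecourse_matrix.tsv", sep="\t")
    ann.to_csv(out / "timecourse_annotations.tsv", sep="\t")

    e_set = GeneSet("E", tuple(g for g in matrix.index if g.startswith("E_")))
    m_set = GeneSet("M", tuple(g for g in matrix.index if g.startswith("M_")))
    xy = ep.em_2d_coordinates(matrix, e_set, m_set, scorer="ssgsea")
    xy.to_csv(out / "em_2d_coordinates.tsv", sep="\t")
    rho = stats.spearmanr(xy["M"], ann["latent_s"]).statistic
    print(f"M-axis activity ~ latent EMT level: rho = {rho:.3f}")

    lin, sat, pref = ep.fit_linear_vs_saturating(
        xy["M"].to_numpy(), matrix.loc["PDL1"].to_numpy()
    )
    print(f"EMT activity -> PD-L1 fit: preferred = {pref} "
          f"(adj R2 linear {lin.adjusted_r_squared:.3f}, "
          f"saturating {sat.adjusted_r_squared:.3f})")

    cohorts = ep.generate_cohorts(cfg, n_cohorts=27, n_planted=30,
                                  planted_correlation=0.8, n_null=300, n_samples=100)
    sig = ep.derive_signature(cohorts, "PDL1", min_cohorts=15)
    (out / "pdl1_signature.txt").write_text("\n".join(sig.genes) + "\n")
    planted = sum(g.startswith("SIG_") for g in sig.genes)
    print(f"signature: {planted}/30 planted genes recovered, "
          f"{len(sig.genes) - planted} others, written to pdl1_signature.txt")


if __name__ == "__main__":
    main()
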