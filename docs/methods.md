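# Methods

## Model

Every network node obeys the same production–degradation ODE

    dX_i/dt = g_i · ∏_j Hs(X_j; X⁰_ji, n_ji, λ_ji) − k_i · X_i,

where the product runs over the regulators of node *i* and
`Hs(X) = λ + (1−λ)/(1+(X/X⁰)ⁿ)` is the shifted Hill multiplier: 1 in
the absence of the regulator, λ at saturation, with λ>1 for activation
and λ<1 for inhibition. MicroRNA nodes (miR-200, miR-145, let-7) use
the same functional form as transcription factors; the model carries
no separate translational layer. Concentrations are in arbitrary
units; time is in units of the inverse degradation rates.

The scientific object is not any single parameterization but the
*ensemble*: thousands of kinetic parameter sets drawn from broad
ranges, each contributing its stable steady states. Statistics over
the pooled states characterize what the wiring — rather than specific
kinetics — enforces.

## Parameter sampling

| parameter | distribution | default |
|---|---|---|
| production g | uniform | [1, 100] per unit time |
| degradation k | uniform | [0.1, 1] |
| Hill coefficient n | uniform integer | 1–6 |
| fold change (activation λ) | uniform | [1, 100] |
| fold change (inhibition λ) | reciprocal of uniform [1,100] | [0.01, 1] |
| threshold X⁰ | uniform on [0.02·M, 1.98·M] | half-functional rule |

M is the Monte-Carlo median level of the regulator, estimated in two
passes (1,000 draws): first the regulation-free median of g/k, then
the median of g/k multiplied by the shifted-Hill factors of each
incoming edge evaluated at random regulator levels, thresholds and
kinetics drawn from the same ranges. This makes each edge roughly
half-functional: measured across ensembles of the core network, the
probability that a regulator sits above its edge threshold is
0.44–0.55 for every edge. An alternative single-pass rule (basal g/k
medians for all nodes) mis-places thresholds of strongly regulated
nodes and collapses the ensemble's phenotypic structure; it is not
offered.

Over- and under-expression (OE/DE) of a node multiply or divide its
production range by the fold (default 20) *after* threshold
calibration, so the perturbation acts on an otherwise unchanged
circuit.

## Integration and state collection

Euler stepping with dt = 0.1 up to t = 1,000 per run; a run has
converged when the largest relative per-node change over a 10-time-unit
window falls below 1e-4. Converged endpoints are merged into distinct
states when their maximum per-node |Δlog₂| is below 0.1 (≈7% level
difference — wide enough to absorb integrator noise, narrow enough to
separate biologically distinct states). Models with more than 5
distinct states are dropped entirely (in practice far below 1% of
models); non-converged runs are counted and discarded. Every reported
state satisfies the fixed-point residual |g·∏Hs − k·X| < 1e-3·k·X.

Initial conditions are sampled log-uniformly between 0.01 and
1.5·(g_i/k_i)·∏λ (the product over incoming activation fold changes).
The upper limit matters: a self-activated node's high branch lies up
to a fold change *above* g/k, and sampling uniformly on [0, 1.5·g/k]
systematically misses those basins (states per model drop from ≈1.34
to ≈1.06 on the core network). The log scale spreads starts across
the dynamic range so small-basin low states are found as reliably as
high ones. `EnsembleConfig(ic_mode="uniform")` restores plain uniform
sampling for comparison.

## Normalization and scores

Steady states are tabulated in log₂ and z-scored per node against the
pooled mean and population standard deviation of *all* retained
solutions (each distinct state of each model contributes one row).
Perturbed ensembles are z-scored against their matched *control*
ensemble's moments — normalizing a perturbed ensemble against itself
recenters every node and hides exactly the shift the perturbation
causes.

Scores are signed means of z-scores: EM = (ZEB1 + SLUG − miR200 −
CDH1)/4, SN = (LIN28 + OCT4 − let7 − miR145)/4, Resistance = ERα36 −
ERα66. Labels: epithelial (EM < −0.25), hybrid (−0.25 ≤ EM ≤ 0.5;
boundary values are hybrid, since only the outer inequalities are
strict), mesenchymal (EM > 0.5); stem-like −0.5 ≤ SN ≤ 0.5; resistant
Resistance > 0. The PD-L1 high/low boundary is fitted as the
equal-posterior point of a two-component Gaussian mixture on the
PD-L1 z-scores (its distribution is bimodal); if the components
overlap (Ashman D < 2) the cut falls back to 0 with a warning, and a
fixed cut can be configured for reproducibility. Binarization for
hybrid sub-phenotypes uses z > 0, the natural center of z-scores.

Mode counting uses a Gaussian KDE with Silverman bandwidth; a mode is
a local maximum with prominence above 5% of the peak density.

## Stochastic stage

The Euler–Maruyama update adds `σ_i·√dt·N(0,1)` to the deterministic
Euler step, with reflection at zero (concentrations cannot go
negative). The default noise is the update rule's unit-amplitude term
scaled by a single `noise_level` applied to all nodes; a per-node σ
array is accepted. A level proportional to each node's maximal
abundance (e.g. 0.05·g/k) was rejected: for high-abundance nodes it
is enormous in absolute terms and drives the log-scale projection into
constant outlier excursions. With zero noise the stochastic stepper
reproduces the deterministic integrator bit for bit (identical
arithmetic order).

The representative tristable model is chosen deterministically from an
ensemble: among models with exactly three states classifying as
(epithelial, PD-L1 low), (hybrid, PD-L1 high), (mesenchymal, PD-L1
high) under the global normalization, the one whose states are
*best separated* in the (EM, PD-L1 z) plane (minimum pairwise distance
≥ 0.3) is taken; marginal models whose hybrid and mesenchymal states
nearly coincide produce landscapes that cannot resolve three valleys.
Qualifying models are rare (a few per several thousand), so the stage
draws up to three independent ensembles and walks candidates from
best to worst separation until a three-valley landscape is obtained —
a deterministic search given the seed.

Landscapes are occupancy histograms over (EM score, PD-L1 z) after a
10% burn-in, on a 60×60 grid clipped to the 0.5–99.5% quantiles (rare
excursions toward zero concentration are extreme outliers on a log
projection and would stretch the grid until real basins blur), padded
5%. U = −log P on occupied bins; unoccupied bins stay undefined
rather than getting an artificial finite potential. Valleys are
strict local maxima of the Gaussian-smoothed (σ = 2 bins) occupancy
above 5% of its peak, and are labelled after snapping to the nearest
deterministic steady state — noise skews occupancy maxima slightly
off the attractor, and the attractor is what a valley represents.
Switch detection assigns each recorded point to a state only inside a
hysteresis radius (default 45% of the smallest center distance) so
boundary flicker does not count as switching; events are changes of
assignment.

## Expression scoring

Matrices are genes × samples DataFrames of log-scale values. The
ssGSEA-style score ranks each sample's genes (average ranks on ties),
walks the descending ranking, and integrates the difference between
the rank-value^0.25-weighted cumulative distribution of set members
and the uniform cumulative distribution of non-members; scores are
min–max normalized across samples. The AUC-style score is the area
under the recovery curve of set members within the top 5% of the
ranking, normalized by the best achievable area, hence in [0, 1].
Both are rank statistics and therefore invariant to any strictly
monotone per-sample transformation, and set members absent from the
matrix are ignored. The two E/M program scores are computed
independently — no forced anti-correlation — so gain of mesenchymal
and loss of epithelial character are separate moves on the 2D plane.

Signature derivation retains a gene when its Spearman correlation with
the anchor exceeds 0.5 at p < 0.01 (t-approximation, average ranks) in
at least K of the cohorts (default 15); the output is monotone
non-increasing in both thresholds. The association fit compares
a·x + b against a·x/(b + x) + c (least squares; the saturating form is
fitted on x shifted to start at 0, with b > 0 enforced) by adjusted
R² = 1 − (1−R²)(n−1)/(n−p−1) with p = 2 and 3.

## Synthetic data

The time-course generator emulates an EMT induction / signal
withdrawal experiment: a latent EMT level s(t) rises logistically
during induction and decays exponentially toward a residual level
*above* the starting point after withdrawal — the asymmetry encodes
the hysteresis seen when populations do not retrace their path on MET.
Mesenchymal genes follow s through a logistic response with
per-gene random amplitudes, epithelial genes mirror it downward,
housekeeping genes are flat, and a PD-L1 gene follows the saturating
response v·s/(K + s) + c (defaults v = 3, K = 0.3, baseline 1).
Noise is additive Gaussian on the log scale (log-normal
multiplicative), sd 0.2. The cohort generator plants genes sharing a
Gaussian latent factor with the anchor at a requested correlation on a
background of independent nulls.

What the generators do *not* emulate: platform-specific distributions
(microarray vs RNA-seq), gene–gene correlation beyond the single
latent factor, dropout and library-size effects of single-cell data,
and batch structure. Passing tests therefore show that the scoring
machinery detects the designed signal — monotone program shifts, a
saturating response, replicated anchor correlation — not that it is
robust to every artifact of real platforms.

## Problem sizes

The analysis drivers and the acceptance script use 2,000 parameter
sets × 100 initial conditions per ensemble (three replicate seeds for
error bars; 5,000 sets for the representative-model search), which
puts ensemble statistics well inside their asymptotic regime — the
EM–PD-L1 correlation moves by <0.05 between 2,000 and 10,000 models —
while keeping a full reproduction run in the minutes range on one
CPU. The compiled (numba) stepper integrates the full ensemble batch
with per-trajectory early stopping at convergence.

## Network reconstruction and its limits

The core five-node wiring follows the described interactions: mutual
ZEB1/miR-200 inhibition with ZEB1 self-activation, SLUG activating
ZEB1 and repressing miR-200 and CDH1, ZEB1 repressing CDH1, miR-200
repressing PD-L1, and PD-L1 repressing CDH1. The exact edge lists of
the stemness and estrogen-receptor extensions are not recoverable from
text alone; the shipped defaults use literature-standard
mutual-inhibition modules (LIN28⊣⊢let-7, OCT4⊣⊢miR-145; ERα66
mutually antagonistic with ERα36, SLUG and ZEB1, plus ERα66⊣PD-L1)
coupled to the EMT axis (miR-200 repressing LIN28/OCT4, ZEB1
repressing let-7/miR-145), chosen among candidate couplings as the
variant that reproduces the reported qualitative behaviour of those
modules. All three networks ship as editable `.topo` data files, so a
corrected transcription never touches code.

## Known limitations

- Under the shipped wiring and standard ranges the EM-score density is
  robustly *bimodal* under the Silverman/5%-prominence mode counter:
  the hybrid compartment (~25% of solutions, centred near EM ≈ 0.15)
  forms a broad plateau between the epithelial and mesenchymal modes
  rather than a third peak. Hybrid states are heterogeneous
  combinations of partially committed nodes, and their EM scores
  spread accordingly. A wiring or parameter-range variant that
  additionally concentrates the hybrid mode was not found.
- The stemness coupling faces a structural trade-off: couplings that
  leave the stemness score uncorrelated with PD-L1 also leave the
  stemness window equally occupied by all phenotypes. The shipped
  wiring reproduces the hybrid-enriched window and the
  status-level independence (P(PD-L1 high | stem-like) ≈ P(PD-L1 high
  | non-stem)), at the price of a correlated raw stemness score.
- No stiff/implicit solvers, no bifurcation continuation, no
  transition-rate theory on the landscape, and no parameter fitting to
  data; the ensembles are characterizations of a fixed wiring.
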