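"""Synthetic expression data with the statistical structure the scoring
machinery is meant to detect.

Two generators are provided.  ``generate_emt_timecourse`` emulates an
EMT-induction / signal-withdrawal experiment: a latent EMT level s(t)
rises during induction and relaxes only partially after withdrawal
(hysteresis), mesenchymal program genes follow s through a logistic
response, epithelial genes mirror it downward, housekeeping genes stay
flat, and a PD-L1 gene tracks s through a saturating Michaelis-Menten
response v*s/(K+s) + c.  ``generate_cohorts`` builds multi-cohort
matrices in which a configurable number of genes share a latent factor
with an anchor gene at a requested correlation, on a background of
independent null genes - the test bed for replicated signature
derivation.  Noise is additive Gaussian on the log scale (log-normal
multiplicative on the linear scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GeneratorConfig", "generate_emt_timecourse", "generate_cohorts"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-expression generators.

    Time is in arbitrary units; the induction phase runs to
    ``t_induction`` and the withdrawal phase to ``t_total``.  The
    latent EMT level follows a logistic rise with the given midpoint
    and steepness, then decays toward ``s_residual`` (> initial level:
    the population does not retrace its path, mimicking hysteresis).
    """

    n_m_genes: int = 25
    n_e_genes: int = 25
    n_housekeeping: int = 20
    n_null_genes: int = 30
    n_timepoints: int = 12
    n_replicates: int = 3
    t_induction: float = 8.0
    t_total: float = 16.0
    latent_midpoint: float = 3.0
    latent_steepness: float = 1.0
    s_residual: float = 0.25
    withdrawal_rate: float = 0.35
    pdl1_v: float = 3.0
    pdl1_k: float = 0.3
    pdl1_baseline: float = 1.0
    base_expression: float = 6.0
    response_amplitude: float = 3.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pdl1_k <= 0:
            raise ValueError("pdl1_k must be positive")
        if min(self.n_m_genes, self.n_e_genes, self.n_timepoints) < 1:
            raise ValueError("gene and time-point counts must be >= 1")


def latent_emt_level(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """The latent EMT trajectory s(t) over the sampled time points.

    Induction: logistic rise toward 1.  Withdrawal: exponential decay
    toward ``s_residual``, which exceeds the starting level, so the
    final state stays partially mesenchymal.
    """
    t = np.linspace(0.0, config.t_total, config.n_timepoints)
    s = np.empty_like(t)
    rise = 1.0 / (1.0 + np.exp(-(t - config.latent_midpoint) * config.latent_steepness))
    s_end = 1.0 / (
        1.0 + np.exp(-(config.t_induction - config.latent_midpoint) * config.latent_steepness)
    )
    induction = t <= config.t_induction
    s[induction] = rise[induction]
    tw = t[~induction] - config.t_induction
    s[~induction] = config.s_residual + (s_end - config.s_residual) * np.exp(
        -config.withdrawal_rate * tw
    )
    return t, s


def _logistic(s: np.ndarray, midpoint: float = 0.5, steep: float = 8.0) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(s - midpoint) * steep))


def generate_emt_timecourse(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic EMT induction/withdrawal time course.

    Returns ``(matrix, annotations)``: a genes x samples log-scale
    matrix (gene groups ``M_*``, ``E_*``, ``HK_*``, ``NULL_*`` plus the
    ``PDL1`` gene) and per-sample annotations (time, latent level s,
    phase).  With ``noise_sd = 0`` the PD-L1 row equals
    ``v*s/(K+s) + c`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    t, s = latent_emt_level(config)
    times = np.repeat(t, config.n_replicates)
    sv = np.repeat(s, config.n_replicates)
    n_samples = times.size
    samples = [f"S{i:03d}" for i in range(n_samples)]

    rows: list[np.ndarray] = []
    names: list[str] = []

    def add_block(prefix: str, count: int, signal: np.ndarray | None, sign: float) -> None:
        for i in range(count):
            amp = config.response_amplitude * rng.uniform(0.5, 1.5)
            base = config.base_expression + rng.normal(0.0, 0.5)
            profile = base + (sign * amp * signal if signal is not None else 0.0)
            rows.append(profile + rng.normal(0.0, config.noise_sd, size=n_samples))
            names.append(f"{prefix}{i:03d}")

    response = _logistic(sv)
    add_block("M_", config.n_m_genes, response, +1.0)
    add_block("E_", config.n_e_genes, response, -1.0)
    add_block("HK_", config.n_housekeeping, None, 0.0)
    for i in range(config.n_null_genes):
        rows.append(
            config.base_expression + rng.normal(0.0, 1.0) + rng.normal(0.0, 1.0, size=n_samples)
        )
        names.append(f"NULL_{i:03d}")
    pdl1 = config.pdl1_v * sv / (config.pdl1_k + sv) + config.pdl1_baseline
    rows.append(pdl1 + rng.normal(0.0, config.noise_sd, size=n_samples))
    names.append("PDL1")

    matrix = pd.DataFrame(np.vstack(rows), index=names, columns=samples)
    annotations = pd.DataFrame(
        {
            "time": times,
            "latent_s": sv,
            "phase": np.where(times <= config.t_induction, "induction", "withdrawal"),
        },
        index=samples,
    )
    return matrix, annotations


def generate_cohorts(
    config: GeneratorConfig = GeneratorConfig(),
    n_cohorts: int = 27,
    n_planted: int = 30,
    planted_correlation: float = 0.8,
    n_null: int = 300,
    n_samples: int = 100,
    anchor: str = "PDL1",
) -> list[pd.DataFrame]:
    """Cohorts with genes planted to correlate with an anchor gene.

    Every cohort holds the anchor, ``n_planted`` genes sharing a latent
    factor with it at the requested (Gaussian) correlation, and
    ``n_null`` independent genes.  Gene names are common across
    cohorts so replication counting is meaningful.
    """
    if not (0 <= planted_correlation < 1):
        raise ValueError("planted_correlation must be in [0, 1)")
    rng = np.random.default_rng(config.seed)
    rho = planted_correlation
    cohorts = []
    planted_names = [f"SIG_{i:03d}" for i in range(n_planted)]
    null_names = [f"NULL_{i:03d}" for i in range(n_null)]
    for _ in range(n_cohorts):
        factor = rng.normal(size=n_samples)
        anchor_vals = factor  # anchor is the latent factor itself
        planted = rho * factor[None, :] + np.sqrt(1 - rho**2) * rng.normal(
            size=(n_planted, n_samples)
        )
        nulls = rng.normal(size=(n_null, n_samples))
        data = np.vstack([anchor_vals[None, :], planted, nulls]) + config.base_expression
        cohorts.append(
            pd.DataFrame(
                data,
                index=[anchor] + planted_names + null_names,
                columns=[f"S{i:03d}" for i in range(n_samples)],
            )
        )
    return cohorts
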