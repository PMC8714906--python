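"""Random-kinetics ensemble simulation of a regulatory topology.

The engine follows the random circuit perturbation (RACIPE) recipe:
for one network topology, draw many kinetic parameter sets from broad
biologically plausible ranges, integrate the shifted-Hill ODE system
from many random initial conditions per set, collect the distinct
stable steady states, and z-normalize the pooled log2 steady-state
levels per node.  The ensemble of states then characterizes the
phenotypes the topology supports, independent of any one parameter
choice.

Defaults: production g ~ U[1, 100], degradation k ~ U[0.1, 1], Hill
coefficient n ~ U{1..6}, fold change ~ U[1, 100] (inhibitory edges use
the reciprocal so lam in [0.01, 1]), and edge thresholds X0 drawn
around the Monte-Carlo median level of the regulator (half-functional
rule).  Up to ``max_states`` (default 5) coexisting states are kept per
model; models exceeding that are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .networks import ACTIVATION, NetworkTopology

__all__ = [
    "ParameterRanges",
    "EnsembleConfig",
    "KineticParameterSet",
    "EnsembleParameters",
    "EnsembleResult",
    "shifted_hill",
    "sample_parameters",
    "sample_ensemble_parameters",
    "find_steady_states",
    "run_ensemble",
    "apply_perturbation",
    "z_normalize",
    "steady_state_residuals",
]


def shifted_hill(x, x0, n, lam):
    """Shifted Hill regulation multiplier ``lam + (1-lam)/(1+(x/x0)^n)``.

    Equals 1 at ``x = 0`` (no regulator) and tends to ``lam`` as
    ``x -> inf``; ``lam > 1`` is activation, ``lam < 1`` inhibition.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("Hill threshold x0 must be positive")
    ratio = np.asarray(x, dtype=float) / x0
    return lam + (1.0 - lam) / (1.0 + ratio**n)


@dataclass(frozen=True)
class ParameterRanges:
    """Sampling intervals for the random kinetics.

    ``production_overrides`` holds per-node (lo, hi) production ranges
    installed by :func:`apply_perturbation`; the half-functional
    threshold scales are always computed from the unperturbed base
    ranges, mirroring how over/under-expression is applied on top of an
    already calibrated circuit.
    """

    production: tuple[float, float] = (1.0, 100.0)
    degradation: tuple[float, float] = (0.1, 1.0)
    hill_coefficient: tuple[int, int] = (1, 6)
    fold_change: tuple[float, float] = (1.0, 100.0)
    threshold_draws: int = 1000
    production_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("production", "degradation", "fold_change"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} interval must be positive and ordered")
        n_lo, n_hi = self.hill_coefficient
        if n_lo < 1 or n_hi < n_lo:
            raise ValueError("hill_coefficient range must satisfy 1 <= lo <= hi")

    def production_range(self, node: str) -> tuple[float, float]:
        return self.production_overrides.get(node, self.production)


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble size, integration and state-collection settings.

    Initial conditions are sampled log-uniformly between ``ic_floor``
    and 1.5x each node's maximal attainable level (g/k times the
    product of incoming activation fold changes).  Sampling uniformly
    on [0, 1.5 g/k] instead (``ic_mode="uniform"``) systematically
    misses basins of self-activated high branches, which sit up to a
    fold change above g/k.
    """

    num_models: int = 10_000
    num_initial_conditions: int = 100
    dt: float = 0.1
    t_max: float = 1000.0
    convergence_tol: float = 1e-4
    convergence_window: float = 10.0
    merge_tol_log2: float = 0.1
    max_states: int = 5
    ic_mode: str = "loguniform"  # or "uniform"
    ic_floor: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_max <= self.dt:
            raise ValueError("need dt > 0 and t_max > dt")
        if self.max_states < 1:
            raise ValueError("max_states must be >= 1")


@dataclass(frozen=True)
class KineticParameterSet:
    """Sampled kinetics for one model: per-node g, k and per-edge lam, n, X0."""

    topology: NetworkTopology
    g: np.ndarray  # (N,)
    k: np.ndarray  # (N,)
    lam: np.ndarray  # (E,)
    hill_n: np.ndarray  # (E,) int
    x0: np.ndarray  # (E,)

    def __post_init__(self) -> None:
        if np.any(self.g <= 0) or np.any(self.k <= 0) or np.any(self.x0 <= 0):
            raise ValueError("g, k and x0 must be positive")
        for e, edge in enumerate(self.topology.edges):
            if edge.sign == ACTIVATION and self.lam[e] < 1.0:
                raise ValueError(f"activation edge {edge.source}->{edge.target} needs lam >= 1")
            if edge.sign != ACTIVATION and not (0.0 < self.lam[e] <= 1.0):
                raise ValueError(f"inhibition edge {edge.source}->{edge.target} needs 0 < lam <= 1")


@dataclass(frozen=True)
class EnsembleParameters:
    """Vectorized kinetics for a whole ensemble (model-major arrays)."""

    topology: NetworkTopology
    g: np.ndarray  # (M, N)
    k: np.ndarray  # (M, N)
    lam: np.ndarray  # (M, E)
    hill_n: np.ndarray  # (M, E) int
    x0: np.ndarray  # (M, E)

    @property
    def num_models(self) -> int:
        return self.g.shape[0]

    def model(self, index: int) -> KineticParameterSet:
        return KineticParameterSet(
            topology=self.topology,
            g=self.g[index].copy(),
            k=self.k[index].copy(),
            lam=self.lam[index].copy(),
            hill_n=self.hill_n[index].copy(),
            x0=self.x0[index].copy(),
        )


@dataclass
class EnsembleResult:
    """Distinct steady states of all retained models, pooled and z-scored.

    ``solutions`` has one row per distinct stable state with columns
    ``model_index``, ``num_states``, ``<node>_log2`` and ``<node>_z``.
    ``log2_mean`` / ``log2_std`` are the pooled per-node moments used
    for the z-normalization (population standard deviation).
    """

    topology: NetworkTopology
    config: EnsembleConfig
    solutions: pd.DataFrame
    log2_mean: pd.Series
    log2_std: pd.Series
    params: EnsembleParameters
    n_models_retained: int
    n_models_dropped_multistate: int
    n_runs_nonconverged: int

    def z_matrix(self) -> pd.DataFrame:
        cols = {f"{n}_z": n for n in self.topology.nodes}
        return self.solutions[list(cols)].rename(columns=cols)

    def solutions_vs_reference(self, reference: "EnsembleResult") -> pd.DataFrame:
        """Solution table re-z-scored with another ensemble's moments.

        Perturbed (over/under-expression) ensembles must be normalized
        against the control ensemble: z-scoring a perturbed ensemble
        against itself recenters every node and hides the shift the
        perturbation causes.
        """
        out = self.solutions.copy()
        for node in self.topology.nodes:
            out[f"{node}_z"] = (
                out[f"{node}_log2"] - reference.log2_mean[node]
            ) / reference.log2_std[node]
        return out


def _median_levels(
    topology: NetworkTopology, ranges: ParameterRanges, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo median steady level per node for the half-functional rule.

    Pass one ignores regulation (median of g/k); pass two multiplies in
    shifted-Hill factors of each incoming edge evaluated at random
    regulator levels and random edge kinetics.
    """
    draws = ranges.threshold_draws
    g = rng.uniform(*ranges.production, size=draws)
    k = rng.uniform(*ranges.degradation, size=draws)
    m0 = float(np.median(g / k))
    levels = np.empty(topology.n_nodes)
    incoming: dict[int, list[int]] = {i: [] for i in range(topology.n_nodes)}
    for e, edge in enumerate(topology.edges):
        incoming[topology.node_index(edge.target)].append(e)
    n_lo, n_hi = ranges.hill_coefficient
    for i in range(topology.n_nodes):
        g = rng.uniform(*ranges.production, size=draws)
        k = rng.uniform(*ranges.degradation, size=draws)
        level = g / k
        for e in incoming[i]:
            sign = topology.edges[e].sign
            u = rng.uniform(*ranges.fold_change, size=draws)
            lam = u if sign == ACTIVATION else 1.0 / u
            n = rng.integers(n_lo, n_hi + 1, size=draws)
            x_reg = rng.uniform(0.0, 2.0 * m0, size=draws)
            x0 = rng.uniform(0.02 * m0, 1.98 * m0, size=draws)
            level = level * shifted_hill(x_reg, x0, n, lam)
        levels[i] = np.median(level)
    return levels


def sample_ensemble_parameters(
    topology: NetworkTopology,
    ranges: ParameterRanges,
    num_models: int,
    rng: np.random.Generator,
) -> EnsembleParameters:
    """Draw kinetics for ``num_models`` models in one vectorized pass."""
    N, E = topology.n_nodes, topology.n_edges
    medians = _median_levels(topology, ranges, rng)
    g = np.empty((num_models, N))
    for i, node in enumerate(topology.nodes):
        lo, hi = ranges.production_range(node)
        g[:, i] = rng.uniform(lo, hi, size=num_models)
    k = rng.uniform(*ranges.degradation, size=(num_models, N))
    n_lo, n_hi = ranges.hill_coefficient
    hill_n = rng.integers(n_lo, n_hi + 1, size=(num_models, E))
    fold = rng.uniform(*ranges.fold_change, size=(num_models, E))
    src, _, sign = topology.edge_arrays()
    lam = np.where(sign[None, :] > 0, fold, 1.0 / fold)
    med_src = medians[src]
    x0 = rng.uniform(0.02 * med_src[None, :], 1.98 * med_src[None, :], size=(num_models, E))
    return EnsembleParameters(topology, g, k, lam, hill_n, x0)


def sample_parameters(
    topology: NetworkTopology, ranges: ParameterRanges, seed: int
) -> KineticParameterSet:
    """Draw one kinetic parameter set (deterministic in ``seed``)."""
    rng = np.random.default_rng(seed)
    return sample_ensemble_parameters(topology, ranges, 1, rng).model(0)


def apply_perturbation(
    target: ParameterRanges | KineticParameterSet,
    topology_or_node,
    node: str | None = None,
    mode: str | None = None,
    fold: float = 20.0,
):
    """Over- (OE) or down-express (DE) one node by scaling its production.

    Accepts either sampling ranges (``apply_perturbation(ranges,
    topology, node, mode)``) or a single parameter set
    (``apply_perturbation(params, node, mode)``).
    """
    if isinstance(target, ParameterRanges):
        topology, node_name = topology_or_node, node
    else:
        topology, node_name, mode = target.topology, topology_or_node, node if mode is None else mode
        if mode is None:
            raise TypeError("mode is required")
    if mode not in ("OE", "DE"):
        raise ValueError(f"mode must be 'OE' or 'DE', got {mode!r}")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    idx = topology.node_index(node_name)  # raises for unknown node
    factor = fold if mode == "OE" else 1.0 / fold
    if isinstance(target, ParameterRanges):
        lo, hi = target.production_range(node_name)
        overrides = dict(target.production_overrides)
        overrides[node_name] = (lo * factor, hi * factor)
        return replace(target, production_overrides=overrides)
    g = target.g.copy()
    g[idx] *= factor
    return replace(target, g=g)


def _attainable_high(topology: NetworkTopology, g: np.ndarray, k: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """1.5x the maximal steady level per node: g/k times incoming activation folds."""
    _, tgt, sign = topology.edge_arrays()
    gain = np.ones_like(g)
    for e in range(topology.n_edges):
        if sign[e] > 0:
            gain[..., tgt[e]] = gain[..., tgt[e]] * lam[..., e]
    return 1.5 * g / k * gain


def _sample_initial_conditions(
    topology: NetworkTopology,
    g: np.ndarray,  # (..., N) per-run arrays (already repeated per IC)
    k: np.ndarray,
    lam: np.ndarray,
    config: EnsembleConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    hi = _attainable_high(topology, g, k, lam)
    if config.ic_mode == "uniform":
        return rng.uniform(0.0, hi)
    if config.ic_mode != "loguniform":
        raise ValueError(f"unknown ic_mode {config.ic_mode!r}")
    lo = np.full_like(hi, config.ic_floor)
    return np.exp(rng.uniform(np.log(lo), np.log(hi)))


def _merge_states(log2_states: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Greedy clustering of converged endpoints in log2 space.

    Two states are identical when their max per-node |delta log2| is
    below ``tol``.  The first endpoint of each cluster is the
    representative; returns (representatives, cluster sizes).
    """
    reps: list[np.ndarray] = []
    counts: list[int] = []
    for row in log2_states:
        for j, rep in enumerate(reps):
            if np.max(np.abs(row - rep)) < tol:
                counts[j] += 1
                break
        else:
            reps.append(row)
            counts.append(1)
    return np.array(reps), np.array(counts)


def _integrate_batch(topology, g, k, lam, hill_n, x0, x_init, config):
    src, tgt, _ = topology.edge_arrays()
    max_steps = int(round(config.t_max / config.dt))
    check_every = max(1, int(round(config.convergence_window / config.dt)))
    return _kernels.integrate_to_steady(
        x_init,
        g,
        k,
        src,
        tgt,
        lam,
        hill_n.astype(np.int64),
        x0,
        config.dt,
        max_steps,
        check_every,
        config.convergence_tol,
    )


def find_steady_states(
    topology: NetworkTopology,
    params: KineticParameterSet,
    config: EnsembleConfig,
) -> tuple[np.ndarray, int]:
    """Distinct stable steady states (log2 scale) of one model.

    Integrates from ``num_initial_conditions`` random starts spread
    over the attainable level range (see :class:`EnsembleConfig`) and
    merges converged endpoints.  Returns ``(states_log2,
    n_nonconverged)``; states may be empty.
    """
    rng = np.random.default_rng(config.seed)
    n_ic = config.num_initial_conditions
    tile = lambda a: np.broadcast_to(a, (n_ic,) + a.shape).copy()
    g, k, lam = tile(params.g), tile(params.k), tile(params.lam)
    x_init = _sample_initial_conditions(topology, g, k, lam, config, rng)
    endpoints, converged = _integrate_batch(
        topology, g, k, lam, tile(params.hill_n), tile(params.x0), x_init, config,
    )
    n_bad = int((~converged).sum())
    good = endpoints[converged]
    if good.size == 0:
        warnings.warn("no initial condition converged for this parameter set")
        return np.empty((0, topology.n_nodes)), n_bad
    log2_states = np.log2(np.maximum(good, 1e-12))
    reps, _ = _merge_states(log2_states, config.merge_tol_log2)
    return reps, n_bad


def z_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Per-column z-scores ``(S - mean) / sd`` with population sd.

    Raises for columns with zero spread (z-score undefined).
    """
    if len(values) < 2:
        raise ValueError("need at least 2 solutions to z-normalize")
    mean = values.mean(axis=0)
    std = values.std(axis=0, ddof=0)
    bad = std[std == 0]
    if len(bad):
        raise ValueError(f"zero variance for node(s): {', '.join(map(str, bad.index))}")
    return (values - mean) / std


def run_ensemble(
    topology: NetworkTopology,
    ranges: ParameterRanges | None = None,
    config: EnsembleConfig | None = None,
) -> EnsembleResult:
    """Full random-kinetics ensemble: sample, integrate, pool, z-score."""
    ranges = ranges or ParameterRanges()
    config = config or EnsembleConfig()
    rng = np.random.default_rng(config.seed)
    M, N = config.num_models, topology.n_nodes
    n_ic = config.num_initial_conditions
    params = sample_ensemble_parameters(topology, ranges, M, rng)

    rep = lambda a: np.repeat(a, n_ic, axis=0)
    g, k, lam = rep(params.g), rep(params.k), rep(params.lam)
    x_init = _sample_initial_conditions(topology, g, k, lam, config, rng)
    endpoints, converged = _integrate_batch(
        topology, g, k, lam, rep(params.hill_n), rep(params.x0), x_init, config,
    )

    rows: list[np.ndarray] = []
    model_idx: list[int] = []
    num_states: list[int] = []
    n_dropped = 0
    n_nonconverged = int((~converged).sum())
    for m in range(M):
        sl = slice(m * n_ic, (m + 1) * n_ic)
        good = endpoints[sl][converged[sl]]
        if good.shape[0] == 0:
            continue
        log2_states = np.log2(np.maximum(good, 1e-12))
        reps, _ = _merge_states(log2_states, config.merge_tol_log2)
        if reps.shape[0] > config.max_states:
            n_dropped += 1
            continue
        for r in reps:
            rows.append(r)
            model_idx.append(m)
            num_states.append(reps.shape[0])
    if not rows:
        raise RuntimeError("ensemble produced no converged solutions")

    log2_df = pd.DataFrame(rows, columns=[f"{n}_log2" for n in topology.nodes])
    mean = log2_df.mean(axis=0)
    std = log2_df.std(axis=0, ddof=0)
    z = z_normalize(log2_df)
    z.columns = [f"{n}_z" for n in topology.nodes]
    solutions = pd.concat(
        [pd.DataFrame({"model_index": model_idx, "num_states": num_states}), log2_df, z],
        axis=1,
    )
    return EnsembleResult(
        topology=topology,
        config=config,
        solutions=solutions,
        log2_mean=pd.Series(mean.values, index=topology.nodes),
        log2_std=pd.Series(std.values, index=topology.nodes),
        params=params,
        n_models_retained=int(pd.Series(model_idx).nunique()),
        n_models_dropped_multistate=n_dropped,
        n_runs_nonconverged=n_nonconverged,
    )


def steady_state_residuals(params: KineticParameterSet, states_log2: np.ndarray) -> np.ndarray:
    """|g*prodHs - k*X| per node for each reported state (linear scale)."""
    src, tgt, _ = params.topology.edge_arrays()
    out = np.empty_like(states_log2)
    for r, row in enumerate(np.atleast_2d(states_log2)):
        x = np.power(2.0, row)
        out[r] = np.abs(
            _kernels.hill_product(
                x, params.g, params.k, src, tgt, params.lam,
                params.hill_n.astype(np.int64), params.x0,
            )
        )
    return out
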