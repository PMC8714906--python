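"""Stochastic dynamics of one parameter set and pseudo-potential landscapes.

Trajectories follow the Euler-Maruyama update

    X_i(t + dt) = X_i(t) + dt * (g_i * prod Hs - k_i * X_i)
                + sigma_i * sqrt(dt) * N(0, 1)

with reflection at zero (concentrations stay non-negative).  Node
levels are projected onto the (EM score, PD-L1 z) plane using the mean
and standard deviation of the deterministic ensemble, so stochastic
states land in the same coordinates as the steady-state solutions.
The pseudo-potential over that plane is U = -log(P) with P the
occupancy histogram of the trajectories after burn-in; its valleys mark
the (meta)stable phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _kernels
from .networks import NetworkTopology
from .phenotyping import EM_SCORE, PhenotypeThresholds, ScoreDefinition, classify_em
from .racipe import EnsembleConfig, EnsembleResult, KineticParameterSet

__all__ = [
    "SDEConfig",
    "TrajectoryBundle",
    "LandscapeGrid",
    "simulate_em",
    "find_tristable_candidates",
    "select_tristable_model",
    "build_landscape",
    "find_landscape_minima",
    "detect_switches",
]


@dataclass(frozen=True)
class SDEConfig:
    """Settings for the Euler-Maruyama simulation.

    ``noise_level`` is the additive noise amplitude applied to every
    node (the update rule's noise term has unit amplitude; the level
    scales it, e.g. for a noise ladder).  An explicit per-node
    ``sigma`` array overrides it.
    """

    dt: float = 0.1
    t_max: float = 2000.0
    noise_level: float = 1.0
    sigma: np.ndarray | None = None
    num_trajectories: int = 100
    record_stride: int = 10
    burn_in_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.noise_level < 0:
            raise ValueError("noise amplitude must be >= 0")
        if self.sigma is not None and np.any(np.asarray(self.sigma) < 0):
            raise ValueError("noise amplitude must be >= 0")


@dataclass
class TrajectoryBundle:
    """Recorded stochastic trajectories plus the projection machinery."""

    topology: NetworkTopology
    times: np.ndarray  # (n_rec,)
    levels: np.ndarray  # (n_traj, n_rec, n_nodes), linear scale
    config: SDEConfig

    def z_levels(self, log2_mean: pd.Series, log2_std: pd.Series) -> np.ndarray:
        """Per-node z-scores under the ensemble normalization."""
        log2 = np.log2(np.maximum(self.levels, 1e-12))
        mean = log2_mean.reindex(list(self.topology.nodes)).to_numpy()
        std = log2_std.reindex(list(self.topology.nodes)).to_numpy()
        return (log2 - mean) / std

    def scores(
        self,
        log2_mean: pd.Series,
        log2_std: pd.Series,
        definition: ScoreDefinition = EM_SCORE,
        pdl1_node: str = "PDL1",
    ) -> tuple[np.ndarray, np.ndarray]:
        """(EM score, PD-L1 z) series of shape (n_traj, n_rec)."""
        z = self.z_levels(log2_mean, log2_std)
        nodes = list(self.topology.nodes)
        score = np.zeros(z.shape[:2])
        for node, w in definition.weights.items():
            score += w * z[..., nodes.index(node)]
        return score, z[..., nodes.index(pdl1_node)]


def simulate_em(
    topology: NetworkTopology,
    params: KineticParameterSet,
    config: SDEConfig,
    x_init: np.ndarray | None = None,
) -> TrajectoryBundle:
    """Euler-Maruyama trajectories from random initial conditions.

    Initial conditions are spread log-uniformly over the attainable
    level range unless supplied explicitly.  With ``noise_level = 0``
    (and no explicit sigma) the trajectories coincide exactly with
    deterministic Euler integration.
    """
    from .racipe import _attainable_high

    rng = np.random.default_rng(config.seed)
    if x_init is None:
        hi = _attainable_high(topology, params.g, params.k, params.lam)
        lo = np.full_like(hi, 1e-2)
        x_init = np.exp(
            rng.uniform(
                np.log(lo)[None, :],
                np.log(hi)[None, :],
                size=(config.num_trajectories, topology.n_nodes),
            )
        )
    sigma = (
        np.asarray(config.sigma, dtype=float)
        if config.sigma is not None
        else np.full(topology.n_nodes, config.noise_level)
    )
    n_steps = int(round(config.t_max / config.dt))
    src, tgt, _ = topology.edge_arrays()
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    levels = _kernels.simulate_sde(
        np.ascontiguousarray(x_init, dtype=float),
        params.g,
        params.k,
        src,
        tgt,
        params.lam,
        params.hill_n.astype(np.int64),
        params.x0,
        sigma,
        config.dt,
        n_steps,
        config.record_stride,
        kernel_seed,
    )
    times = np.arange(levels.shape[1]) * config.dt * config.record_stride
    return TrajectoryBundle(topology, times, levels, config)


def find_tristable_candidates(
    ensemble: EnsembleResult,
    thresholds: PhenotypeThresholds = PhenotypeThresholds(),
    pdl1_cut: float | None = None,
    min_separation: float = 0.3,
) -> pd.DataFrame:
    """Models whose three states are (E, PD-L1 low), (Hybrid, PD-L1
    high), (Mesenchymal, PD-L1 high), ranked by state separation.

    Classification uses the global ensemble z-normalization, so each
    candidate is judged in the same coordinates as the whole ensemble.
    ``min_separation`` (pairwise Euclidean distance in the (EM, PD-L1 z)
    plane) filters out models whose basins an occupancy landscape could
    not resolve.  Returns columns ``model_index`` and ``separation``,
    best first.
    """
    import dataclasses

    from .phenotyping import annotate_solutions

    if pdl1_cut is not None:
        thresholds = dataclasses.replace(thresholds, pdl1_cut=pdl1_cut)
    table = annotate_solutions(ensemble.solutions, thresholds)
    want = {("Epithelial", False), ("Hybrid", True), ("Mesenchymal", True)}
    tri = table[table["num_states"] == 3]
    rows = []
    for m, grp in tri.groupby("model_index"):
        got = set(zip(grp["em_label"], grp["pdl1_high"]))
        if got != want:
            continue
        pts = grp[["em_score", "pdl1_z"]].to_numpy()
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        sep = float(d[np.triu_indices(3, 1)].min())
        if sep >= min_separation:
            rows.append({"model_index": int(m), "separation": sep})
    out = pd.DataFrame(rows, columns=["model_index", "separation"])
    return out.sort_values(["separation", "model_index"],
                           ascending=[False, True], ignore_index=True)


def select_tristable_model(
    ensemble: EnsembleResult,
    thresholds: PhenotypeThresholds = PhenotypeThresholds(),
    pdl1_cut: float | None = None,
    min_separation: float = 0.3,
) -> tuple[int, KineticParameterSet]:
    """The best-separated model qualifying under
    :func:`find_tristable_candidates` (ties broken by model index)."""
    cands = find_tristable_candidates(ensemble, thresholds, pdl1_cut, min_separation)
    if cands.empty:
        raise LookupError(
            "no tristable (E/PD-L1-low, H/PD-L1-high, M/PD-L1-high) parameter set "
            "found; increase the ensemble size"
        )
    m = int(cands.loc[0, "model_index"])
    return m, ensemble.params.model(m)


@dataclass
class LandscapeGrid:
    """Occupancy probability and pseudo-potential over (EM, PD-L1 z)."""

    em_edges: np.ndarray
    pdl1_edges: np.ndarray
    probability: np.ndarray  # (n_em, n_pdl1), sums to 1
    potential: np.ndarray  # -log(P) where P > 0, NaN elsewhere

    @property
    def em_centers(self) -> np.ndarray:
        return 0.5 * (self.em_edges[:-1] + self.em_edges[1:])

    @property
    def pdl1_centers(self) -> np.ndarray:
        return 0.5 * (self.pdl1_edges[:-1] + self.pdl1_edges[1:])


def build_landscape(
    em: np.ndarray,
    pdl1: np.ndarray,
    bins: int = 60,
    burn_in_frac: float = 0.1,
    pad_frac: float = 0.05,
) -> LandscapeGrid:
    """Pseudo-potential U = -log(P) from trajectory occupancy.

    The first ``burn_in_frac`` of each trajectory is discarded; the
    grid covers the observed range padded by ``pad_frac``.  Unoccupied
    bins keep U = NaN rather than an artificial finite value.
    """
    em = np.atleast_2d(em)
    pdl1 = np.atleast_2d(pdl1)
    start = int(burn_in_frac * em.shape[1])
    x = em[:, start:].ravel()
    y = pdl1[:, start:].ravel()
    if x.size == 0:
        raise ValueError("no samples after burn-in")

    def _edges(v):
        # clip to central quantiles: rare excursions toward zero
        # concentration are extreme outliers on a log projection and
        # would stretch the grid until real basins blur together
        lo, hi = np.quantile(v, [0.005, 0.995])
        if hi <= lo:
            lo, hi = float(v.min()), float(v.max())
        pad = pad_frac * (hi - lo if hi > lo else 1.0)
        return np.linspace(lo - pad, hi + pad, bins + 1)

    ex, ey = _edges(x), _edges(y)
    hist, _, _ = np.histogram2d(x, y, bins=(ex, ey))
    if (hist > 0).sum() < 2:
        raise ValueError("trajectories occupy fewer than 2 bins")
    prob = hist / hist.sum()
    with np.errstate(divide="ignore"):
        potential = np.where(prob > 0, -np.log(prob), np.nan)
    return LandscapeGrid(ex, ey, prob, potential)


def find_landscape_minima(
    grid: LandscapeGrid,
    smooth_sigma: float = 2.0,
    min_height_frac: float = 0.05,
) -> pd.DataFrame:
    """Valleys of the pseudo-potential (= peaks of smoothed occupancy).

    The occupancy is Gaussian-smoothed (``smooth_sigma`` in bins) to
    absorb histogram noise; a valley is a strict local maximum of the
    smoothed density above ``min_height_frac`` of its global maximum.
    Returns one row per valley with (em, pdl1) coordinates, sorted by
    occupancy.
    """
    dens = ndimage.gaussian_filter(grid.probability, smooth_sigma)
    footprint = np.ones((3, 3), dtype=bool)
    local_max = dens == ndimage.maximum_filter(dens, footprint=footprint, mode="nearest")
    local_max &= dens > min_height_frac * dens.max()
    # plateaus at the border of the filter produce duplicate flags; keep
    # one representative per connected component
    labels, n = ndimage.label(local_max)
    rows = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        i, j = idx[np.argmax(dens[idx[:, 0], idx[:, 1]])]
        rows.append(
            {
                "em": grid.em_centers[i],
                "pdl1": grid.pdl1_centers[j],
                "density": dens[i, j],
                "probability": grid.probability[i, j],
            }
        )
    out = pd.DataFrame(rows).sort_values("density", ascending=False, ignore_index=True)
    return out


def classify_minima(
    minima: pd.DataFrame,
    thresholds: PhenotypeThresholds = PhenotypeThresholds(),
    pdl1_cut: float = 0.0,
    state_coords: np.ndarray | None = None,
) -> pd.DataFrame:
    """Attach (EM label, PD-L1 high) phenotype calls to landscape valleys.

    With ``state_coords`` (the deterministic steady states in the (EM,
    PD-L1 z) plane), each valley is snapped to its nearest steady state
    before labelling: noise skews occupancy maxima slightly away from
    the underlying attractor, and the attractor is what the valley
    represents.
    """
    out = minima.copy()
    em, pdl1 = out["em"].to_numpy(), out["pdl1"].to_numpy()
    if state_coords is not None:
        centers = np.asarray(state_coords, dtype=float)
        pts = np.stack([em, pdl1], axis=1)
        nearest = np.argmin(
            np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2), axis=1
        )
        out["state_index"] = nearest
        em, pdl1 = centers[nearest, 0], centers[nearest, 1]
    out["em_label"] = [classify_em(v, thresholds) for v in em]
    out["pdl1_high"] = pdl1 > pdl1_cut
    return out


def detect_switches(
    em: np.ndarray,
    pdl1: np.ndarray,
    centers: np.ndarray,
    r_in: float | None = None,
) -> pd.DataFrame:
    """State-switching events along (EM, PD-L1) trajectories.

    Each recorded point is assigned to a state only when it comes
    within ``r_in`` of that state's center (hysteresis band); between
    bands the previous assignment persists.  An event is a change of
    assignment.  Returns events with trajectory index, record index and
    from/to state labels.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[0] < 2:
        raise ValueError("need at least 2 state centers")
    if r_in is None:
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
        r_in = 0.45 * float(d[np.triu_indices(len(centers), 1)].min())
    em = np.atleast_2d(em)
    pdl1 = np.atleast_2d(pdl1)
    events = []
    for t in range(em.shape[0]):
        pts = np.stack([em[t], pdl1[t]], axis=1)
        d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
        nearest = np.argmin(d, axis=1)
        inside = d[np.arange(len(pts)), nearest] <= r_in
        state = -1
        for r in range(len(pts)):
            if inside[r]:
                new = int(nearest[r])
                if state != -1 and new != state:
                    events.append(
                        {"trajectory": t, "record": r, "from_state": state, "to_state": new}
                    )
                state = new
    return pd.DataFrame(events, columns=["trajectory", "record", "from_state", "to_state"])
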