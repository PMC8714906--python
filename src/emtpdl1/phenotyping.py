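"""Scores, phenotype labels and ensemble statistics for z-scored solutions.

The EM score ``(ZEB1 + SLUG - miR200 - CDH1)/4`` maps each steady state
onto the epithelial-mesenchymal axis; solutions are labelled epithelial
(score < -0.25), hybrid (-0.25 to 0.5, boundaries inclusive) or
mesenchymal (> 0.5).  A stemness score ``(LIN28 + OCT4 - let7 -
miR145)/4`` with a stem-like window [-0.5, 0.5] and a tamoxifen
resistance score ``ERa36 - ERa66`` (resistant > 0) play the same role
for the extended networks.  PD-L1 states are split into high/low at a
two-component Gaussian-mixture boundary fitted to the bimodal
distribution of its z-scores (or a fixed cut via configuration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "ScoreDefinition",
    "PhenotypeThresholds",
    "EM_SCORE",
    "SN_SCORE",
    "RESISTANCE_SCORE",
    "compute_score",
    "classify_em",
    "classify_stem",
    "fit_binary_cutpoint",
    "annotate_solutions",
    "conditional_probability",
    "replicate_conditionals",
    "spearman_matrix",
    "hybrid_subphenotypes",
    "count_kde_modes",
    "phenotype_fractions",
]


@dataclass(frozen=True)
class ScoreDefinition:
    """A named signed-weight combination of per-node z-scores."""

    name: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights or not all(np.isfinite(list(self.weights.values()))):
            raise ValueError("weights must be non-empty and finite")


EM_SCORE = ScoreDefinition(
    "EM", {"ZEB1": 0.25, "SLUG": 0.25, "miR200": -0.25, "CDH1": -0.25}
)
SN_SCORE = ScoreDefinition(
    "SN", {"LIN28": 0.25, "OCT4": 0.25, "let7": -0.25, "miR145": -0.25}
)
RESISTANCE_SCORE = ScoreDefinition("Resistance", {"ERa36": 1.0, "ERa66": -1.0})


@dataclass(frozen=True)
class PhenotypeThresholds:
    """Cutpoints for the categorical phenotype labels."""

    em_epithelial: float = -0.25
    em_mesenchymal: float = 0.5
    sn_window: tuple[float, float] = (-0.5, 0.5)
    resistance_cut: float = 0.0
    pdl1_cut: float | None = None  # None -> fit a Gaussian-mixture boundary

    def __post_init__(self) -> None:
        if self.em_epithelial >= self.em_mesenchymal:
            raise ValueError("EM cutpoints must be ordered")
        if self.sn_window[0] >= self.sn_window[1]:
            raise ValueError("SN window must be ordered")


def _z_columns(table: pd.DataFrame, definition: ScoreDefinition) -> dict[str, str]:
    cols = {}
    for node in definition.weights:
        col = f"{node}_z" if f"{node}_z" in table.columns else node
        if col not in table.columns:
            raise KeyError(f"node {node!r} required by score {definition.name!r} is missing")
        cols[node] = col
    return cols


def compute_score(table: pd.DataFrame, definition: ScoreDefinition) -> pd.Series:
    """Weighted sum of z-scores per solution (row)."""
    cols = _z_columns(table, definition)
    out = sum(w * table[cols[n]] for n, w in definition.weights.items())
    out.name = definition.name
    return out


def classify_em(scores, thresholds: PhenotypeThresholds = PhenotypeThresholds()):
    """Label EM scores as Epithelial / Hybrid / Mesenchymal.

    Boundary values fall in the Hybrid class (the hybrid interval is
    closed; the epithelial and mesenchymal inequalities are strict).
    """
    s = np.asarray(scores, dtype=float)
    labels = np.where(
        s < thresholds.em_epithelial,
        "Epithelial",
        np.where(s > thresholds.em_mesenchymal, "Mesenchymal", "Hybrid"),
    )
    if np.ndim(scores) == 0:
        return labels.item()
    return pd.Series(labels, index=getattr(scores, "index", None), name="em_label")


def classify_stem(scores, thresholds: PhenotypeThresholds = PhenotypeThresholds()):
    """True where the SN score falls inside the stem-like window."""
    lo, hi = thresholds.sn_window
    s = np.asarray(scores, dtype=float)
    mask = (s >= lo) & (s <= hi)
    if np.ndim(scores) == 0:
        return bool(mask)
    return pd.Series(mask, index=getattr(scores, "index", None), name="stem_like")


def fit_binary_cutpoint(values, min_separation: float = 2.0) -> float:
    """High/low boundary of a bimodal sample via a 2-component GMM.

    Returns the equal-posterior point between the two component means.
    If the mixture is degenerate (components closer than
    ``min_separation`` pooled standard deviations, Ashman's D), falls
    back to 0 with a warning.
    """
    from sklearn.mixture import GaussianMixture

    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if v.shape[0] < 50:
        raise ValueError("need at least 50 values to fit a mixture cutpoint")
    gm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(v)
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(mu)
    mu, sd = mu[order], sd[order]
    ashman_d = np.sqrt(2.0) * abs(mu[1] - mu[0]) / np.sqrt(sd[0] ** 2 + sd[1] ** 2)
    if ashman_d < min_separation:
        warnings.warn("mixture components overlap; falling back to cutpoint 0")
        return 0.0
    grid = np.linspace(mu[0], mu[1], 512).reshape(-1, 1)
    post = gm.predict_proba(grid)[:, order]
    crossing = np.argmin(np.abs(post[:, 1] - post[:, 0]))
    return float(grid[crossing, 0])


def annotate_solutions(
    table: pd.DataFrame,
    thresholds: PhenotypeThresholds = PhenotypeThresholds(),
    scores: tuple[ScoreDefinition, ...] = (EM_SCORE,),
    pdl1_node: str = "PDL1",
) -> pd.DataFrame:
    """Attach scores and categorical labels to a z-scored solution table.

    Adds ``em_score``/``em_label`` and ``pdl1_z``/``pdl1_high`` always;
    ``sn_score``/``stem_like`` and ``resistance_score``/``resistant``
    when the corresponding definitions are requested.
    """
    out = table.copy()
    for definition in scores:
        s = compute_score(out, definition)
        if definition.name == "EM":
            out["em_score"] = s
            out["em_label"] = classify_em(s, thresholds)
        elif definition.name == "SN":
            out["sn_score"] = s
            out["stem_like"] = classify_stem(s, thresholds)
        elif definition.name == "Resistance":
            out["resistance_score"] = s
            out["resistant"] = s > thresholds.resistance_cut
        else:
            out[definition.name] = s
    pdl1_col = f"{pdl1_node}_z" if f"{pdl1_node}_z" in out.columns else pdl1_node
    if pdl1_col in out.columns:
        out["pdl1_z"] = out[pdl1_col]
        cut = thresholds.pdl1_cut
        if cut is None:
            cut = fit_binary_cutpoint(out[pdl1_col].to_numpy())
        out["pdl1_high"] = out[pdl1_col] > cut
        out.attrs["pdl1_cut"] = float(cut)
    return out


def conditional_probability(
    table: pd.DataFrame, condition: str, given: str
) -> pd.DataFrame:
    """P(condition | given-class) with counts, per class of ``given``.

    Classes present in the table but empty after filtering are
    impossible by construction; classes passed via a categorical with
    unobserved levels get ``NaN`` probability and ``undefined=True``.
    """
    groups = table.groupby(given, observed=False)[condition]
    counts = groups.size()
    hits = groups.sum()
    prob = hits / counts
    return pd.DataFrame(
        {
            "n": counts,
            "n_condition": hits,
            "probability": prob,
            "undefined": counts == 0,
        }
    )


def replicate_conditionals(
    tables: list[pd.DataFrame], condition: str, given: str
) -> pd.DataFrame:
    """Mean and standard deviation of conditionals over replicate runs."""
    reps = [conditional_probability(t, condition, given)["probability"] for t in tables]
    stacked = pd.concat(reps, axis=1)
    return pd.DataFrame(
        {
            "mean": stacked.mean(axis=1),
            "sd": stacked.std(axis=1, ddof=0),
            "n_replicates": stacked.notna().sum(axis=1),
        }
    )


def spearman_matrix(table: pd.DataFrame, nodes: list[str]) -> pd.DataFrame:
    """Pairwise Spearman rank correlations of per-node z-scores."""
    if len(table) < 3:
        raise ValueError("need at least 3 solutions for a correlation matrix")
    cols = {n: (f"{n}_z" if f"{n}_z" in table.columns else n) for n in nodes}
    data = table[[cols[n] for n in nodes]].to_numpy(dtype=float)
    constant = data.std(axis=0) == 0
    rho = stats.spearmanr(data).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=nodes, columns=nodes)


_BINARIZE_NODES = ("ZEB1", "SLUG", "CDH1")


def hybrid_subphenotypes(
    table: pd.DataFrame, nodes: tuple[str, ...] = _BINARIZE_NODES
) -> pd.DataFrame:
    """Binarized marker combinations within the hybrid compartment.

    Each hybrid solution is assigned one of the 2^len(nodes)
    combinations (node high iff its z-score > 0).  Returns per
    combination the fraction of hybrids and P(PD-L1 high | combination),
    sorted by abundance.
    """
    hybrids = table[table["em_label"] == "Hybrid"]
    if hybrids.empty:
        raise ValueError("hybrid compartment is empty")
    combo = pd.Series("", index=hybrids.index)
    for n in nodes:
        col = f"{n}_z" if f"{n}_z" in hybrids.columns else n
        combo = combo + n + np.where(hybrids[col] > 0, "+", "-")
    out = pd.DataFrame(
        {
            "n": combo.value_counts(),
            "fraction": combo.value_counts(normalize=True),
        }
    )
    if "pdl1_high" in hybrids.columns:
        out["p_pdl1_high"] = hybrids.groupby(combo)["pdl1_high"].mean()
    return out.sort_values("fraction", ascending=False)


def count_kde_modes(scores, prominence_frac: float = 0.05) -> int:
    """Number of modes of a Gaussian KDE (Silverman bandwidth).

    A mode is a local maximum of the density with prominence above
    ``prominence_frac`` of the peak density.
    """
    v = np.asarray(scores, dtype=float)
    if v.size < 100:
        raise ValueError("need at least 100 values for mode counting")
    kde = stats.gaussian_kde(v, bw_method="silverman")
    pad = 0.05 * (v.max() - v.min())
    grid = np.linspace(v.min() - pad, v.max() + pad, 1024)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, prominence=prominence_frac * dens.max())
    return int(len(peaks))


def phenotype_fractions(table: pd.DataFrame) -> pd.Series:
    """Fractions of Epithelial / Hybrid / Mesenchymal solutions."""
    return (
        table["em_label"]
        .value_counts(normalize=True)
        .reindex(["Epithelial", "Hybrid", "Mesenchymal"], fill_value=0.0)
    )
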