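"""Gene-set activity scoring and EMT-axis quantification for expression data.

Expression matrices are plain pandas DataFrames (genes x samples,
log-scale values).  Two rank-based per-sample activity scores are
provided: a single-sample GSEA style score (integrated difference
between the weighted cumulative distribution of set members, weight =
rank value^alpha with alpha = 0.25, and the uniform cumulative
distribution of non-members, min-max normalized across samples) and an
AUCell-style score (area under the recovery curve of set genes within
the top-ranked fraction of the genome, normalized to [0, 1]).  Both are
invariant to strictly monotone transformations of a sample's values.

On top of the scorers sit the 2D epithelial/mesenchymal coordinates
(independent activity of an E and an M gene program), the derivation of
an anchor-correlated gene signature replicated across cohorts, and the
linear-versus-saturating (Michaelis-Menten) association fit compared by
adjusted R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GeneSet",
    "FitResult",
    "read_expression_tsv",
    "read_expression_mtx",
    "read_gene_set",
    "read_gmt",
    "ssgsea_score",
    "auc_score",
    "em_2d_coordinates",
    "derive_signature",
    "fit_linear_vs_saturating",
]


@dataclass(frozen=True)
class GeneSet:
    """A named list of member genes.

    Members are unique; an empty set is representable (e.g. a signature
    derivation that recovered nothing) but is rejected by the scorers.
    """

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class FitResult:
    """One fitted association model with its goodness of fit."""

    form: str  # "linear" or "saturating"
    params: dict[str, float]
    r_squared: float
    adjusted_r_squared: float
    residual_sd: float
    converged: bool = True


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes-by-samples TSV with gene names in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicate gene or sample names in {path}")
    if df.isna().any().any():
        raise ValueError(f"missing values in expression matrix {path}")
    return df


def read_expression_mtx(
    mtx_path: str | Path, genes_path: str | Path, samples_path: str | Path
) -> pd.DataFrame:
    """MatrixMarket matrix plus one-name-per-line gene/sample indexes."""
    from scipy.io import mmread

    m = mmread(str(mtx_path))
    if hasattr(m, "toarray"):
        m = m.toarray()
    m = np.asarray(m)
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    if m.shape != (len(genes), len(samples)):
        raise ValueError("matrix shape does not match gene/sample index lengths")
    return pd.DataFrame(m, index=genes, columns=samples)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """One gene per line, comments (#) and blanks ignored."""
    genes = [
        g.strip()
        for g in Path(path).read_text().splitlines()
        if g.strip() and not g.startswith("#")
    ]
    return GeneSet(name or Path(path).stem, tuple(genes))


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT format: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets.append(GeneSet(parts[0], tuple(dict.fromkeys(parts[2:]))))
    return sets


def _member_mask(matrix: pd.DataFrame, gene_set: GeneSet) -> np.ndarray:
    mask = matrix.index.isin(gene_set.genes)
    if not mask.any():
        raise ValueError(
            f"gene set {gene_set.name!r} has no overlap with the expression matrix"
        )
    return mask


def ssgsea_score(
    matrix: pd.DataFrame,
    gene_set: GeneSet,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.Series:
    """Single-sample gene-set enrichment score per sample.

    Per sample, genes are ranked by expression (descending, average
    ranks for ties give each gene a rank value in [1, N] with N the
    most expressed).  Walking down the ranking, the score integrates
    the difference between the rank-value^alpha weighted ECDF of set
    members and the uniform ECDF of non-members.  With ``normalize``
    (and >= 2 samples) scores are min-max scaled across samples.
    """
    mask = _member_mask(matrix, gene_set)
    values = matrix.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    n_out = (~mask).sum()
    scores = np.empty(n_samples)
    # rank value: N for the most expressed gene, averaged over ties
    ranks = stats.rankdata(values, axis=0, method="average")
    for s in range(n_samples):
        order = np.argsort(-values[:, s], kind="stable")
        in_set = mask[order]
        w = ranks[order, s] ** alpha
        w[~in_set] = 0.0
        cum_in = np.cumsum(w)
        total_in = cum_in[-1]
        cum_out = np.cumsum(~in_set) / max(n_out, 1)
        scores[s] = np.sum(cum_in / total_in - cum_out)
    out = pd.Series(scores, index=matrix.columns, name=gene_set.name)
    if normalize and n_samples >= 2:
        lo, hi = out.min(), out.max()
        if hi > lo:
            out = (out - lo) / (hi - lo)
    return out


def auc_score(
    matrix: pd.DataFrame, gene_set: GeneSet, top_fraction: float = 0.05
) -> pd.Series:
    """Area under the top-rank recovery curve of set genes, in [0, 1].

    Per sample, genes are ranked descending by expression; the recovery
    curve counts set genes found among the top ``k = ceil(top_fraction
    * N)`` ranks.  The area is normalized by the maximal area a perfect
    ranking (all set genes first) would attain.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    mask = _member_mask(matrix, gene_set)
    values = matrix.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    k = int(np.ceil(top_fraction * n_genes))
    n_set = int(mask.sum())
    # AUC of the step recovery curve evaluated after each of the k ranks
    ideal_hits = np.minimum(np.arange(1, k + 1), n_set)
    max_area = ideal_hits.sum()
    scores = np.empty(n_samples)
    for s in range(n_samples):
        order = np.argsort(-values[:, s], kind="stable")
        hits = np.cumsum(mask[order][:k])
        scores[s] = hits.sum() / max_area
    return pd.Series(scores, index=matrix.columns, name=gene_set.name)


_SCORERS = {"ssgsea": ssgsea_score, "auc": auc_score}


def em_2d_coordinates(
    matrix: pd.DataFrame,
    e_set: GeneSet,
    m_set: GeneSet,
    scorer: str = "ssgsea",
) -> pd.DataFrame:
    """Independent epithelial and mesenchymal activity per sample.

    The two programs are scored separately (no forced anti-correlation)
    so gain of mesenchymal and loss of epithelial character can be
    tracked as separate moves on the 2D plane.
    """
    try:
        fn = _SCORERS[scorer]
    except KeyError:
        raise ValueError(f"unknown scorer {scorer!r}; use one of {sorted(_SCORERS)}")
    return pd.DataFrame({"E": fn(matrix, e_set), "M": fn(matrix, m_set)})


def _spearman_vs_anchor(matrix: pd.DataFrame, anchor: str):
    """Spearman rho and t-approximation p-value of every gene vs the anchor."""
    ranks = matrix.rank(axis=1, method="average").to_numpy(dtype=float)
    a = matrix.index.get_loc(anchor)
    ra = ranks[a]
    n = ranks.shape[1]
    ra_c = ra - ra.mean()
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((rc**2).sum(axis=1) * (ra_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ ra_c) / denom
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return pd.Series(rho, index=matrix.index), pd.Series(p, index=matrix.index)


def derive_signature(
    cohorts: list[pd.DataFrame],
    anchor: str,
    rho_threshold: float = 0.5,
    p_threshold: float = 0.01,
    min_cohorts: int = 15,
) -> GeneSet:
    """Genes robustly rank-correlated with an anchor gene across cohorts.

    A gene enters the signature when its Spearman correlation with the
    anchor exceeds ``rho_threshold`` at ``p < p_threshold`` in at least
    ``min_cohorts`` of the cohorts.  The anchor itself is excluded.
    """
    if min_cohorts > len(cohorts):
        raise ValueError("min_cohorts exceeds the number of cohorts")
    counts: dict[str, int] = {}
    for i, cohort in enumerate(cohorts):
        if anchor not in cohort.index:
            raise KeyError(f"anchor gene {anchor!r} missing from cohort {i}")
        rho, p = _spearman_vs_anchor(cohort, anchor)
        passing = cohort.index[(rho > rho_threshold) & (p < p_threshold)]
        for g in passing:
            counts[g] = counts.get(g, 0) + 1
    if min_cohorts == 0:
        genes = sorted(set(g for cohort in cohorts for g in cohort.index) - {anchor})
    else:
        genes = sorted(g for g, c in counts.items() if c >= min_cohorts and g != anchor)
    return GeneSet(f"{anchor}_associated", tuple(genes))


def _adjusted_r2(y, resid, n_params: int) -> tuple[float, float]:
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    n = len(y)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    return r2, adj


def fit_linear_vs_saturating(x, y) -> tuple[FitResult, FitResult, str]:
    """Fit ``a*x + b`` and ``a*x/(b + x) + c`` and compare by adjusted R^2.

    Returns (linear fit, saturating fit, preferred form).  A
    non-convergent saturating fit is flagged (``converged=False``) and
    the linear model wins by default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2, adj = _adjusted_r2(y, resid, 2)
    linear = FitResult("linear", {"a": slope, "b": intercept}, r2, adj, float(resid.std()))

    def mm(xv, a, b, c):
        return a * xv / (b + xv) + c

    x_shift = x - x.min()  # Michaelis-Menten form needs x >= 0
    try:
        p0 = (np.ptp(y) if np.ptp(y) > 0 else 1.0, max(np.median(x_shift), 1e-3), y.min())
        popt, _ = optimize.curve_fit(
            mm, x_shift, y, p0=p0,
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        resid_s = y - mm(x_shift, *popt)
        r2s, adjs = _adjusted_r2(y, resid_s, 3)
        saturating = FitResult(
            "saturating",
            {"a": popt[0], "b": popt[1], "c": popt[2], "x_offset": float(x.min())},
            r2s, adjs, float(resid_s.std()),
        )
    except (RuntimeError, ValueError):
        saturating = FitResult("saturating", {}, float("nan"), -np.inf, float("nan"), converged=False)

    preferred = "saturating" if saturating.adjusted_r_squared > linear.adjusted_r_squared else "linear"
    return linear, saturating, preferred
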