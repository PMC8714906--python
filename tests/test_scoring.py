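import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emtpdl1 as ep
from emtpdl1.scoring import (
    GeneSet,
    auc_score,
    derive_signature,
    em_2d_coordinates,
    fit_linear_vs_saturating,
    read_expression_mtx,
    read_expression_tsv,
    read_gene_set,
    read_gmt,
    ssgsea_score,
)


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


# --------------------------------------------------------------------- ssGSEA

def test_ssgsea_hand_computed_toy_value():
    """5 genes, one sample, set {g0, g2} at expression ranks 1 and 3.

    Walking the descending ranking, the weighted in-set ECDF uses
    rank-value^0.25 weights (5^.25, 3^.25) and the out-set ECDF is
    uniform over the 3 non-members; summing the difference over the 5
    positions gives 1.7304 (hand evaluation).
    """
    m = _matrix([[5.0], [4.0], [3.0], [2.0], [1.0]])
    s = ssgsea_score(m, GeneSet("t", ("g0", "g2")))
    w1, w3 = 5 ** 0.25, 3 ** 0.25
    tot = w1 + w3
    expected = (w1 / tot - 0) + (w1 / tot - 1 / 3) + (1 - 1 / 3) + (1 - 2 / 3) + 0
    assert s.iloc[0] == pytest.approx(expected)
    assert s.iloc[0] == pytest.approx(1.7304, abs=1e-3)


def test_ssgsea_extreme_orderings_attain_bounds():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(50, 5))
    m = _matrix(base)
    gs = GeneSet("t", tuple(f"g{i}" for i in range(4)))
    # sample 0: set genes on top; sample 1: set genes at the bottom
    m.iloc[:, 0] = np.arange(50, 0, -1)
    m.iloc[:4, 0] = [100, 99, 98, 97]
    m.iloc[:, 1] = np.arange(50, 0, -1)
    m.iloc[:4, 1] = [-1, -2, -3, -4]
    s = ssgsea_score(m, gs)
    assert s.iloc[0] == pytest.approx(s.max())
    assert s.iloc[1] == pytest.approx(s.min())
    assert s.max() == pytest.approx(1.0) and s.min() == pytest.approx(0.0)


def test_ssgsea_no_overlap_errors():
    with pytest.raises(ValueError, match="overlap"):
        ssgsea_score(_matrix(np.eye(4)), GeneSet("t", ("x", "y")))


# ----------------------------------------------------------------------- AUC

def test_auc_hand_computed_toy_value():
    """100 genes, 4-gene set with 2 members at ranks 1-2, top 5%.

    Recovery counts over the first five ranks are 1,2,2,2,2 (area 9);
    a perfect ranking would give 1,2,3,4,4 (area 14); score 9/14.
    """
    vals = np.arange(100, 0, -1, dtype=float)[:, None]
    m = _matrix(vals)
    gs = GeneSet("t", ("g0", "g1", "g50", "g60"))
    s = auc_score(m, gs, top_fraction=0.05)
    assert s.iloc[0] == pytest.approx(9 / 14)


def test_auc_extremes():
    vals = np.arange(100, 0, -1, dtype=float)[:, None]
    m = _matrix(vals)
    all_top = GeneSet("t", ("g0", "g1", "g2"))
    none_top = GeneSet("b", ("g90", "g91", "g92"))
    assert auc_score(m, all_top, 0.05).iloc[0] == pytest.approx(1.0)
    assert auc_score(m, none_top, 0.05).iloc[0] == 0.0


# ------------------------------------------------------------- rank invariance

@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_scores_invariant_under_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    m = _matrix(rng.normal(size=(40, 4)))
    gs = GeneSet("t", ("g1", "g7", "g13", "g21"))
    transformed = np.exp(m / 3.0) + 1.0
    assert np.allclose(ssgsea_score(m, gs), ssgsea_score(transformed, gs))
    assert np.allclose(auc_score(m, gs, 0.2), auc_score(transformed, gs, 0.2))


def test_scores_ignore_genes_absent_from_matrix():
    rng = np.random.default_rng(1)
    m = _matrix(rng.normal(size=(30, 3)))
    gs = GeneSet("t", ("g1", "g2", "g3"))
    gs_extra = GeneSet("t2", ("g1", "g2", "g3", "NOT_THERE"))
    assert np.allclose(ssgsea_score(m, gs), ssgsea_score(m, gs_extra))
    assert np.allclose(auc_score(m, gs, 0.2), auc_score(m, gs_extra, 0.2))


def test_ssgsea_agrees_with_independent_implementation():
    """Cross-check sample ordering against gseapy's ssGSEA on a random
    matrix: both are rank-based enrichment statistics, so per-set
    sample scores must be strongly rank-correlated."""
    gseapy = pytest.importorskip("gseapy")
    rng = np.random.default_rng(7)
    m = _matrix(np.abs(rng.normal(size=(200, 12))) + 0.1)
    genes = list(m.index)
    gs = {"SET": [genes[i] for i in range(0, 60, 3)]}
    ours = ssgsea_score(m, GeneSet("SET", tuple(gs["SET"])), normalize=False)
    res = gseapy.ssgsea(data=m, gene_sets=gs, outdir=None, sample_norm_method="rank",
                        min_size=1, seed=0, no_plot=True)
    theirs = res.res2d.set_index("Name")["ES"].astype(float).reindex(ours.index)
    from scipy import stats

    rho = stats.spearmanr(ours, theirs).statistic
    assert rho > 0.9


# ---------------------------------------------------------------- 2D EM plane

def test_em_2d_duplicate_sets_give_identical_axes():
    rng = np.random.default_rng(2)
    m = _matrix(rng.normal(size=(50, 6)))
    gs = GeneSet("e", ("g0", "g5", "g10"))
    xy = em_2d_coordinates(m, gs, GeneSet("m", gs.genes), scorer="ssgsea")
    assert np.allclose(xy["E"], xy["M"])


def test_em_2d_null_matrix_axes_uncorrelated():
    rng = np.random.default_rng(3)
    m = _matrix(rng.normal(size=(300, 200)))
    e = GeneSet("e", tuple(f"g{i}" for i in range(0, 30)))
    mm = GeneSet("m", tuple(f"g{i}" for i in range(40, 70)))
    xy = em_2d_coordinates(m, e, mm, scorer="ssgsea")
    from scipy import stats

    assert abs(stats.spearmanr(xy["E"], xy["M"]).statistic) < 0.3


def test_em_2d_unknown_scorer():
    m = _matrix(np.eye(4))
    gs = GeneSet("t", ("g0",))
    with pytest.raises(ValueError, match="scorer"):
        em_2d_coordinates(m, gs, gs, scorer="magic")


# ------------------------------------------------------------------ signature

def _cohorts(seed=0, rho=0.8, n_cohorts=20):
    cfg = ep.GeneratorConfig(seed=seed)
    return ep.generate_cohorts(cfg, n_cohorts=n_cohorts, n_planted=30,
                               planted_correlation=rho, n_null=300, n_samples=100)


def test_signature_recovers_planted_genes():
    sig = derive_signature(_cohorts(), "PDL1", min_cohorts=15)
    planted = [g for g in sig.genes if g.startswith("SIG_")]
    nulls = [g for g in sig.genes if g.startswith("NULL_")]
    assert len(planted) == 30
    assert len(nulls) <= 1
    assert "PDL1" not in sig.genes


def test_signature_null_correlation_recovers_nothing():
    sig = derive_signature(_cohorts(rho=0.0), "PDL1", min_cohorts=15)
    assert len(sig.genes) == 0


def test_signature_monotone_in_replication_and_rho():
    cohorts = _cohorts()
    k15 = set(derive_signature(cohorts, "PDL1", min_cohorts=15).genes)
    k13 = set(derive_signature(cohorts, "PDL1", min_cohorts=13).genes)
    assert k15 <= k13
    strict = set(derive_signature(cohorts, "PDL1", rho_threshold=0.7, min_cohorts=15).genes)
    assert strict <= k15
    everything = derive_signature(cohorts, "PDL1", min_cohorts=0)
    assert set(everything.genes) == set(cohorts[0].index) - {"PDL1"}


def test_signature_missing_anchor_names_cohort():
    cohorts = _cohorts(n_cohorts=3)
    cohorts[1] = cohorts[1].drop(index="PDL1")
    with pytest.raises(KeyError, match="cohort 1"):
        derive_signature(cohorts, "PDL1", min_cohorts=2)


# ----------------------------------------------------------------------- fits

def test_fit_prefers_exact_line():
    x = np.linspace(0, 5, 40)
    y = 2 * x + 1
    lin, sat, pref = fit_linear_vs_saturating(x, y)
    assert pref == "linear"
    assert lin.adjusted_r_squared == pytest.approx(1.0)
    assert lin.params["a"] == pytest.approx(2.0)


def test_fit_recovers_saturating_parameters():
    rng = np.random.default_rng(0)
    x = np.linspace(0.0, 1.0, 80)
    y = 3 * x / (0.2 + x) + 1 + rng.normal(0, 0.05, 80)
    lin, sat, pref = fit_linear_vs_saturating(x, y)
    assert pref == "saturating"
    assert sat.params["a"] == pytest.approx(3.0, rel=0.15)
    assert sat.params["b"] == pytest.approx(0.2, rel=0.15)
    assert sat.params["c"] == pytest.approx(1.0, rel=0.15)


def test_fit_constant_y_degenerate():
    x = np.linspace(0, 1, 20)
    lin, sat, _ = fit_linear_vs_saturating(x, np.ones(20))
    assert lin.r_squared == pytest.approx(0.0, abs=1e-9)


def test_fit_input_validation():
    with pytest.raises(ValueError):
        fit_linear_vs_saturating([1, 2, 3], [1, 2, 3])
    with pytest.raises(ValueError):
        fit_linear_vs_saturating(np.ones(20), np.arange(20.0))


# ------------------------------------------------------------------------- IO

def test_expression_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    m = _matrix(rng.normal(size=(6, 3)))
    p = tmp_path / "expr.tsv"
    m.to_csv(p, sep="\t")
    back = read_expression_tsv(p)
    pd.testing.assert_frame_equal(back, m)


def test_expression_mtx_loader(tmp_path):
    from scipy import io as sio
    from scipy import sparse

    rng = np.random.default_rng(6)
    m = rng.poisson(3, size=(5, 4)).astype(float)
    sio.mmwrite(str(tmp_path / "m.mtx"), sparse.csr_matrix(m))
    (tmp_path / "genes.txt").write_text("\n".join(f"g{i}" for i in range(5)))
    (tmp_path / "samples.txt").write_text("\n".join(f"s{j}" for j in range(4)))
    df = read_expression_mtx(tmp_path / "m.mtx", tmp_path / "genes.txt", tmp_path / "samples.txt")
    assert np.allclose(df.to_numpy(), m)


def test_gene_set_readers(tmp_path):
    (tmp_path / "set.txt").write_text("# comment\nTP53\nCD274\n\nZEB1\n")
    gs = read_gene_set(tmp_path / "set.txt")
    assert gs.genes == ("TP53", "CD274", "ZEB1")
    (tmp_path / "sets.gmt").write_text("S1\tdesc\tA\tB\nS2\tdesc\tC\n")
    sets = read_gmt(tmp_path / "sets.gmt")
    assert [s.name for s in sets] == ["S1", "S2"]
    assert sets[0].genes == ("A", "B")


def test_gene_set_duplicates_rejected():
    with pytest.raises(ValueError):
        GeneSet("d", ("A", "A"))
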