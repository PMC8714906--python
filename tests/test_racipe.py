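import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import emtpdl1 as ep
from emtpdl1.racipe import (
    EnsembleConfig,
    ParameterRanges,
    sample_ensemble_parameters,
    steady_state_residuals,
)

from conftest import make_params


# ---------------------------------------------------------------- shifted Hill

def test_shifted_hill_basal_and_saturating_limits():
    assert ep.shifted_hill(0.0, 5.0, 3, 0.1) == pytest.approx(1.0)
    assert ep.shifted_hill(1e9, 5.0, 3, 0.1) == pytest.approx(0.1, rel=1e-5)
    assert ep.shifted_hill(123.0, 5.0, 2, 1.0) == pytest.approx(1.0)


def test_shifted_hill_halfway_value():
    # at X = X0 with n = 1 the multiplier is lam + (1 - lam)/2
    assert ep.shifted_hill(5.0, 5.0, 1, 0.1) == pytest.approx(0.55)


def test_shifted_hill_bounds_and_domain():
    rng = np.random.default_rng(0)
    for _ in range(200):
        lam = rng.uniform(0.01, 100)
        v = ep.shifted_hill(rng.uniform(0, 1000), rng.uniform(0.1, 100), rng.integers(1, 7), lam)
        assert min(1, lam) - 1e-12 <= v <= max(1, lam) + 1e-12
    with pytest.raises(ValueError):
        ep.shifted_hill(1.0, 0.0, 2, 0.5)


# ------------------------------------------------------------------- sampling

def test_sample_parameters_deterministic_and_in_range(core_network):
    p1 = ep.sample_parameters(core_network, ParameterRanges(), seed=7)
    p2 = ep.sample_parameters(core_network, ParameterRanges(), seed=7)
    assert np.array_equal(p1.g, p2.g) and np.array_equal(p1.x0, p2.x0)
    assert np.all((p1.g >= 1) & (p1.g <= 100))
    assert np.all((p1.k >= 0.1) & (p1.k <= 1))
    for e, edge in enumerate(core_network.edges):
        if edge.sign == "activation":
            assert 1 <= p1.lam[e] <= 100
        else:
            assert 0.01 <= p1.lam[e] <= 1


def test_isolated_node_median_matches_brute_force(single_node_network):
    # with the self-loop disabled (lam = 1) the only level scale is g/k;
    # the Monte-Carlo median feeding the threshold rule must match a
    # direct simulation of median(g/k)
    rng = np.random.default_rng(123)
    g = rng.uniform(1, 100, 200_000)
    k = rng.uniform(0.1, 1, 200_000)
    expected = np.median(g / k)
    from emtpdl1.racipe import _median_levels

    got = _median_levels(single_node_network, ParameterRanges(threshold_draws=20_000),
                         np.random.default_rng(5))
    # the node has a self-edge, whose Hill factor at lam drawn from the
    # fold range is not neutral; compare against the basal pass instead
    rng2 = np.random.default_rng(5)
    g2 = rng2.uniform(1, 100, 20_000)
    k2 = rng2.uniform(0.1, 1, 20_000)
    basal = np.median(g2 / k2)
    assert basal == pytest.approx(expected, rel=0.05)
    assert got[0] > 0


def test_ensemble_parameter_threshold_balance(core_network):
    """Half-functional rule: each edge's threshold straddles its
    regulator's realized levels about half the time."""
    cfg = EnsembleConfig(num_models=400, num_initial_conditions=30, seed=3)
    res = ep.run_ensemble(core_network, config=cfg)
    src, _, _ = core_network.edge_arrays()
    levels = 2.0 ** res.solutions[[f"{n}_log2" for n in core_network.nodes]].to_numpy()
    x0 = res.params.x0[res.solutions["model_index"].to_numpy()]
    for e in range(core_network.n_edges):
        frac = np.mean(levels[:, src[e]] > x0[:, e])
        assert 0.25 < frac < 0.75


# ------------------------------------------------------------- steady states

def test_unregulated_fixed_point(single_node_network):
    params = make_params(single_node_network, g=[10.0], k=[0.5], lam=[1.0],
                         hill_n=[2], x0=[5.0])
    cfg = EnsembleConfig(num_models=1, num_initial_conditions=20, seed=0)
    states, n_bad = ep.find_steady_states(single_node_network, params, cfg)
    assert n_bad == 0
    assert states.shape == (1, 1)
    assert states[0, 0] == pytest.approx(np.log2(20.0), abs=1e-3)


def test_all_neutral_regulation_single_state(core_network):
    rng = np.random.default_rng(11)
    g = rng.uniform(1, 100, core_network.n_nodes)
    k = rng.uniform(0.1, 1, core_network.n_nodes)
    params = make_params(core_network, g, k, np.ones(core_network.n_edges),
                         np.full(core_network.n_edges, 2), np.full(core_network.n_edges, 50.0))
    cfg = EnsembleConfig(num_models=1, num_initial_conditions=30, seed=1)
    states, _ = ep.find_steady_states(core_network, params, cfg)
    assert states.shape[0] == 1
    assert np.allclose(2.0 ** states[0], g / k, rtol=1e-3)


def _toggle_oracle_states(params):
    """Brute-force steady states of the 2-node toggle by 1D root scan.

    At a fixed point x_B solves F(x_B) = g_B*H(x_A*(x_B)) / k_B - x_B
    with x_A*(x_B) = g_A*H(x_B)/k_A.  Roots are located by sign changes
    on a dense log grid and refined with brentq; stability follows from
    the 2x2 Jacobian.
    """
    gA, gB = params.g
    kA, kB = params.k
    lamAB, lamBA = params.lam  # edge order: A -| B, B -| A
    nAB, nBA = params.hill_n
    x0AB, x0BA = params.x0

    H = ep.shifted_hill

    def xA_of_xB(xb):
        return gA * H(xb, x0BA, nBA, lamBA) / kA

    def F(xb):
        return gB * H(xA_of_xB(xb), x0AB, nAB, lamAB) / kB - xb

    grid = np.logspace(-6, np.log10(2 * gB / kB), 4000)
    vals = F(grid)
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0 or np.sign(vals[i]) != np.sign(vals[i + 1]):
            r = optimize.brentq(F, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-12)
            if not any(abs(np.log(r) - np.log(q)) < 1e-6 for q in roots):
                roots.append(r)
    stable = []
    for xb in roots:
        xa = xA_of_xB(xb)
        eps = 1e-6
        dH_ab = (H(xa * (1 + eps), x0AB, nAB, lamAB) - H(xa, x0AB, nAB, lamAB)) / (xa * eps)
        dH_ba = (H(xb * (1 + eps), x0BA, nBA, lamBA) - H(xb, x0BA, nBA, lamBA)) / (xb * eps)
        jac = np.array([[-kA, gA * dH_ba], [gB * dH_ab, -kB]])
        if np.all(np.real(np.linalg.eigvals(jac)) < 0):
            stable.append((xa, xb))
    return np.array(stable)


def test_symmetric_toggle_switch_is_bistable(toggle_network):
    params = make_params(toggle_network, g=[50.0, 50.0], k=[0.5, 0.5],
                         lam=[0.01, 0.01], hill_n=[4, 4], x0=[30.0, 30.0])
    cfg = EnsembleConfig(num_models=1, num_initial_conditions=100, seed=2)
    states, _ = ep.find_steady_states(toggle_network, params, cfg)
    oracle = _toggle_oracle_states(params)
    assert states.shape[0] == 2 == oracle.shape[0]


def test_toggle_states_match_brute_force_oracle(toggle_network):
    """Integrator state sets equal the nullcline-scan oracle on random
    kinetics of the 2-node toggle motif."""
    rng = np.random.default_rng(0)
    cfg = EnsembleConfig(num_models=1, num_initial_conditions=120, seed=9)
    checked = 0
    for trial in range(25):
        params = make_params(
            toggle_network,
            g=rng.uniform(1, 100, 2),
            k=rng.uniform(0.1, 1, 2),
            lam=1.0 / rng.uniform(1, 100, 2),
            hill_n=rng.integers(1, 7, 2),
            x0=rng.uniform(1, 180, 2),
        )
        states, _ = ep.find_steady_states(toggle_network, params, cfg)
        oracle = _toggle_oracle_states(params)
        assert states.shape[0] == oracle.shape[0], f"trial {trial}"
        got = np.sort(states[:, 0])
        want = np.sort(np.log2(oracle[:, 0]))
        assert np.allclose(got, want, atol=cfg.merge_tol_log2), f"trial {trial}"
        checked += 1
    assert checked == 25


def test_reported_states_satisfy_fixed_point_residual(small_core_ensemble):
    sol = small_core_ensemble.solutions
    rng = np.random.default_rng(4)
    for idx in rng.choice(len(sol), size=40, replace=False):
        row = sol.iloc[idx]
        params = small_core_ensemble.params.model(int(row["model_index"]))
        state = row[[f"{n}_log2" for n in small_core_ensemble.topology.nodes]].to_numpy(float)
        resid = steady_state_residuals(params, state[None, :])[0]
        x = 2.0 ** state
        assert np.all(resid < 1e-3 * params.k * x + 1e-9)


# ------------------------------------------------------------------- ensemble

def test_ensemble_z_scores_are_standardized(small_core_ensemble):
    for n in small_core_ensemble.topology.nodes:
        z = small_core_ensemble.solutions[f"{n}_z"]
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=0) - 1) < 1e-9


def test_ensemble_determinism(core_network):
    cfg = EnsembleConfig(num_models=50, num_initial_conditions=20, seed=123)
    a = ep.run_ensemble(core_network, config=cfg)
    b = ep.run_ensemble(core_network, config=cfg)
    pd.testing.assert_frame_equal(a.solutions, b.solutions)
    assert np.array_equal(a.params.g, b.params.g)


def test_ensemble_respects_max_states(small_core_ensemble):
    assert small_core_ensemble.solutions["num_states"].max() <= 5


def test_penta_plus_models_are_rare(small_core_ensemble):
    dropped = small_core_ensemble.n_models_dropped_multistate
    total = small_core_ensemble.config.num_models
    assert dropped / total < 0.05


# --------------------------------------------------------------- perturbation

def test_apply_perturbation_on_ranges(core_network):
    ranges = ParameterRanges()
    oe = ep.apply_perturbation(ranges, core_network, "SLUG", "OE", fold=20)
    assert oe.production_range("SLUG") == (20.0, 2000.0)
    assert oe.production_range("ZEB1") == (1.0, 100.0)
    back = ep.apply_perturbation(oe, core_network, "SLUG", "DE", fold=20)
    assert back.production_range("SLUG") == pytest.approx((1.0, 100.0))
    ident = ep.apply_perturbation(ranges, core_network, "SLUG", "OE", fold=1)
    assert ident.production_range("SLUG") == (1.0, 100.0)


def test_apply_perturbation_on_params_and_errors(core_network):
    params = ep.sample_parameters(core_network, ParameterRanges(), seed=0)
    idx = core_network.node_index("miR200")
    de = ep.apply_perturbation(params, "miR200", "DE", fold=10)
    assert de.g[idx] == pytest.approx(params.g[idx] / 10)
    with pytest.raises(Exception):
        ep.apply_perturbation(ParameterRanges(), core_network, "NOPE", "OE")
    with pytest.raises(ValueError):
        ep.apply_perturbation(ParameterRanges(), core_network, "SLUG", "UP")


# -------------------------------------------------------------- z-normalize

def test_z_normalize_hand_value():
    df = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
    z = ep.z_normalize(df)
    assert np.allclose(z["a"], [-1.2247448, 0.0, 1.2247448])


def test_z_normalize_idempotent_on_standardized():
    rng = np.random.default_rng(8)
    v = rng.normal(size=500)
    v = (v - v.mean()) / v.std()
    df = pd.DataFrame({"a": v})
    assert np.allclose(ep.z_normalize(df)["a"], v, atol=1e-12)


def test_z_normalize_rejects_constant_column():
    with pytest.raises(ValueError, match="flat"):
        ep.z_normalize(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))
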