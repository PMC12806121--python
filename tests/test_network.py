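"""Network assembly, seeding, heterogeneity and the full seeded simulation."""

import numpy as np
import pytest

from fracbrain import (
    ModelParameters,
    NetworkParameters,
    assemble_network_rhs,
    build_adjacency,
    build_laplacians,
    make_initial_condition,
    mixed_tauopathy_overrides,
    positive_equilibrium,
    simulate_network,
    summarize,
)
from fracbrain.model import rhs_local_damage
from fracbrain.network import NetworkState, variable_block


def isolated_node_connectome():
    import pandas as pd

    nodes = pd.DataFrame(
        {"id": [0], "x": [0.0], "y": [0.0], "z": [0.0],
         "brain_id": ["entorhinal"], "region": ["limbic"]}
    )
    edges = pd.DataFrame(columns=["source", "target", "n_fibers", "length_mm"])
    from fracbrain import Connectome

    return Connectome(nodes, edges, {"abeta": np.array([0]), "tau": np.array([0])})


class TestAssembly:
    def test_single_node_reduces_to_local_model(self, default_params):
        conn = isolated_node_connectome()
        net = NetworkParameters(base=default_params)
        rhs = assemble_network_rhs(conn, build_laplacians(build_adjacency(conn), default_params), net)
        y = np.array([0.7, 0.1, 0.4, 0.05, 0.1, 0.2])
        np.testing.assert_allclose(rhs(0.0, y), rhs_local_damage(y, default_params), atol=1e-14)

    def test_homogeneous_equilibrium_is_a_network_fixed_point(self, default_params, fixtures):
        conn = fixtures["two_region_12"]
        e = positive_equilibrium(default_params).state
        net = NetworkParameters(base=default_params)
        rhs = assemble_network_rhs(conn, build_laplacians(build_adjacency(conn), default_params), net)
        n = conn.n_nodes
        flat = NetworkState(*(np.full(n, e[i]) for i in range(5)), q=np.zeros(n)).pack()
        field = rhs(0.0, flat)
        assert np.max(np.abs(field[: 5 * n])) < 1e-12

    def test_homogeneous_equilibrium_persists_under_integration(self, default_params, fixtures):
        conn = fixtures["two_region_12"]
        e = positive_equilibrium(default_params).state
        n = conn.n_nodes
        init = NetworkState(*(np.full(n, e[i]) for i in range(5)), q=np.zeros(n))
        traj = simulate_network(conn, NetworkParameters(base=default_params), 1.0, 100.0, 0.05,
                                initial=init, store_every=400)
        expected = np.concatenate([np.full(n, e[i]) for i in range(5)])
        assert np.max(np.abs(traj.states[-1, : 5 * n] - expected)) < 1e-9

    def test_unknown_override_node_rejected(self, default_params, fixtures):
        net = NetworkParameters(base=default_params, overrides={99: {"b2": 1.6}})
        conn = fixtures["two_region_12"]
        with pytest.raises(ValueError, match="unknown node"):
            assemble_network_rhs(conn, build_laplacians(build_adjacency(conn), default_params), net)

    def test_diffusion_parameter_override_rejected(self, default_params, fixtures):
        net = NetworkParameters(base=default_params, overrides={0: {"rho_u": 2.0}})
        with pytest.raises(ValueError, match="non-local"):
            net.expand(12)


class TestSeeding:
    def test_baseline_outside_seed_sets(self, fixtures):
        conn = fixtures["two_region_12"]
        state = make_initial_condition(conn)
        outside = [k for k in range(conn.n_nodes)
                   if k not in set(conn.seed_sets["abeta"]) | set(conn.seed_sets["tau"])]
        for k in outside:
            assert (state.u[k], state.u_tilde[k], state.v[k], state.v_tilde[k],
                    state.w[k], state.q[k]) == (0.75, 0.0, 0.5, 0.0, 0.1, 0.0)

    def test_relative_seed_magnitudes(self, fixtures):
        conn = fixtures["two_region_12"]
        state = make_initial_condition(conn)
        assert np.allclose(state.u_tilde[conn.seed_sets["abeta"]], 0.0038 * 0.75)
        assert np.allclose(state.v_tilde[conn.seed_sets["tau"]], 0.0025 * 0.5)

    def test_absolute_mode(self, fixtures):
        conn = fixtures["two_region_12"]
        state = make_initial_condition(conn, mode="absolute")
        assert np.allclose(state.u_tilde[conn.seed_sets["abeta"]], 0.0038)

    def test_empty_seed_set_rejected(self, fixtures):
        conn = fixtures["two_region_12"]
        conn_no_seeds = type(conn)(conn.nodes, conn.edges, {"abeta": [], "tau": []})
        with pytest.raises(ValueError, match="empty"):
            make_initial_condition(conn_no_seeds)

    def test_toxic_free_state_stays_toxic_free(self, default_params, fixtures):
        """With zero seeding the toxin-free subspace is invariant."""
        conn = fixtures["two_region_12"]
        init = make_initial_condition(conn, seed_fraction_abeta=0.0, seed_fraction_tau=0.0)
        traj = simulate_network(conn, NetworkParameters(base=default_params), 1.0, 10.0, 0.01,
                                initial=init, store_every=100)
        n = conn.n_nodes
        assert np.max(variable_block(traj.states, "u_tilde", n)) == 0.0
        assert np.max(variable_block(traj.states, "v_tilde", n)) == 0.0


@pytest.fixture(scope="module")
def long_run(default_params, fixtures):
    conn = fixtures["two_region_12"]
    return conn, simulate_network(conn, NetworkParameters(base=default_params),
                                  1.0, 2000.0, 0.05, store_every=160)


class TestSeededDynamics:
    def test_concentrations_converge_to_coexistence_point(self, default_params, long_run):
        conn, traj = long_run
        e = positive_equilibrium(default_params).state
        n = conn.n_nodes
        i400 = np.argmin(np.abs(traj.times - 400.0))
        for s, name in enumerate(["u", "u_tilde", "v", "v_tilde", "w"]):
            block = variable_block(traj.states, name, n)[i400]
            assert np.max(np.abs(block - e[s])) < 1e-2, name

    def test_damage_converges_to_complete_loss(self, long_run):
        conn, traj = long_run
        q_end = variable_block(traj.states, "q", conn.n_nodes)[-1]
        assert np.all(q_end > 0.95)

    def test_damage_nondecreasing_in_time(self, long_run):
        conn, traj = long_run
        q = variable_block(traj.states, "q", conn.n_nodes)
        assert np.min(np.diff(q, axis=0)) >= 0

    def test_decoupled_network_matches_isolated_node(self, default_params, fixtures):
        conn = fixtures["path3"]
        p = default_params.replace(rho_u=0, rho_u_tilde=0, rho_v=0, rho_v_tilde=0)
        init = make_initial_condition(conn)
        traj = simulate_network(conn, NetworkParameters(base=p), 1.0, 20.0, 0.01,
                                initial=init, store_every=100)
        # node 1 is the amyloid seed; integrate it alone and compare
        from fracbrain import solve_rk4

        y0 = np.array([0.75, 0.0038 * 0.75, 0.5, 0.0, 0.1, 0.0])
        solo = solve_rk4(lambda t, y: rhs_local_damage(y, p), y0, 20.0, 0.01,
                         store_every=100)
        n = conn.n_nodes
        net_node1 = np.stack(
            [variable_block(traj.states, v, n)[:, 1] for v in
             ("u", "u_tilde", "v", "v_tilde", "w", "q")], axis=1
        )
        np.testing.assert_allclose(net_node1, solo.states, atol=1e-10)


class TestMixedTauopathy:
    def test_empty_spec_is_pure_base(self, fixtures):
        net = mixed_tauopathy_overrides(fixtures["two_region_12"], {})
        assert net.overrides == {}

    def test_unknown_brain_id_rejected(self, fixtures):
        with pytest.raises(ValueError, match="precuneus"):
            mixed_tauopathy_overrides(fixtures["two_region_12"], {"precuneus": (1.6, 4.14)})

    def test_overridden_nodes_classify_primary(self, fixtures):
        from fracbrain import classify_tauopathy

        conn = fixtures["two_region_12"]
        net = mixed_tauopathy_overrides(conn, {"entorhinal": (1.6, 4.14)})
        ent = conn.nodes.index[conn.nodes.brain_id == "entorhinal"]
        for node in range(conn.n_nodes):
            expected = "primary" if node in set(ent) else "secondary"
            assert classify_tauopathy(net.node_params(node)) == expected

    def test_no_op_override_equals_base(self, default_params, fixtures):
        conn = fixtures["two_region_12"]
        spec = {bid: (default_params.b2, default_params.b3) for bid in set(conn.nodes.brain_id)}
        net = mixed_tauopathy_overrides(conn, spec)
        for node in range(conn.n_nodes):
            assert net.node_params(node) == default_params


class TestSummaries:
    def test_uniform_state_gives_equal_groups(self, default_params, fixtures):
        conn = fixtures["two_region_12"]
        e = positive_equilibrium(default_params).state
        n = conn.n_nodes
        init = NetworkState(*(np.full(n, e[i]) for i in range(5)), q=np.zeros(n))
        traj = simulate_network(conn, NetworkParameters(base=default_params), 1.0, 1.0, 0.01,
                                initial=init, store_every=10)
        s = summarize(traj, conn, "region")
        vt = s["v_tilde"]
        assert np.allclose(vt.to_numpy(), vt.to_numpy()[:, :1])

    def test_ranking_by_terminal_toxic_tau(self, default_params, fixtures):
        conn = fixtures["two_region_12"]
        net = mixed_tauopathy_overrides(conn, {"entorhinal": (1.6, 4.14),
                                               "parahippocampal": (1.6, 4.14)})
        traj = simulate_network(conn, net, 1.0, 200.0, 0.01, store_every=2000)
        s = summarize(traj, conn, "region")
        assert s["ranking"][0] == "limbic"

    def test_invalid_grouping_rejected(self, default_params, fixtures):
        conn = fixtures["two_region_12"]
        traj = simulate_network(conn, NetworkParameters(base=default_params), 1.0, 1.0, 0.01,
                                store_every=10)
        with pytest.raises(ValueError, match="grouping"):
            summarize(traj, conn, "hemisphere")
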