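import numpy as np
import pytest

from modanneal import (
    AnnealSchedule,
    ModularityConfig,
    build_potts,
    detect_communities,
    exact_ground_state,
    modularity_kronecker,
    modularity_matrix,
    register_backend,
    simulated_annealing,
)
from modanneal.samplers import _metropolis_chain

from conftest import random_graph


def _potts(graph, k, gamma=1.0):
    return build_potts(modularity_matrix(graph, ModularityConfig(gamma)), k)


class TestExact:
    def test_two_triangles(self, two_triangles):
        res = exact_ground_state(_potts(two_triangles, 2))
        assert res.modularity == pytest.approx(0.5, abs=1e-12)
        np.testing.assert_array_equal(res.partition.labels, [0, 0, 0, 1, 1, 1])

    def test_bridged_triangles(self, bridged_triangles):
        res = exact_ground_state(_potts(bridged_triangles, 2))
        assert res.modularity == pytest.approx(5 / 14, abs=1e-12)

    def test_single_edge_k3_uniform(self, single_edge):
        res = exact_ground_state(_potts(single_edge, 3))
        assert res.modularity == pytest.approx(0.0, abs=1e-12)
        assert res.partition.n_communities == 1

    def test_guard_refuses_large(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 30)
        with pytest.raises(ValueError, match="guard"):
            exact_ground_state(_potts(g, 4))

    def test_deterministic(self, bridged_triangles):
        a = exact_ground_state(_potts(bridged_triangles, 3))
        b = exact_ground_state(_potts(bridged_triangles, 3))
        np.testing.assert_array_equal(a.partition.labels, b.partition.labels)
        assert a.energy == b.energy


class TestSimulatedAnnealing:
    def test_matches_exact_on_random_graphs(self):
        """Best-of-20 SA finds the enumerated optimum on 25 small graphs."""
        rng = np.random.default_rng(2024)
        schedule = AnnealSchedule(restarts=20, seed=77)
        for trial in range(25):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, 4))
            g = random_graph(rng, n, weighted=bool(rng.integers(2)))
            model = _potts(g, k)
            oracle = exact_ground_state(model)
            sa = simulated_annealing(model, schedule)
            assert sa.modularity == pytest.approx(oracle.modularity, abs=1e-9), (
                f"trial {trial}: SA Q={sa.modularity} vs exact {oracle.modularity}"
            )

    def test_bit_identical_given_seed(self, bridged_triangles):
        model = _potts(bridged_triangles, 3)
        schedule = AnnealSchedule(restarts=5, seed=123)
        a = simulated_annealing(model, schedule)
        b = simulated_annealing(model, schedule)
        np.testing.assert_array_equal(a.partition.labels, b.partition.labels)
        assert a.energy == b.energy and a.restart_index == b.restart_index
        assert a.restart_energies == b.restart_energies

    def test_stored_modularity_consistent(self, bridged_triangles):
        model = _potts(bridged_triangles, 3)
        res = simulated_annealing(model, AnnealSchedule(restarts=3, seed=5))
        q = modularity_kronecker(
            modularity_matrix(bridged_triangles), res.partition
        )
        assert res.modularity == pytest.approx(q, abs=1e-12)

    def test_best_over_restarts_never_worse_than_any(self, bridged_triangles):
        model = _potts(bridged_triangles, 2)
        res = simulated_annealing(model, AnnealSchedule(restarts=10, seed=9))
        assert res.energy <= min(res.restart_energies) + 1e-12
        # running minimum of per-restart energies is monotone by construction
        running = np.minimum.accumulate(res.restart_energies)
        assert (np.diff(running) <= 0).all()

    def test_incremental_delta_matches_full_energy(self):
        """The O(n) in-chain updates land on the exact final energy."""
        rng = np.random.default_rng(55)
        g = random_graph(rng, 10, weighted=True)
        model = _potts(g, 3)
        schedule = AnnealSchedule(restarts=1, seed=8)
        temps = schedule.temperatures()
        moves = 10 * model.n
        chain_rng = np.random.default_rng(schedule.seed)
        labels = chain_rng.integers(0, 3, model.n).astype(np.int64)
        total = temps.size * moves
        E = _metropolis_chain(
            np.ascontiguousarray(model.J), labels, 3, temps, moves,
            chain_rng.integers(0, model.n, total),
            chain_rng.integers(0, 3, total),
            chain_rng.random(total),
        )
        assert E == pytest.approx(model.energy(labels), abs=1e-9)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            AnnealSchedule(T_start=0.1, T_end=1.0)
        with pytest.raises(ValueError):
            AnnealSchedule(cooling_factor=1.5)


class TestDetectCommunities:
    def test_two_triangles_kmax5_finds_two(self, two_triangles):
        res = detect_communities(two_triangles, 5,
                                 schedule=AnnealSchedule(restarts=20, seed=3))
        assert res.n_communities_nonempty == 2
        assert res.modularity == pytest.approx(0.5, abs=1e-9)

    def test_exact_backend(self, two_triangles):
        res = detect_communities(two_triangles, 3, backend="exact")
        assert res.modularity == pytest.approx(0.5, abs=1e-12)

    def test_kmax_one_warns(self, two_triangles):
        with pytest.warns(UserWarning, match="degenerate"):
            res = detect_communities(two_triangles, 1)
        assert res.n_communities_nonempty == 1
        assert res.modularity == pytest.approx(0.0, abs=1e-12)


class TestExternalBackend:
    def teardown_method(self):
        register_backend(None)

    def test_unregistered_errors(self, two_triangles):
        register_backend(None)
        with pytest.raises(RuntimeError, match="no adapter"):
            detect_communities(two_triangles, 2, backend="external")

    def test_mock_adapter_rescored_locally(self, two_triangles):
        register_backend(lambda dqm_json: [0, 0, 0, 1, 1, 1])
        res = detect_communities(two_triangles, 2, backend="external")
        assert res.modularity == pytest.approx(0.5, abs=1e-12)

    def test_adapter_matching_oracle_is_identical(self, bridged_triangles):
        oracle = detect_communities(bridged_triangles, 2, backend="exact")
        register_backend(lambda dqm_json: oracle.partition.labels.tolist())
        res = detect_communities(bridged_triangles, 2, backend="external")
        np.testing.assert_array_equal(res.partition.labels, oracle.partition.labels)
        assert res.energy == oracle.energy and res.modularity == oracle.modularity

    def test_out_of_range_case_rejected(self, two_triangles):
        register_backend(lambda dqm_json: [0, 0, 0, 1, 1, 2])
        with pytest.raises(ValueError, match="case"):
            detect_communities(two_triangles, 2, backend="external")

    def test_wrong_length_rejected(self, two_triangles):
        register_backend(lambda dqm_json: [0, 1])
        with pytest.raises(ValueError, match="labels"):
            detect_communities(two_triangles, 2, backend="external")
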