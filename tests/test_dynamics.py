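"""The per-timestep rules: movement, induction, adhesion, breaking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synspheroid import (
    ModelParams,
    Phenotype,
    SeedingSpec,
    induction_probability,
    simulate,
    step,
)
from synspheroid.dynamics import (
    rule_adhesion,
    rule_centripetal_move,
    rule_cluster_move,
    rule_induction,
    rule_link_breaking,
    ticks_for_hours,
)

from conftest import make_state

B, N, G, R = Phenotype.BFP, Phenotype.NEG, Phenotype.GFP_NCAD, Phenotype.MCH_PCAD


class TestInductionProbability:
    def test_hand_evaluated_values(self):
        assert induction_probability(0.20, 8, 8) == pytest.approx(1 - math.exp(-0.20))
        assert induction_probability(10, 8, 8) == pytest.approx(1 - math.exp(-10))
        assert induction_probability(0.20, 4, 8) == pytest.approx(1 - math.exp(-0.10))

    def test_zero_neighbors_gives_zero(self):
        assert induction_probability(5.0, 0, 8) == 0.0
        assert induction_probability(5.0, 0, 26) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            induction_probability(-0.1, 1, 8)
        with pytest.raises(ValueError):
            induction_probability(0.2, 9, 8)
        with pytest.raises(ValueError):
            induction_probability(0.2, 1, 7)

    @given(
        c=st.floats(0, 20), n=st.integers(0, 8), m=st.integers(0, 8),
        c2=st.floats(0, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_c_and_n(self, c, n, m, c2):
        p = induction_probability(c, n, 8)
        assert 0.0 <= p < 1.0
        if m >= n:
            assert induction_probability(c, m, 8) >= p
        if c2 >= c:
            assert induction_probability(c2, n, 8) >= p


class TestCentripetalMove:
    def test_forced_unique_move_to_center(self, rng):
        # one cell one site right of the center of a 15x15 world
        state = make_state({(7, 8): B})
        rule_centripetal_move(state, rng)
        assert state.lattice.geometry.coord_of(state.lattice.positions[0]) == (7, 7)

    def test_fully_blocked_cell_stays(self, rng):
        cells = {(7, 7): B}
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx or dy:
                    cells[(7 + dx, 7 + dy)] = N
        state = make_state(cells)
        center_id = state.lattice.occupancy[7 * 15 + 7]
        rule_centripetal_move(state, rng)
        assert state.lattice.occupancy[7 * 15 + 7] == center_id

    def test_equidistant_tie_broken_uniformly(self):
        # a lone mobile cell at (7,9) with its westward path blocked by an
        # (immobilized) wall: the two best open neighbors (6,9) and (8,9)
        # are equidistant from the center and each should win ~half of trials
        wins = 0
        trials = 10_000
        for k in range(trials):
            state = make_state({(6, 8): N, (7, 8): N, (7, 9): B, (8, 8): N})
            state.add_link(0, 1)  # linked wall cells do not move centripetally
            state.add_link(1, 3)
            r = np.random.default_rng(k)
            rule_centripetal_move(state, r)
            moved = state.lattice.geometry.coord_of(state.lattice.positions[2])
            assert moved in ((6, 9), (8, 9))
            wins += moved == (6, 9)
        assert abs(wins / trials - 0.5) < 0.02

    def test_occupancy_bijection_preserved(self, rng):
        state = make_state({(i, j): B for i in range(5, 10) for j in range(5, 8)})
        for _ in range(10):
            rule_centripetal_move(state, rng)
            state.lattice.validate()


class TestClusterMove:
    def _linked_chain(self, coords, params=None):
        state = make_state({c: G for c in coords}, params=params)
        ids = list(range(len(coords)))
        for a, b in zip(ids, ids[1:]):
            state.add_link(a, b)
        return state

    def test_small_component_stays_connected(self, rng):
        state = self._linked_chain([(7, 6), (7, 7), (7, 8)])
        before = set(state.lattice.positions)
        rule_cluster_move(state, rng)
        after = set(state.lattice.positions)
        assert len(after) == 3
        assert after != before  # plenty of open space: the chain moved
        # still link-connected: brute-force traversal over Moore adjacency
        geo = state.lattice.geometry
        pos = state.lattice.positions
        for (i, j) in state.links:
            assert geo.chebyshev(pos[i], pos[j]) == 1

    def test_component_at_mu_does_not_move(self, rng):
        coords = [(7, 5), (7, 6), (7, 7), (7, 8), (7, 9)]  # size == mu == 5
        state = self._linked_chain(coords)
        before = list(state.lattice.positions)
        rule_cluster_move(state, rng)
        assert state.lattice.positions == before

    def test_blocked_leader_freezes_component(self, rng):
        # pair near center, every Moore neighbor of the leader occupied
        cells = {(7, 7): G, (7, 8): G}
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                p = (7 + dx, 7 + dy)
                if p not in cells:
                    cells[p] = N
        state = make_state(cells)
        ids = {state.lattice.geometry.coord_of(s): i
               for i, s in enumerate(state.lattice.positions)}
        state.add_link(ids[(7, 7)], ids[(7, 8)])
        before = list(state.lattice.positions)
        rule_cluster_move(state, rng)
        # the leader (7,7) is fully blocked: the linked pair must not move
        assert state.lattice.positions[ids[(7, 7)]] == before[ids[(7, 7)]]
        assert state.lattice.positions[ids[(7, 8)]] == before[ids[(7, 8)]]

    def test_displaced_cells_relocate_into_vacated_sites(self, rng):
        state = make_state({(7, 6): G, (7, 7): G, (7, 8): N, (6, 6): N})
        state.add_link(0, 1)
        for _ in range(20):
            rule_cluster_move(state, rng)
            state.lattice.validate()
        assert state.lattice.n_cells == 4


class TestInduction:
    def test_no_induction_before_delay(self, rng):
        cells = {(7, 7): N}
        for dx, dy in [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]:
            cells[(7 + dx, 7 + dy)] = B
        state = make_state(cells, params=ModelParams())
        state.tick = 9  # < a = 10
        rule_induction(state, rng)
        assert all(c == -1 for c in state.committed)

    def test_zero_sender_neighbors_never_induces(self, rng):
        state = make_state({(7, 7): N, (3, 3): B}, params=ModelParams(c_a=100.0))
        state.tick = 50
        for _ in range(50):
            rule_induction(state, rng)
        assert state.committed[list(state.lattice.phenotypes).index(int(N))] == -1

    def test_expression_lag_and_phenotype_flip(self, rng):
        cells = {(7, 7): N}
        for dx, dy in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
            cells[(7 + dx, 7 + dy)] = B
        state = make_state(cells, params=ModelParams(c_a=1000.0))
        idx = list(state.lattice.phenotypes).index(int(N))
        state.tick = 10
        rule_induction(state, rng)  # certain induction at this c
        assert state.committed[idx] == int(G)
        assert state.induced_at[idx] == 10
        assert state.expresses_at[idx] == 20
        assert state.lattice.phenotypes[idx] == int(N)  # color change lags
        state.tick = 20
        rule_induction(state, rng)
        assert state.lattice.phenotypes[idx] == int(G)

    def test_circuit1_never_changes_phenotypes(self):
        from synspheroid import make_ruleset

        params = make_ruleset("1A")
        state = simulate(params, SeedingSpec(n_cells=60, ratio=(1, 1)), 100, seed=5)
        counts = state.lattice.phenotype_counts()
        assert counts[G] == 30 and counts[R] == 30
        assert counts[B] == 0 and counts[N] == 0

    def test_no_green_phenotype_before_earliest_expression_tick(self):
        params = ModelParams()  # a + delta_a = 20
        for seed in range(5):
            snaps = simulate(
                params, SeedingSpec(n_cells=100, ratio=(1, 1)), 19,
                seed=seed, snapshot_ticks=[10, 15, 19],
            )
            for s in snaps:
                assert all(p != int(G) and p != int(R) for p in s.lattice.phenotypes)


class TestAdhesion:
    def test_certain_homotypic_link(self, rng):
        state = make_state({(7, 7): G, (7, 8): G}, params=ModelParams(p_a=1.0))
        rule_adhesion(state, rng)
        assert (0, 1) in state.links

    def test_zero_heterotypic_probability_never_links(self, rng):
        state = make_state({(7, 7): G, (7, 8): R}, params=ModelParams(p_ab=0.0))
        for _ in range(50):
            rule_adhesion(state, rng)
        assert not state.links

    def test_non_cadherin_cells_never_link(self, rng):
        state = make_state(
            {(7, 7): B, (7, 8): N, (8, 7): G},
            params=ModelParams(p_a=1.0, p_b=1.0, p_ab=1.0),
        )
        rule_adhesion(state, rng)
        assert not state.links

    def test_wedged_cell_switches_out(self, rng):
        # G-R-G along a row with P_a = 1: after the rule the two greens
        # must occupy adjacent sites
        state = make_state(
            {(7, 6): G, (7, 7): R, (7, 8): G},
            params=ModelParams(p_a=1.0, p_b=0.0, p_ab=0.0),
        )
        rule_adhesion(state, rng)
        greens = sorted(
            state.lattice.geometry.coord_of(s)
            for s, p in zip(state.lattice.positions, state.lattice.phenotypes)
            if p == int(G)
        )
        (x1, y1), (x2, y2) = greens
        assert max(abs(x1 - x2), abs(y1 - y2)) == 1

    def test_separating_cell_switches_with_p_ab(self, rng):
        state = make_state(
            {(7, 6): G, (7, 7): N, (7, 8): R},
            params=ModelParams(p_a=0.0, p_b=0.0, p_ab=1.0),
        )
        rule_adhesion(state, rng)
        coords = {
            Phenotype(p): state.lattice.geometry.coord_of(s)
            for s, p in zip(state.lattice.positions, state.lattice.phenotypes)
        }
        (x1, y1), (x2, y2) = coords[G], coords[R]
        assert max(abs(x1 - x2), abs(y1 - y2)) == 1


class TestLinkBreaking:
    def _component_with_links(self, n=11):
        # a row of greens linked into a single chain: n cells, n-1 links
        coords = [(7, 2 + i) for i in range(n)]
        state = make_state({c: G for c in coords}, params=ModelParams(t_reform=3))
        for a in range(n - 1):
            state.add_link(a, a + 1)
        return state

    def test_half_rounded_up_break(self, rng):
        state = self._component_with_links(11)  # 10 links
        rule_link_breaking(state, rng)
        assert len(state.links) == 5
        assert len(state.cooldown_until) == 5

    def test_cooldown_blocks_reform_until_t_reform(self):
        rng = np.random.default_rng(0)
        state = make_state({(7, 7): G, (7, 8): G}, params=ModelParams(p_a=1.0, t_reform=3))
        state.tick = 5
        state.add_link(0, 1)
        rule_link_breaking(state, rng)  # the single link breaks (ceil(1/2)=1)
        assert not state.links
        for tick in (6, 7, 8):
            state.tick = tick
            rule_adhesion(state, rng)
            assert not state.links, f"pair relinked during cooldown at tick {tick}"
        state.tick = 9
        rule_adhesion(state, rng)
        assert (0, 1) in state.links

    def test_no_links_is_noop(self, rng):
        state = make_state({(7, 7): G, (9, 9): R})
        rule_link_breaking(state, rng)
        assert not state.links and not state.cooldown_until


class TestStepAndSimulate:
    def test_step_on_empty_state_only_advances_tick(self, rng):
        state = make_state({})
        step(state, rng, check=True)
        assert state.tick == 1

    def test_determinism_under_fixed_seed(self):
        spec = SeedingSpec(n_cells=80, ratio=(1, 1))
        a = simulate(ModelParams(), spec, 40, seed=7)
        b = simulate(ModelParams(), spec, 40, seed=7)
        assert a.lattice.positions == b.lattice.positions
        assert a.lattice.phenotypes == b.lattice.phenotypes
        assert a.links == b.links

    def test_zero_ticks_returns_initial_state(self):
        state = simulate(ModelParams(), SeedingSpec(n_cells=50), 0, seed=1)
        assert state.tick == 0
        assert state.lattice.n_cells == 50

    def test_conservation_and_link_legality(self):
        # structural invariants checked after every rule application
        state = simulate(
            ModelParams(), SeedingSpec(n_cells=120, ratio=(1, 1)), 60,
            seed=3, check=True,
        )
        assert state.lattice.n_cells == 120

    def test_zero_probabilities_give_empty_link_set(self):
        params = ModelParams(p_a=0.0, p_b=0.0, p_ab=0.0)
        snaps = simulate(
            params, SeedingSpec(n_cells=100, ratio=(1, 1)), 60,
            seed=9, snapshot_ticks=range(0, 61, 10),
        )
        assert all(not s.links for s in snaps)

    def test_phenotype_transitions_single_and_legal(self):
        spec = SeedingSpec(n_cells=100, ratio=(1, 1))
        snaps = simulate(ModelParams(), spec, 80, seed=11, snapshot_ticks=range(0, 81, 5))
        allowed = {(int(N), int(G)), (int(B), int(R))}
        for earlier, later in zip(snaps, snaps[1:]):
            for i, (p0, p1) in enumerate(
                zip(earlier.lattice.phenotypes, later.lattice.phenotypes)
            ):
                if p0 != p1:
                    assert (p0, p1) in allowed, f"cell {i}: {p0} -> {p1}"

    def test_invalid_params_rejected_before_running(self):
        with pytest.raises(ValueError):
            ModelParams(p_a=1.5)
        with pytest.raises(ValueError):
            ModelParams(a=-1)
        with pytest.raises(ValueError):
            ModelParams(circuit=4)
        with pytest.raises(ValueError):
            simulate(ModelParams(), SeedingSpec(n_cells=10), -1, seed=0)


def test_tick_time_conversion():
    assert ticks_for_hours(50.0) == 100.0
    assert ticks_for_hours(13.0) == 26.0
    assert ticks_for_hours(21.0) == 42.0
    assert ticks_for_hours(50.0, tick_minutes=15.0) == 200.0
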