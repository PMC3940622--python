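"""Movement kernel: base probabilities, habitat bias, step sampling, walks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import hedgewalk as hw
from hedgewalk.walker import (
    EAST,
    NORTH,
    OFF_GRID,
    ParameterError,
    WalkerState,
)


class TestBaseProbabilities:
    @pytest.mark.parametrize(
        "p_f, v, expected",
        [
            (0.25, 0.0, (0.25, 0.25, 0.25)),  # uniform over the 4 directions
            (0.5, 1.0, (0.5, 0.25, 0.0)),  # backward moves vanish at v=1
            (0.875, 0.4, (0.875, 0.05, 0.025)),  # direct formula evaluation
        ],
    )
    def test_printed_formula(self, p_f, v, expected):
        assert hw.base_probabilities(p_f, v) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p_f, v", [(0.0, 0.5), (1.5, 0.5), (0.5, -0.1), (0.5, 2)])
    def test_out_of_range_rejected(self, p_f, v):
        with pytest.raises(ParameterError):
            hw.base_probabilities(p_f, v)

    @given(
        p_f=st.floats(0.01, 1.0, allow_nan=False),
        v=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_kernel_normalised_and_nonnegative(self, p_f, v):
        pf, ps, pb = hw.base_probabilities(p_f, v)
        assert min(pf, ps, pb) >= 0
        assert pf + pb + 2 * ps == pytest.approx(1.0, abs=1e-12)


class TestMovementParams:
    def test_unnormalised_kernel_rejected(self):
        with pytest.raises(ParameterError):
            hw.MovementParams(p_f=0.5, p_s=0.3, p_b=0.3)

    def test_invalid_r_rejected(self):
        with pytest.raises(ParameterError):
            hw.MovementParams.from_forward(0.5, 0.5, r=1.5)


class TestAdjustedPreferences:
    def _params(self):
        return hw.MovementParams(p_f=0.5, p_s=0.2, p_b=0.1, r=0.5)

    def test_same_habitat_identity(self):
        ctx = hw.NeighbourContext(hw.WILD, hw.WILD, hw.WILD, hw.WILD, hw.WILD)
        m = hw.adjusted_preferences(self._params(), ctx)
        assert m.tolist() == [0.5, 0.1, 0.2, 0.2]

    def test_r_zero_all_different_kills_all(self):
        params = hw.MovementParams(p_f=0.5, p_s=0.2, p_b=0.1, r=0.0)
        ctx = hw.NeighbourContext(hw.WILD, hw.CROP, hw.CROP, hw.CROP, hw.CROP)
        assert hw.adjusted_preferences(params, ctx).tolist() == [0, 0, 0, 0]

    def test_forward_different_scaled_by_r(self):
        ctx = hw.NeighbourContext(hw.WILD, hw.CROP, hw.WILD, hw.WILD, hw.WILD)
        m = hw.adjusted_preferences(self._params(), ctx)
        assert m.tolist() == [0.25, 0.1, 0.2, 0.2]

    def test_off_grid_neighbour_zeroed(self):
        ctx = hw.NeighbourContext(hw.WILD, OFF_GRID, hw.WILD, hw.WILD, hw.WILD)
        m = hw.adjusted_preferences(self._params(), ctx)
        assert m.tolist() == [0.0, 0.1, 0.2, 0.2]


class TestStepProbabilities:
    def test_hand_normalisation(self):
        a = hw.step_probabilities(np.array([0.25, 0.1, 0.2, 0.2]))
        assert a == pytest.approx([1 / 3, 2 / 15, 4 / 15, 4 / 15])

    def test_valid_kernel_already_normalised(self):
        p = hw.MovementParams(p_f=0.5, p_s=0.2, p_b=0.1)
        a = hw.step_probabilities(p.rel_probabilities())
        assert a == pytest.approx([0.5, 0.1, 0.2, 0.2])

    def test_all_zero_returns_stay_sentinel(self):
        assert hw.step_probabilities(np.zeros(4)) is None

    def test_negative_preference_rejected(self):
        with pytest.raises(ParameterError):
            hw.step_probabilities(np.array([0.5, -0.1, 0.3, 0.3]))

    @given(
        m=st.lists(st.floats(0, 10, allow_nan=False), min_size=4, max_size=4).filter(
            lambda v: sum(v) > 1e-9
        )
    )
    def test_normalisation_invariant(self, m):
        assert hw.step_probabilities(np.array(m)).sum() == pytest.approx(1.0)


class TestStep:
    def test_pure_forward_keeps_heading(self, uniform_wild_landscape, rng):
        params = hw.MovementParams(p_f=1.0, p_s=0.0, p_b=0.0)
        state = WalkerState(100, 100, EAST)
        for _ in range(5):
            state, moved, switched = hw.step(
                state, uniform_wild_landscape, params, rng
            )
            assert moved and not switched and state.heading == EAST
        assert (state.x, state.y) == (105, 100)

    def test_r_zero_single_exit_is_forced(self, rng):
        # walker on wild with exactly one wild neighbour and r=0 must take it
        fields = np.arange(9).reshape(3, 3)
        habitat = np.zeros((3, 3), dtype=np.uint8)
        habitat[1, 1] = habitat[0, 1] = hw.WILD
        grid = hw.LandscapeGrid(3, 3, fields, habitat)
        params = hw.MovementParams(p_f=0.25, p_s=0.25, p_b=0.25, r=0.0)
        for _ in range(20):
            state, moved, switched = hw.step(WalkerState(1, 1, NORTH), grid, params, rng)
            assert moved and not switched
            assert (state.x, state.y) == (1, 0)

    def test_empirical_frequencies_match_probabilities(self, rng):
        # mixed habitats around the walker; 10k replicate single steps
        fields = np.zeros((3, 3), dtype=int)
        habitat = np.array(
            [[0, 1, 0], [1, 1, 0], [0, 0, 0]], dtype=np.uint8
        )
        grid = hw.LandscapeGrid(3, 3, fields, habitat)
        params = hw.MovementParams(p_f=0.5, p_s=0.2, p_b=0.1, r=0.4)
        state = WalkerState(1, 1, NORTH)
        ctx = hw.neighbour_context(state, grid)
        a = hw.step_probabilities(hw.adjusted_preferences(params, ctx))
        counts = {}
        for _ in range(10_000):
            new, _, _ = hw.step(state, grid, params, rng)
            counts[(new.x, new.y)] = counts.get((new.x, new.y), 0) + 1
        # map relative directions (F,B,L,R) from NORTH heading to cells
        cells = [(1, 0), (1, 2), (0, 1), (2, 1)]
        observed = np.array([counts.get(c, 0) for c in cells])
        _, p = sps.chisquare(observed, 10_000 * a)
        assert p > 0.01


class TestSimulateWalk:
    def test_straight_line_walk(self, uniform_wild_landscape):
        params = hw.MovementParams(p_f=1.0, p_s=0.0, p_b=0.0)
        stats = hw.simulate_walk(
            uniform_wild_landscape, (100, 100), params, 50, np.random.default_rng(0)
        )
        assert stats.max_distance == 50
        assert stats.n_switches == 0
        assert stats.prop_wild == 1.0

    def test_r_zero_confines_to_nest_habitat(self, small_landscape, rng):
        nest = hw.place_nest(small_landscape, rng)
        params = hw.MovementParams.from_forward(0.6, 0.5, r=0.0)
        for seed in range(10):
            stats = hw.simulate_walk(
                small_landscape, nest, params, 300, np.random.default_rng(seed)
            )
            assert stats.prop_wild == 1.0
            assert stats.n_switches == 0

    def test_r_one_neutral_matches_uniform_habitat_walk(self, small_landscape):
        # r=1 ignores habitat: same random stream on the real landscape and on
        # a uniform-habitat copy of it yields the identical trajectory
        params = hw.MovementParams.from_forward(0.5, 0.3, r=1.0)
        flat = small_landscape.copy()
        flat.habitat_of[:] = hw.WILD
        a = hw.simulate_walk(
            small_landscape, (30, 30), params, 500, np.random.default_rng(3), record=True
        )
        b = hw.simulate_walk(
            flat, (30, 30), params, 500, np.random.default_rng(3), record=True
        )
        np.testing.assert_array_equal(a[1]["x"], b[1]["x"])
        np.testing.assert_array_equal(a[1]["y"], b[1]["y"])

    def test_max_distance_bounded_by_timesteps(self, small_landscape, rng):
        nest = hw.place_nest(small_landscape, rng)
        params = hw.MovementParams.from_forward(0.7, 0.2, r=0.8)
        for seed in range(5):
            stats = hw.simulate_walk(
                small_landscape, nest, params, 40, np.random.default_rng(seed)
            )
            assert stats.max_distance <= 40

    def test_trajectory_record_consistent_with_stats(self, small_landscape, rng):
        nest = hw.place_nest(small_landscape, rng)
        params = hw.MovementParams.from_forward(0.5, 0.5, r=0.5)
        stats, traj = hw.simulate_walk(
            small_landscape, nest, params, 200, np.random.default_rng(9), record=True
        )
        d = np.hypot(traj["x"] - nest[0], traj["y"] - nest[1])
        assert stats.max_distance == pytest.approx(d.max())
        assert stats.n_switches == int(traj["switched"].sum())
        assert stats.prop_wild == pytest.approx(
            (traj["habitat"] == hw.WILD).mean()
        )

    def test_nest_outside_grid_rejected(self, small_landscape, rng):
        params = hw.MovementParams.from_forward(0.5, 0.5)
        with pytest.raises(ParameterError):
            hw.simulate_walk(small_landscape, (99, 3), params, 10, rng)

    def test_stay_in_place_when_nowhere_to_go(self, rng):
        # wild nest cell fully surrounded by crop, r=0: walker never moves
        fields = np.arange(9).reshape(3, 3)
        habitat = np.zeros((3, 3), dtype=np.uint8)
        habitat[1, 1] = hw.WILD
        grid = hw.LandscapeGrid(3, 3, fields, habitat)
        params = hw.MovementParams(p_f=0.25, p_s=0.25, p_b=0.25, r=0.0)
        stats = hw.simulate_walk(grid, (1, 1), params, 30, rng)
        assert stats.max_distance == 0
        assert stats.prop_wild == 1.0
        assert stats.n_switches == 0
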