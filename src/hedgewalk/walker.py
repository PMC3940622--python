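"""Habitat-biased correlated random walk of a central-place forager.

The walker occupies one grid cell and carries a heading: the absolute
direction (N/E/S/W) of the move that brought it to its current cell. Each
timestep it picks one of the four orthogonal neighbours — forward, backward,
left or right relative to the heading — with base probabilities
``p_F``, ``p_B`` and ``p_S`` (each side), ``p_F + p_B + 2 p_S = 1``.

Habitat preference enters as a multiplicative switching reduction ``r``: the
preference for entering neighbour ``i`` is ``m_i = p_i`` when that cell has
the same habitat as the current cell and ``m_i = r * p_i`` when it differs.
Actual move probabilities are the normalised preferences
``a_i = m_i / (m_F + m_B + m_L + m_R)``. ``r = 1`` makes the walk
habitat-neutral; ``r = 0`` confines the walker to its starting habitat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .landscape import WILD, LandscapeGrid

# Absolute headings, clockwise from north; index into _DX/_DY.
NORTH, EAST, SOUTH, WEST = 0, 1, 2, 3
HEADING_NAMES = ("N", "E", "S", "W")
_DX = (0, 1, 0, -1)
_DY = (-1, 0, 1, 0)  # y grows downward (origin top-left)

#: Habitat label for a neighbour that lies outside the grid.
OFF_GRID: int = -1

# Relative direction order used throughout: forward, backward, left, right.
_REL_OFFSETS = (0, 2, 3, 1)  # heading rotations, clockwise quarter turns


class ParameterError(ValueError):
    """Raised for movement parameters outside their valid ranges."""


def base_probabilities(p_f: float, v: float) -> tuple[float, float, float]:
    """Base step kernel ``(p_F, p_S, p_B)`` from forward bias and side constant.

    ``p_S = (1 - p_F)/3 + v (1 - p_F)/6`` and ``p_B = 1 - p_F - 2 p_S``;
    ``v`` in [0, 1] tilts the non-forward mass between backward (v=0, all
    three residual directions equal) and sideways (v=1, no backward moves).
    """
    if not 0 < p_f <= 1:
        raise ParameterError(f"p_F must be in (0, 1], got {p_f}")
    if not 0 <= v <= 1:
        raise ParameterError(f"v must be in [0, 1], got {v}")
    p_s = (1.0 - p_f) / 3.0 + v * (1.0 - p_f) / 6.0
    p_b = 1.0 - p_f - 2.0 * p_s
    return p_f, p_s, max(p_b, 0.0)


@dataclass(frozen=True)
class MovementParams:
    """The walker's step kernel and habitat-switching reduction.

    ``p_f + p_b + 2 p_s`` must equal 1; ``r`` in [0, 1].
    """

    p_f: float
    p_s: float
    p_b: float
    r: float = 1.0

    def __post_init__(self) -> None:
        if min(self.p_f, self.p_s, self.p_b) < 0:
            raise ParameterError("step probabilities must be non-negative")
        if abs(self.p_f + self.p_b + 2 * self.p_s - 1.0) > 1e-12:
            raise ParameterError("p_F + p_B + 2 p_S must equal 1")
        if not 0 <= self.r <= 1:
            raise ParameterError(f"r must be in [0, 1], got {self.r}")

    @classmethod
    def from_forward(cls, p_f: float, v: float, r: float = 1.0) -> "MovementParams":
        """Build the kernel from ``(p_F, v)`` via :func:`base_probabilities`."""
        p_f, p_s, p_b = base_probabilities(p_f, v)
        return cls(p_f=p_f, p_s=p_s, p_b=p_b, r=r)

    def rel_probabilities(self) -> np.ndarray:
        """Base probabilities in (forward, backward, left, right) order."""
        return np.array([self.p_f, self.p_b, self.p_s, self.p_s])


@dataclass(frozen=True)
class WalkerState:
    x: int
    y: int
    heading: int  # NORTH/EAST/SOUTH/WEST


class NeighbourContext(NamedTuple):
    """Habitat labels around the walker, in relative terms.

    Each of ``c_f``/``c_b``/``c_l``/``c_r`` is CROP, WILD, or OFF_GRID.
    """

    c_current: int
    c_f: int
    c_b: int
    c_l: int
    c_r: int


@dataclass(frozen=True)
class TrajectoryStats:
    """Summary statistics of one simulated foraging walk.

    max_distance
        Maximum Euclidean distance (cell centres, grid units) from the nest
        over the walk's post-move positions.
    n_switches
        Number of habitat changes between consecutively occupied cells.
    prop_wild
        Fraction of the T post-move positions lying on wild cells (the nest
        cell at t=0 is excluded from the denominator).
    border_contacts
        Number of timesteps on which at least one neighbour lay off-grid;
        a diagnostic for boundary influence on the walk.
    """

    max_distance: float
    n_switches: int
    prop_wild: float
    border_contacts: int = 0


def neighbour_context(state: WalkerState, landscape: LandscapeGrid) -> NeighbourContext:
    """Read habitats of current cell and its four relative neighbours."""
    hab = landscape.habitat_of
    w, h = landscape.width, landscape.height

    def at(dir_abs: int) -> int:
        nx, ny = state.x + _DX[dir_abs], state.y + _DY[dir_abs]
        if 0 <= nx < w and 0 <= ny < h:
            return int(hab[ny, nx])
        return OFF_GRID

    dirs = [(state.heading + off) % 4 for off in _REL_OFFSETS]
    return NeighbourContext(
        c_current=int(hab[state.y, state.x]),
        c_f=at(dirs[0]),
        c_b=at(dirs[1]),
        c_l=at(dirs[2]),
        c_r=at(dirs[3]),
    )


def adjusted_preferences(
    params: MovementParams, ctx: NeighbourContext
) -> np.ndarray:
    """Preference 4-vector ``(m_F, m_B, m_L, m_R)``.

    Same habitat keeps the base probability, a differing habitat is scaled
    by ``r``, and off-grid neighbours get zero preference (moves off the
    landscape are forbidden; remaining directions are renormalised by
    :func:`step_probabilities`).
    """
    base = (params.p_f, params.p_b, params.p_s, params.p_s)
    labels = (ctx.c_f, ctx.c_b, ctx.c_l, ctx.c_r)
    m = np.empty(4)
    for i, (p, c) in enumerate(zip(base, labels)):
        if c == OFF_GRID:
            m[i] = 0.0
        elif c == ctx.c_current:
            m[i] = p
        else:
            m[i] = params.r * p
    return m


def step_probabilities(m: np.ndarray) -> np.ndarray | None:
    """Normalise preferences to move probabilities ``a_i = m_i / sum(m)``.

    Returns ``None`` (the stay-in-place sentinel) when every preference is
    zero — the walker has nowhere it is willing to go this timestep.
    """
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise ParameterError("preferences must be non-negative")
    total = m.sum()
    if total == 0:
        return None
    return m / total


def step(
    state: WalkerState,
    landscape: LandscapeGrid,
    params: MovementParams,
    rng: np.random.Generator,
) -> tuple[WalkerState, bool, bool]:
    """Advance the walker one timestep.

    Returns ``(new_state, moved, switched_habitat)``. On the stay-in-place
    sentinel the state is returned unchanged with both flags False.
    """
    ctx = neighbour_context(state, landscape)
    a = step_probabilities(adjusted_preferences(params, ctx))
    if a is None:
        return state, False, False
    k = int(rng.choice(4, p=a))  # index into (F, B, L, R)
    dir_abs = (state.heading + _REL_OFFSETS[k]) % 4
    nx, ny = state.x + _DX[dir_abs], state.y + _DY[dir_abs]
    switched = int(landscape.habitat_of[ny, nx]) != ctx.c_current
    return WalkerState(nx, ny, dir_abs), True, switched


def simulate_walk(
    landscape: LandscapeGrid,
    nest: tuple[int, int],
    params: MovementParams,
    T: int,
    rng: np.random.Generator,
    record: bool = False,
) -> TrajectoryStats | tuple[TrajectoryStats, dict[str, np.ndarray]]:
    """Simulate a T-step walk from the nest and summarise it.

    The initial heading is drawn uniformly from the four absolute
    directions. With ``record=True`` also returns per-timestep arrays
    (``t, x, y, heading, habitat, switched``) suitable for a trajectory dump.

    The step logic is inlined (rather than calling :func:`step` T times) for
    speed; behaviour is identical and covered by distributional tests.
    """
    if T < 1:
        raise ParameterError("T must be >= 1")
    w, h = landscape.width, landscape.height
    nx0, ny0 = nest
    if not (0 <= nx0 < w and 0 <= ny0 < h):
        raise ParameterError(f"nest {nest} outside the {w}x{h} grid")
    hab = landscape.habitat_of
    p_rel = (params.p_f, params.p_b, params.p_s, params.p_s)
    r = params.r

    x, y = nx0, ny0
    heading = int(rng.integers(4))
    u = rng.random(T)

    cur_hab = int(hab[y, x])
    max_d2 = 0.0
    n_switch = 0
    wild_steps = 0
    border = 0
    if record:
        rec_x = np.empty(T, dtype=np.int32)
        rec_y = np.empty(T, dtype=np.int32)
        rec_h = np.empty(T, dtype=np.int8)
        rec_hab = np.empty(T, dtype=np.int8)
        rec_sw = np.zeros(T, dtype=bool)

    for t in range(T):
        m0 = m1 = m2 = m3 = 0.0
        touched_border = False
        # forward, backward, left, right
        for k, off in enumerate(_REL_OFFSETS):
            d = (heading + off) & 3
            nx, ny = x + _DX[d], y + _DY[d]
            if 0 <= nx < w and 0 <= ny < h:
                c = hab[ny, nx]
                mk = p_rel[k] if c == cur_hab else r * p_rel[k]
            else:
                mk = 0.0
                touched_border = True
            if k == 0:
                m0 = mk
            elif k == 1:
                m1 = mk
            elif k == 2:
                m2 = mk
            else:
                m3 = mk
        if touched_border:
            border += 1
        total = m0 + m1 + m2 + m3
        if total > 0.0:
            z = u[t] * total
            if z < m0:
                k = 0
            elif z < m0 + m1:
                k = 1
            elif z < m0 + m1 + m2:
                k = 2
            else:
                k = 3
            heading = (heading + _REL_OFFSETS[k]) & 3
            x += _DX[heading]
            y += _DY[heading]
            new_hab = int(hab[y, x])
            if new_hab != cur_hab:
                n_switch += 1
                switched = True
            else:
                switched = False
            cur_hab = new_hab
        else:
            switched = False  # stay in place; heading unchanged
        if cur_hab == WILD:
            wild_steps += 1
        d2 = (x - nx0) ** 2 + (y - ny0) ** 2
        if d2 > max_d2:
            max_d2 = d2
        if record:
            rec_x[t], rec_y[t], rec_h[t] = x, y, heading
            rec_hab[t], rec_sw[t] = cur_hab, switched

    stats = TrajectoryStats(
        max_distance=float(np.sqrt(max_d2)),
        n_switches=n_switch,
        prop_wild=wild_steps / T,
        border_contacts=border,
    )
    if record:
        traj = {
            "t": np.arange(1, T + 1),
            "x": rec_x,
            "y": rec_y,
            "heading": rec_h,
            "habitat": rec_hab,
            "switched": rec_sw,
        }
        return stats, traj
    return stats
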