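"""Voronoi-tessellated agricultural landscapes with wild field-edge corridors.

A landscape is a rectangular grid of unit cells. A configured number of
*field seeds* is dropped uniformly at random onto distinct cells, and every
cell joins the field of its nearest seed (a grid-based Voronoi tessellation).
Cells on the boundary between two fields form single-cell-thick strips of
wild habitat ("hedgerows"); everything else is cultivated crop. Pollinator
nests sit inside the wild strips, which act as the corridor network of the
landscape.

Coordinate convention: 0-based, ``x`` = column, ``y`` = row, origin at the
top-left. Arrays are indexed ``[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

#: Habitat labels used in ``habitat_of`` rasters.
CROP: int = 0
WILD: int = 1

#: 4-connected (orthogonal) structuring element for connectivity queries.
_ORTHO = ndimage.generate_binary_structure(2, 1)


class LandscapeError(ValueError):
    """Raised for invalid landscape configurations or impossible requests."""


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of one generated landscape.

    Parameters
    ----------
    width, height
        Grid dimensions in cells; both must exceed 1.
    n_fields
        Number of Voronoi field seeds (>= 1, at most ``width * height``).
    rng_seed
        Optional seed recorded for provenance; generation functions take an
        explicit :class:`numpy.random.Generator` so the config itself is
        purely descriptive.
    """

    width: int
    height: int
    n_fields: int
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.width <= 1 or self.height <= 1:
            raise LandscapeError("grid must be at least 2 cells in each dimension")
        if self.n_fields < 1:
            raise LandscapeError("n_fields must be >= 1")
        if self.n_fields > self.width * self.height:
            raise LandscapeError(
                f"cannot place {self.n_fields} distinct seeds on a "
                f"{self.width}x{self.height} grid"
            )


@dataclass(frozen=True)
class FieldSeed:
    """Generating point of one Voronoi field."""

    field_id: int
    x: int
    y: int


@dataclass
class LandscapeGrid:
    """A tessellated landscape: per-cell field membership and habitat.

    ``field_of[y, x]`` is the id of the field the cell belongs to and never
    changes under manipulation; ``habitat_of[y, x]`` is :data:`CROP` or
    :data:`WILD` and is what set-aside conversion and hedge removal modify.
    """

    width: int
    height: int
    field_of: np.ndarray
    habitat_of: np.ndarray
    seeds: list[FieldSeed] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.field_of = np.asarray(self.field_of, dtype=np.int32)
        self.habitat_of = np.asarray(self.habitat_of, dtype=np.uint8)
        if self.field_of.shape != (self.height, self.width):
            raise LandscapeError("field_of shape disagrees with stated dimensions")
        if self.habitat_of.shape != (self.height, self.width):
            raise LandscapeError("habitat_of shape disagrees with stated dimensions")

    @property
    def n_fields(self) -> int:
        return int(self.field_of.max()) + 1

    def wild_count(self) -> int:
        return int((self.habitat_of == WILD).sum())

    def wild_cells(self) -> np.ndarray:
        """(n, 2) array of (y, x) coordinates of wild cells, row-major order."""
        return np.argwhere(self.habitat_of == WILD)

    def copy(self) -> "LandscapeGrid":
        return LandscapeGrid(
            self.width,
            self.height,
            self.field_of.copy(),
            self.habitat_of.copy(),
            list(self.seeds),
        )


def generate_seeds(config: LandscapeConfig, rng: np.random.Generator) -> list[FieldSeed]:
    """Drop ``config.n_fields`` seeds on uniformly random distinct cells."""
    n_cells = config.width * config.height
    flat = rng.choice(n_cells, size=config.n_fields, replace=False)
    ys, xs = np.divmod(flat, config.width)
    return [FieldSeed(i, int(x), int(y)) for i, (x, y) in enumerate(zip(xs, ys))]


def assign_fields(
    seeds: Sequence[FieldSeed], width: int, height: int
) -> np.ndarray:
    """Assign every cell to the field of the nearest seed (Euclidean, cell centres).

    Ties go to the lowest ``field_id``: distances are computed in exact
    integer arithmetic (squared Euclidean between integer cell coordinates)
    and ``argmin`` keeps the first minimum. Seeds are sorted by ``field_id``
    first, so the result is independent of the order the seeds are listed in.
    """
    if not seeds:
        raise LandscapeError("assign_fields requires at least one seed")
    order = sorted(seeds, key=lambda s: s.field_id)
    ids = np.array([s.field_id for s in order], dtype=np.int32)
    sx = np.array([s.x for s in order], dtype=np.int64)
    sy = np.array([s.y for s in order], dtype=np.int64)

    out = np.empty((height, width), dtype=np.int32)
    xs = np.arange(width, dtype=np.int64)
    # Process in row blocks to bound the (cells x seeds) distance matrix.
    block = max(1, int(4_000_000 // max(len(order) * width, 1)) + 1)
    for y0 in range(0, height, block):
        y1 = min(y0 + block, height)
        ys_blk = np.arange(y0, y1, dtype=np.int64)
        dx2 = (xs[None, :, None] - sx[None, None, :]) ** 2
        dy2 = (ys_blk[:, None, None] - sy[None, None, :]) ** 2
        nearest = np.argmin(dx2 + dy2, axis=2)
        out[y0:y1] = ids[nearest]
    return out


def classify_hedgerows(field_map: np.ndarray) -> np.ndarray:
    """Mark single-thickness wild strips along field boundaries.

    A cell is WILD iff its right or lower orthogonal neighbour belongs to a
    different field (one-sided scan). Marking only one side of each
    field-field interface keeps every strip exactly one cell wide; the
    naive "any differing neighbour" rule would mark both sides. Cells on
    the grid border are compared only against in-grid neighbours.

    The resulting corridor network is connected as a geometric object —
    under 8-adjacency (diagonals included) it is almost always a single
    component — but along staircase (non-axis-aligned) boundaries
    consecutive strip cells meet only at corners, so under strict
    orthogonal adjacency the network breaks into many fragments. Walkers
    move orthogonally, which makes this fragmentation a real feature of
    the model: habitat specialists (switching reduction r = 0) are
    confined to the fragment their nest sits on, and interventions that
    add wild area (set-asides) can merge fragments and markedly extend
    their range. See :func:`wild_components` to quantify both views.
    """
    field_map = np.asarray(field_map)
    habitat = np.zeros(field_map.shape, dtype=np.uint8)
    habitat[:, :-1][field_map[:, :-1] != field_map[:, 1:]] = WILD
    habitat[:-1, :][field_map[:-1, :] != field_map[1:, :]] = WILD
    return habitat


def generate_landscape(
    config: LandscapeConfig, rng: np.random.Generator
) -> LandscapeGrid:
    """Generate a full landscape: seeds -> Voronoi fields -> hedgerow strips."""
    seeds = generate_seeds(config, rng)
    field_map = assign_fields(seeds, config.width, config.height)
    habitat = classify_hedgerows(field_map)
    return LandscapeGrid(config.width, config.height, field_map, habitat, seeds)


def place_nest(
    landscape: LandscapeGrid, rng: np.random.Generator
) -> tuple[int, int]:
    """Pick a uniformly random wild cell as the nest; returns ``(x, y)``.

    Central-place foragers are assumed to nest inside the field edges, the
    cultivated interior being too disturbed.
    """
    cells = landscape.wild_cells()
    if len(cells) == 0:
        raise LandscapeError("landscape has no wild cells to place a nest in")
    y, x = cells[rng.integers(len(cells))]
    return int(x), int(y)


def wild_components(
    landscape: LandscapeGrid, diagonal: bool = False
) -> tuple[np.ndarray, int]:
    """Label connected components of the wild cell set.

    Returns ``(labels, n_components)`` where ``labels`` is 0 on crop cells
    and 1..n on wild cells. With ``diagonal=False`` (the default)
    components are orthogonally connected — the adjacency a walker
    experiences, under which generated corridor networks are highly
    fragmented. With ``diagonal=True`` corner contacts count as connected,
    and the generated network is almost always a single component.
    """
    structure = np.ones((3, 3), dtype=bool) if diagonal else _ORTHO
    labels, n = ndimage.label(landscape.habitat_of == WILD, structure=structure)
    return labels, int(n)


def isolated_wild_cells(landscape: LandscapeGrid) -> np.ndarray:
    """(n, 2) (y, x) coordinates of wild cells with no orthogonal wild neighbour."""
    wild = landscape.habitat_of == WILD
    neigh = np.zeros(wild.shape, dtype=np.int8)
    neigh[:, :-1] += wild[:, 1:]
    neigh[:, 1:] += wild[:, :-1]
    neigh[:-1, :] += wild[1:, :]
    neigh[1:, :] += wild[:-1, :]
    return np.argwhere(wild & (neigh == 0))
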