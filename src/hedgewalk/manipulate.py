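"""Landscape interventions: set-aside conversion and hedgerow removal.

Two manipulations common to agricultural stewardship policy are modelled:

* converting whole crop fields to wild *set-aside* (every cell of the chosen
  field becomes wild habitat), and
* removing individual *hedges* — the wild strip separating one specific pair
  of adjacent fields — whose cells revert to crop.

Both act on the habitat raster only; Voronoi field membership is immutable,
so manipulations are reversible on paper and cumulative in practice via the
caller-held ``already_*`` sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import CROP, WILD, LandscapeGrid


class ScheduleError(ValueError):
    """Raised when a manipulation schedule cannot be satisfied."""


@dataclass(frozen=True)
class Hedge:
    """The wild strip between one adjacent field pair.

    ``field_pair`` is the unordered (stored sorted) pair of field ids;
    ``cells`` the (y, x) coordinates of the member hedgerow cells.
    """

    field_pair: tuple[int, int]
    cells: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.cells)


def convert_setasides(
    landscape: LandscapeGrid,
    k_new: int,
    already_converted: frozenset[int] | set[int],
    rng: np.random.Generator,
) -> tuple[LandscapeGrid, frozenset[int]]:
    """Convert ``k_new`` further randomly-chosen fields entirely to wild.

    Fields already in ``already_converted`` are ineligible; the returned set
    is the cumulative record to pass to the next call. The input landscape
    is not modified.
    """
    converted = frozenset(already_converted)
    eligible = np.array(
        sorted(set(range(landscape.n_fields)) - converted), dtype=np.int64
    )
    if k_new < 0:
        raise ScheduleError("k_new must be non-negative")
    if k_new > len(eligible):
        raise ScheduleError(
            f"asked for {k_new} new set-asides but only {len(eligible)} "
            "unconverted fields remain"
        )
    out = landscape.copy()
    if k_new == 0:
        return out, converted
    chosen = rng.choice(eligible, size=k_new, replace=False)
    out.habitat_of[np.isin(out.field_of, chosen)] = WILD
    return out, converted | frozenset(int(f) for f in chosen)


def enumerate_hedges(landscape: LandscapeGrid) -> list[Hedge]:
    """List the individual hedges of a basal (unmanipulated) landscape.

    A wild cell belongs to the hedge between fields A and B iff its own
    field id is A or B and the field ids seen among itself and its in-grid
    orthogonal neighbours are exactly ``{A, B}``. Junction cells touching
    three or more fields belong to no hedge: they are the vertices of the
    corridor network and are preserved under removal. Hedges are returned
    sorted by field pair.
    """
    fields = landscape.field_of
    h, w = fields.shape
    members: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for y, x in landscape.wild_cells():
        own = int(fields[y, x])
        seen = {own}
        if x > 0:
            seen.add(int(fields[y, x - 1]))
        if x < w - 1:
            seen.add(int(fields[y, x + 1]))
        if y > 0:
            seen.add(int(fields[y - 1, x]))
        if y < h - 1:
            seen.add(int(fields[y + 1, x]))
        if len(seen) == 2:
            pair = tuple(sorted(seen))
            members.setdefault(pair, []).append((int(y), int(x)))
    return [
        Hedge(field_pair=pair, cells=tuple(cells))
        for pair, cells in sorted(members.items())
    ]


def remove_hedges(
    landscape: LandscapeGrid,
    hedges: list[Hedge],
    k_new: int,
    already_removed: frozenset[int] | set[int],
    rng: np.random.Generator,
) -> tuple[LandscapeGrid, frozenset[int]]:
    """Remove ``k_new`` further randomly-chosen hedges (cells become crop).

    ``already_removed`` holds indices into ``hedges`` from previous calls;
    enumeration is always defined on the basal landscape, removal state
    lives in this set. The input landscape is not modified.
    """
    removed = frozenset(already_removed)
    eligible = np.array(
        sorted(set(range(len(hedges))) - removed), dtype=np.int64
    )
    if k_new < 0:
        raise ScheduleError("k_new must be non-negative")
    if k_new > len(eligible):
        raise ScheduleError(
            f"asked to remove {k_new} more hedges but only {len(eligible)} remain"
        )
    out = landscape.copy()
    if k_new == 0:
        return out, removed
    chosen = rng.choice(eligible, size=k_new, replace=False)
    for idx in chosen:
        for y, x in hedges[int(idx)].cells:
            out.habitat_of[y, x] = CROP
    return out, removed | frozenset(int(i) for i in chosen)
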