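"""Plain-text readers/writers: landscape rasters, results tables, run manifests.

Landscape raster dialect
------------------------
A landscape is stored as two whitespace-separated integer grids, one row of
cells per line: ``<stem>.fields.txt`` (per-cell field id) and
``<stem>.habitat.txt`` (0 = crop, 1 = wild). Each file starts with a 3-line
``#`` header giving the dimensions, the generating seed (or ``unknown``)
and the coordinate convention. ``write`` followed by ``read`` is the
identity on the grids.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .landscape import CROP, WILD, LandscapeGrid

_CONVENTION = "0-based; x=column, y=row; origin top-left; row per line"


class RasterFormatError(ValueError):
    """Raised when a landscape raster file violates the documented dialect."""


def _write_grid(path: Path, grid: np.ndarray, kind: str, seed) -> None:
    h, w = grid.shape
    header = (
        f"# hedgewalk {kind} raster: width={w} height={h}\n"
        f"# seed={seed if seed is not None else 'unknown'}\n"
        f"# convention: {_CONVENTION}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt="%d")


def _read_grid(path: Path) -> tuple[np.ndarray, int, int]:
    lines = Path(path).read_text().splitlines()
    header = [l for l in lines if l.startswith("#")]
    if not header or "width=" not in header[0]:
        raise RasterFormatError(f"{path}: missing raster header")
    first = header[0]
    dims = dict(
        tok.split("=") for tok in first.split(":")[1].split() if "=" in tok
    )
    width, height = int(dims["width"]), int(dims["height"])
    body = [l for l in lines if l and not l.startswith("#")]
    try:
        grid = np.array([[int(tok) for tok in l.split()] for l in body])
    except ValueError as exc:
        raise RasterFormatError(f"{path}: non-integer cell value") from exc
    if grid.shape != (height, width):
        raise RasterFormatError(
            f"{path}: header says {width}x{height}, body is "
            f"{grid.shape[1]}x{grid.shape[0]}"
        )
    return grid, width, height


def write_landscape_raster(
    landscape: LandscapeGrid, stem: str | Path, seed: int | None = None
) -> tuple[Path, Path]:
    """Write ``<stem>.fields.txt`` and ``<stem>.habitat.txt``; returns the paths."""
    stem = Path(stem)
    fpath = stem.with_suffix(stem.suffix + ".fields.txt")
    hpath = stem.with_suffix(stem.suffix + ".habitat.txt")
    _write_grid(fpath, landscape.field_of, "field_id", seed)
    _write_grid(hpath, landscape.habitat_of, "habitat", seed)
    return fpath, hpath


def read_landscape_raster(stem: str | Path) -> LandscapeGrid:
    """Read a landscape written by :func:`write_landscape_raster`.

    Accepts either the stem or the path of one of the two member files.
    Seed points are not stored in the raster dialect, so the returned
    grid's ``seeds`` list is empty.
    """
    stem = str(stem)
    for suffix in (".fields.txt", ".habitat.txt"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    fields, fw, fh = _read_grid(Path(stem + ".fields.txt"))
    habitat, hw, hh = _read_grid(Path(stem + ".habitat.txt"))
    if (fw, fh) != (hw, hh):
        raise RasterFormatError(
            f"field grid is {fw}x{fh} but habitat grid is {hw}x{hh}"
        )
    bad = set(np.unique(habitat)) - {CROP, WILD}
    if bad:
        raise RasterFormatError(f"habitat values outside {{0, 1}}: {sorted(bad)}")
    return LandscapeGrid(fw, fh, fields, habitat)


def write_habitat_pgm(landscape: LandscapeGrid, path: str | Path) -> Path:
    """Export the habitat grid as an ASCII PGM (P2) image for visual checks.

    Crop cells are white (255), wild cells black (0), matching the
    white-fields / black-hedgerows rendering convention.
    """
    path = Path(path)
    img = np.where(landscape.habitat_of == WILD, 0, 255)
    with open(path, "w") as fh:
        fh.write(f"P2\n{landscape.width} {landscape.height}\n255\n")
        np.savetxt(fh, img, fmt="%d")
    return path


def write_results_csv(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a results table as CSV, bytewise reproducible for equal inputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, lineterminator="\n", float_format="%.12g")
    return path


def write_trajectory_csv(traj: dict[str, np.ndarray], path: str | Path) -> Path:
    """Dump a recorded trajectory (t, x, y, heading, habitat, switched) as CSV."""
    return write_results_csv(pd.DataFrame(traj), path)


@dataclass
class RunManifest:
    """Provenance record sufficient to reproduce a run byte-for-byte."""

    protocol: str
    master_seed: int
    config: dict = field(default_factory=dict)
    counters: dict = field(default_factory=dict)
    version: str = __version__

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path


def load_config_yaml(path: str | Path) -> dict:
    """Flat-key YAML config file -> dict of overrides for ExperimentConfig."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping of keys to values")
    return data
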