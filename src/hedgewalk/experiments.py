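"""Experiment protocols: the six model runs and factorial sensitivity sweeps.

Each protocol generates a batch of independent environments (a Voronoi
landscape plus a nest and a set of nuisance movement parameters drawn once
per environment), runs one walk per level of the systematically varied
variable, and returns a long-format results table with one row per
(environment, level) — the repeated-measures structure the statistical
analysis relies on.

Protocols
---------
M1   vary the forward bias p_F over {0.25, 0.375, ..., 0.875}
M2   vary the switching reduction r over {(2/3)^0, ..., (2/3)^13}
M3   cumulatively convert 0, 5, ..., 50 fields to wild set-aside
M3a  as M3 with r = 0 (habitat specialists); max distance only
M4   cumulatively remove 0, 4, ..., 40 hedges
M4a  as M4 with r = 0; max distance only
SENS factorial sweeps of a movement/landscape axis against a manipulation

Defaults are the full study conditions: 1000 environments of 1000 x 1000
cells with 101-200 fields, walks of 1000 timesteps. Scaled-down runs simply
pass a smaller :class:`ExperimentConfig`.

Randomness is organised as a spawn tree of ``numpy.random.SeedSequence``:
one child per environment, and within an environment named substreams for
the landscape, the nest, the nuisance parameters, the manipulation schedule
and each level's walk — so adding levels or environments never perturbs the
others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import (
    LandscapeConfig,
    LandscapeGrid,
    WILD,
    generate_landscape,
    place_nest,
)
from .manipulate import convert_setasides, enumerate_hedges, remove_hedges
from .walker import MovementParams, TrajectoryStats, simulate_walk

# Systematic levels of each protocol.
MODEL1_PF_LEVELS: tuple[float, ...] = tuple(0.25 + 0.125 * k for k in range(6))
MODEL2_R_LEVELS: tuple[float, ...] = tuple((2.0 / 3.0) ** k for k in range(14))
SETASIDE_POINTS: tuple[int, ...] = tuple(range(0, 51, 5))
HEDGE_POINTS: tuple[int, ...] = tuple(range(0, 41, 4))

# Sensitivity-axis levels.
SENS_PF_LEVELS: tuple[float, ...] = tuple(round(0.1 * k, 10) for k in range(1, 10))
SENS_PS_LEVELS: tuple[float, ...] = tuple(round(0.05 * k, 10) for k in range(10))
SENS_R_LEVELS: tuple[float, ...] = tuple(round(0.1 * k, 10) for k in range(10))
SENS_NFIELDS_LEVELS: tuple[int, ...] = (101, 120, 140, 160, 180, 200)

_STAT_COLS = ("max_distance", "n_switches", "prop_wild")


@dataclass(frozen=True)
class ExperimentConfig:
    """Conditions of one protocol run.

    Defaults are the full study conditions; pass smaller values for desk
    runs. ``n_fields_range`` is inclusive on both ends.
    """

    n_environments: int = 1000
    width: int = 1000
    height: int = 1000
    n_fields_range: tuple[int, int] = (101, 200)
    timesteps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_fields_range
        if not (1 <= lo <= hi):
            raise ValueError("n_fields_range must satisfy 1 <= lo <= hi")
        if self.n_environments < 1 or self.timesteps < 1:
            raise ValueError("n_environments and timesteps must be >= 1")


@dataclass
class RunLog:
    """Counters accumulated during a protocol run (redraws, boundary contact)."""

    landscape_redraws: int = 0
    nest_redraws: int = 0
    border_contacts: int = 0


def _draw_n_fields(cfg: ExperimentConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.n_fields_range
    return int(rng.integers(lo, hi + 1))


def _make_environment(
    cfg: ExperimentConfig,
    land_ss: np.random.SeedSequence,
    nest_ss: np.random.SeedSequence,
    log: RunLog,
    min_hedges: int = 0,
    min_setaside_fields: int = 0,
):
    """Generate a landscape (+nest, +hedges if requested), redrawing on failure.

    A landscape is redrawn when it has no wild cell to nest in, fewer
    hedges than the removal schedule needs, or fewer fields than the
    set-aside schedule needs; each redraw is counted in the run log.
    """
    while True:
        rng = np.random.default_rng(land_ss.spawn(1)[0])
        n_fields = _draw_n_fields(cfg, rng)
        grid = generate_landscape(
            LandscapeConfig(cfg.width, cfg.height, n_fields), rng
        )
        hedges = enumerate_hedges(grid) if min_hedges else []
        if (
            grid.wild_count() > 0
            and len(hedges) >= min_hedges
            and n_fields >= min_setaside_fields
        ):
            break
        log.landscape_redraws += 1
    nest = place_nest(grid, np.random.default_rng(nest_ss))
    return grid, nest, hedges


def _row(
    env_id: int,
    protocol: str,
    level_name: str,
    level_value,
    stats: TrajectoryStats | None,
    nuisance: dict,
) -> dict:
    row = {"env_id": env_id, "protocol": protocol, level_name: level_value}
    row.update(nuisance)
    if stats is None:
        row.update(max_distance=np.nan, n_switches=np.nan, prop_wild=np.nan,
                   border_contacts=np.nan)
    else:
        row.update(
            max_distance=stats.max_distance,
            n_switches=stats.n_switches,
            prop_wild=stats.prop_wild,
            border_contacts=stats.border_contacts,
        )
    return row


def _finish(rows: list[dict], log: RunLog) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df.attrs["run_log"] = log
    return df


def run_model1(config: ExperimentConfig) -> pd.DataFrame:
    """Effect of movement choice: vary p_F, nuisance r and v drawn per environment."""
    master = np.random.SeedSequence(config.seed)
    rows: list[dict] = []
    log = RunLog()
    for env_id, env_ss in enumerate(master.spawn(config.n_environments)):
        land_ss, nest_ss, par_ss, walk_ss = env_ss.spawn(4)
        grid, nest, _ = _make_environment(config, land_ss, nest_ss, log)
        prng = np.random.default_rng(par_ss)
        r, v = prng.uniform(), prng.uniform()
        for level_ss, p_f in zip(walk_ss.spawn(len(MODEL1_PF_LEVELS)), MODEL1_PF_LEVELS):
            params = MovementParams.from_forward(p_f, v, r)
            stats = simulate_walk(
                grid, nest, params, config.timesteps, np.random.default_rng(level_ss)
            )
            log.border_contacts += stats.border_contacts
            rows.append(
                _row(env_id, "M1", "p_F", p_f, stats,
                     {"r": r, "v": v, "n_fields": grid.n_fields,
                      "nest_x": nest[0], "nest_y": nest[1]})
            )
    return _finish(rows, log)


def run_model2(config: ExperimentConfig) -> pd.DataFrame:
    """Effect of the switching reduction: vary r over (2/3)^k, k = 0..13."""
    master = np.random.SeedSequence(config.seed)
    rows: list[dict] = []
    log = RunLog()
    for env_id, env_ss in enumerate(master.spawn(config.n_environments)):
        land_ss, nest_ss, par_ss, walk_ss = env_ss.spawn(4)
        grid, nest, _ = _make_environment(config, land_ss, nest_ss, log)
        prng = np.random.default_rng(par_ss)
        p_f, v = prng.uniform(0.25, 1.0), prng.uniform()
        for level_ss, r in zip(walk_ss.spawn(len(MODEL2_R_LEVELS)), MODEL2_R_LEVELS):
            params = MovementParams.from_forward(p_f, v, r)
            stats = simulate_walk(
                grid, nest, params, config.timesteps, np.random.default_rng(level_ss)
            )
            log.border_contacts += stats.border_contacts
            rows.append(
                _row(env_id, "M2", "r", r, stats,
                     {"p_F": p_f, "v": v, "n_fields": grid.n_fields,
                      "nest_x": nest[0], "nest_y": nest[1]})
            )
    return _finish(rows, log)


def _run_setaside(
    config: ExperimentConfig,
    protocol: str,
    r_fixed: float | None,
    record_all_stats: bool,
) -> pd.DataFrame:
    master = np.random.SeedSequence(config.seed)
    rows: list[dict] = []
    log = RunLog()
    max_k = max(SETASIDE_POINTS)
    for env_id, env_ss in enumerate(master.spawn(config.n_environments)):
        land_ss, nest_ss, par_ss, manip_ss, walk_ss = env_ss.spawn(5)
        grid, nest, _ = _make_environment(
            config, land_ss, nest_ss, log, min_setaside_fields=max_k
        )
        prng = np.random.default_rng(par_ss)
        p_f, v = prng.uniform(0.25, 1.0), prng.uniform()
        r = prng.uniform() if r_fixed is None else r_fixed
        mrng = np.random.default_rng(manip_ss)
        converted: frozenset[int] = frozenset()
        current = grid
        for level_ss, k in zip(walk_ss.spawn(len(SETASIDE_POINTS)), SETASIDE_POINTS):
            current, converted = convert_setasides(
                current, k - len(converted), converted, mrng
            )
            params = MovementParams.from_forward(p_f, v, r)
            stats = simulate_walk(
                current, nest, params, config.timesteps, np.random.default_rng(level_ss)
            )
            log.border_contacts += stats.border_contacts
            nuis = {"p_F": p_f, "v": v, "r": r, "n_fields": grid.n_fields,
                    "nest_x": nest[0], "nest_y": nest[1]}
            if record_all_stats:
                rows.append(_row(env_id, protocol, "n_setasides", k, stats, nuis))
            else:  # distance-only protocols (habitat specialists)
                row = _row(env_id, protocol, "n_setasides", k, None, nuis)
                row["max_distance"] = stats.max_distance
                rows.append(row)
    return _finish(rows, log)


def run_model3(config: ExperimentConfig) -> pd.DataFrame:
    """Effect of set-aside insertion; r drawn uniformly per environment."""
    return _run_setaside(config, "M3", r_fixed=None, record_all_stats=True)


def run_model3a(config: ExperimentConfig, record_all_stats: bool = False) -> pd.DataFrame:
    """Set-aside insertion for habitat specialists (r = 0).

    With ``r = 0`` the pollinators never swap habitats, so only the maximum
    geometric distance from the nest is recorded; ``record_all_stats=True``
    retains all three statistics for auditing the confinement property.
    """
    return _run_setaside(config, "M3a", r_fixed=0.0, record_all_stats=record_all_stats)


def _run_hedge_removal(
    config: ExperimentConfig,
    protocol: str,
    r_fixed: float | None,
    record_all_stats: bool,
) -> pd.DataFrame:
    master = np.random.SeedSequence(config.seed)
    rows: list[dict] = []
    log = RunLog()
    n_hedges_needed = max(HEDGE_POINTS)
    for env_id, env_ss in enumerate(master.spawn(config.n_environments)):
        land_ss, nest_ss, par_ss, manip_ss, walk_ss = env_ss.spawn(5)
        grid, nest, hedges = _make_environment(
            config, land_ss, nest_ss, log, min_hedges=n_hedges_needed
        )
        prng = np.random.default_rng(par_ss)
        p_f, v = prng.uniform(0.25, 1.0), prng.uniform()
        r = prng.uniform() if r_fixed is None else r_fixed
        mrng = np.random.default_rng(manip_ss)
        nest_rng = np.random.default_rng(nest_ss.spawn(1)[0])
        removed: frozenset[int] = frozenset()
        current = grid
        for level_ss, k in zip(walk_ss.spawn(len(HEDGE_POINTS)), HEDGE_POINTS):
            current, removed = remove_hedges(
                current, hedges, k - len(removed), removed, mrng
            )
            if current.habitat_of[nest[1], nest[0]] != WILD:
                # nest hedge was removed: redraw from the remaining wild cells
                nest = place_nest(current, nest_rng)
                log.nest_redraws += 1
            params = MovementParams.from_forward(p_f, v, r)
            stats = simulate_walk(
                current, nest, params, config.timesteps, np.random.default_rng(level_ss)
            )
            log.border_contacts += stats.border_contacts
            nuis = {"p_F": p_f, "v": v, "r": r, "n_fields": grid.n_fields,
                    "n_hedges": len(hedges), "nest_x": nest[0], "nest_y": nest[1]}
            if record_all_stats:
                rows.append(_row(env_id, protocol, "n_removed", k, stats, nuis))
            else:
                row = _row(env_id, protocol, "n_removed", k, None, nuis)
                row["max_distance"] = stats.max_distance
                rows.append(row)
    return _finish(rows, log)


def run_model4(config: ExperimentConfig) -> pd.DataFrame:
    """Effect of cumulative hedgerow removal; r drawn uniformly per environment."""
    return _run_hedge_removal(config, "M4", r_fixed=None, record_all_stats=True)


def run_model4a(config: ExperimentConfig, record_all_stats: bool = False) -> pd.DataFrame:
    """Hedgerow removal for habitat specialists (r = 0); distance only."""
    return _run_hedge_removal(config, "M4a", r_fixed=0.0, record_all_stats=record_all_stats)


# ---------------------------------------------------------------------------
# Factorial sensitivity analysis
# ---------------------------------------------------------------------------

SENS_AXES = {
    "p_F": SENS_PF_LEVELS,
    "p_S": SENS_PS_LEVELS,
    "r": SENS_R_LEVELS,
    "n_fields": SENS_NFIELDS_LEVELS,
}


def _draw_nuisance(prng: np.random.Generator) -> dict[str, float]:
    """Nuisance parameters for one sensitivity parameter set (drawn once)."""
    return {
        "p_F": prng.uniform(0.25, 1.0),
        "v": prng.uniform(),
        "r": prng.uniform(),
        "u_pf": prng.uniform(),  # multiplier used by the p_S-axis construction
    }


def _sens_kernel(axis: str, level, nuis: dict[str, float]) -> MovementParams:
    """Movement kernel for one sensitivity grid point.

    Parameters not on the systematic axis come from the set's nuisance
    draw; the p_S axis fixes p_S directly and sets
    p_F = (1 - 2 p_S) * U[0, 1], which guarantees p_B >= 0.
    """
    if axis == "p_F":
        return MovementParams.from_forward(level, nuis["v"], nuis["r"])
    if axis == "p_S":
        p_s = float(level)
        p_f = (1.0 - 2.0 * p_s) * nuis["u_pf"]
        return MovementParams(
            p_f=p_f, p_s=p_s, p_b=1.0 - p_f - 2.0 * p_s, r=nuis["r"]
        )
    if axis == "r":
        return MovementParams.from_forward(nuis["p_F"], nuis["v"], level)
    if axis == "n_fields":
        return MovementParams.from_forward(nuis["p_F"], nuis["v"], nuis["r"])
    raise ValueError(f"unknown sensitivity axis {axis!r}")


def _manipulated_sequence(
    grid: LandscapeGrid,
    manip: str,
    points: tuple[int, ...],
    mrng: np.random.Generator,
) -> list[LandscapeGrid]:
    """Cumulative landscape sequence along a manipulation schedule."""
    seq = []
    current = grid
    if manip == "set_aside":
        converted: frozenset[int] = frozenset()
        for k in points:
            current, converted = convert_setasides(
                current, k - len(converted), converted, mrng
            )
            seq.append(current)
    elif manip == "hedge_removal":
        hedges = enumerate_hedges(grid)
        removed: frozenset[int] = frozenset()
        for k in points:
            current, removed = remove_hedges(
                current, hedges, k - len(removed), removed, mrng
            )
            seq.append(current)
    else:
        raise ValueError(f"unknown manipulation {manip!r}")
    return seq


def run_sensitivity(
    config: ExperimentConfig,
    axis: str,
    manip: str,
    n_param_sets: int = 1000,
    return_raw: bool = False,
) -> pd.DataFrame:
    """Factorial sweep of one axis against a manipulation schedule.

    ``axis`` is one of ``p_F``, ``p_S``, ``r``, ``n_fields``; ``manip`` is
    ``set_aside`` (assay points 0, 5, ..., 50) or ``hedge_removal``
    (0, 4, ..., 40). For each of ``n_param_sets`` randomised nuisance
    parameter sets, one walker traverses every combination of axis level and
    assay point; the same landscape and manipulation sequence are shared
    across axis levels (except on the ``n_fields`` axis, where the landscape
    is the axis). Returns per-grid-point mean and standard deviation of the
    three movement statistics, or the raw per-walk table with
    ``return_raw=True``.
    """
    if axis not in SENS_AXES:
        raise ValueError(f"unknown sensitivity axis {axis!r}")
    levels = SENS_AXES[axis]
    points = SETASIDE_POINTS if manip == "set_aside" else HEDGE_POINTS
    if manip not in ("set_aside", "hedge_removal"):
        raise ValueError(f"unknown manipulation {manip!r}")
    min_hedges = max(points) if manip == "hedge_removal" else 0
    min_fields = max(points) if manip == "set_aside" else 0

    master = np.random.SeedSequence(config.seed)
    rows: list[dict] = []
    log = RunLog()
    for set_id, env_ss in enumerate(master.spawn(n_param_sets)):
        land_ss, nest_ss, par_ss, manip_ss, walk_ss = env_ss.spawn(5)
        nuis = _draw_nuisance(np.random.default_rng(par_ss))
        if axis != "n_fields":
            grid, nest, _ = _make_environment(
                config, land_ss, nest_ss, log,
                min_hedges=min_hedges, min_setaside_fields=min_fields,
            )
            seq = _manipulated_sequence(
                grid, manip, points, np.random.default_rng(manip_ss)
            )
        for level_ss, level in zip(walk_ss.spawn(len(levels)), levels):
            if axis == "n_fields":
                sub = ExperimentConfig(
                    n_environments=1, width=config.width, height=config.height,
                    n_fields_range=(int(level), int(level)),
                    timesteps=config.timesteps, seed=config.seed,
                )
                grid, nest, _ = _make_environment(
                    sub, land_ss, nest_ss, log,
                    min_hedges=min_hedges, min_setaside_fields=min_fields,
                )
                seq = _manipulated_sequence(
                    grid, manip, points, np.random.default_rng(manip_ss)
                )
            params = _sens_kernel(axis, level, nuis)
            for walk_sub, (k, land) in zip(level_ss.spawn(len(points)), zip(points, seq)):
                stats = simulate_walk(
                    land, nest, params, config.timesteps,
                    np.random.default_rng(walk_sub),
                )
                rows.append({
                    "set_id": set_id, axis: level, "assay_point": k,
                    "max_distance": stats.max_distance,
                    "n_switches": stats.n_switches,
                    "prop_wild": stats.prop_wild,
                })
    raw = _finish(rows, log)
    if return_raw:
        return raw
    agg = raw.groupby([axis, "assay_point"], as_index=False).agg(
        **{
            f"{which}_{stat}": (stat, which)
            for stat in _STAT_COLS
            for which in ("mean", "std")
        }
    )
    agg.attrs["run_log"] = log
    return agg
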