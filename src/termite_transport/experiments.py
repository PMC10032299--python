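"""Experiment drivers: single runs, replicate sets, grid sweeps (E-maps and
jam maps) and PRCC experiments, with deterministic per-run seeding.

Every run in a sweep or design is seeded from the master seed plus a counter
path (cell index, replicate index) through ``numpy.random.SeedSequence``-style
entropy lists, so any single cell can be re-run in isolation from its logged
seed path without re-executing the sweep.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import dynamics, metrics, sensitivity, tunnel
from .tunnel import ConfigurationError

logger = logging.getLogger(__name__)

ALL_LEVELS = tuple(range(1, 12))


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation condition: the four control levels plus model constants."""

    k1: int = 1
    k2: int = 1
    k3: int = 1
    k4: int = 1
    n_agents: int = 100
    T: int = 5000
    replicates: int = 10
    seed: int = 0
    p_transfer: float = 0.2
    loss_per_transfer: float = 0.09
    jam_group: int = 4
    jam_duration: int = 100
    meeting_rule: str = "encounter"
    scale: float = 10_000.0
    length_cells: int = tunnel.DEFAULT_LENGTH_CELLS
    amplitude: float = tunnel.DEFAULT_AMPLITUDE
    curvature_zones: tuple = tunnel.DEFAULT_CURVATURE_ZONES
    efficiency_mode: str = "increment"
    saturation_window: tuple = metrics.SATURATION_WINDOW

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4"):
            if getattr(self, name) not in range(1, 12):
                raise ConfigurationError(f"{name} must be in 1..11")
        if self.T < 1:
            raise ConfigurationError("T must be >= 1")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.n_agents < 1:
            raise ConfigurationError("n_agents must be >= 1")

    def behavior_params(self) -> dynamics.BehaviorParams:
        return dynamics.BehaviorParams(
            k1=self.k1,
            k2=self.k2,
            p_transfer=self.p_transfer,
            loss_per_transfer=self.loss_per_transfer,
            jam_group=self.jam_group,
            jam_duration=self.jam_duration,
            meeting_rule=self.meeting_rule,
        )

    def tunnel_spec(self) -> tunnel.TunnelSpec:
        return tunnel.build_tunnel(
            length_cells=self.length_cells,
            amplitude=self.amplitude,
            curvature_zones=self.curvature_zones,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["curvature_zones"] = [list(z) for z in self.curvature_zones]
        d["saturation_window"] = list(self.saturation_window)
        return d


def child_rng(master_seed: int, *path: int) -> np.random.Generator:
    """Deterministic per-run generator from the master seed and a counter path."""
    return np.random.default_rng([int(master_seed), *map(int, path)])


def run_single(config: SimulationConfig, *path: int) -> metrics.RunResult:
    """Execute one run of T steps under ``config``.

    ``path`` is the counter path appended to the master seed (defaults to the
    single replicate index 0); the same (config, path) is bit-reproducible.
    """
    if not path:
        path = (0,)
    rng = child_rng(config.seed, *path)
    spec = config.tunnel_spec()
    layout = tunnel.place_irregularities(spec, config.k3, config.k4, rng)
    world = dynamics.init_world(
        config.behavior_params(), spec, layout, rng, n_agents=config.n_agents
    )
    t0 = time.perf_counter()
    dynamics.run(world, rng, config.T)
    eff = metrics.efficiency_series(
        world.ledger,
        config.T,
        s=config.scale,
        N0=config.n_agents,
        mode=config.efficiency_mode,
    )
    result = metrics.RunResult(
        config=config.to_dict(),
        seed_path=(config.seed, *path),
        ledger=world.ledger,
        jam_log=world.jam_log,
        efficiency=eff,
        counters={
            "pickups": world.n_pickups,
            "deposits": world.n_deposits,
            "transfers": world.n_transfers,
            "curvature_stops": world.n_curvature_stops,
            "pauses": world.n_pauses,
        },
    )
    logger.info(
        "run k=(%d,%d,%d,%d) seed_path=%s total_food=%.3f total_jams=%d "
        "wall=%.2fs",
        config.k1,
        config.k2,
        config.k3,
        config.k4,
        result.seed_path,
        result.total_food,
        result.total_jams,
        time.perf_counter() - t0,
    )
    return result


def run_replicates(config: SimulationConfig, *prefix: int) -> list[metrics.RunResult]:
    """Run ``config.replicates`` independent replicates with child seeds
    ``(seed, *prefix, r)``."""
    return [run_single(config, *prefix, r) for r in range(config.replicates)]


@dataclass(frozen=True)
class SweepResult:
    """Replicate-averaged grid of saturation-window E and total jam frequency."""

    axes: tuple                      # ((name, levels), ...)
    table: pd.DataFrame              # one row per grid cell

    def grid(self, value: str = "E_sat") -> pd.DataFrame:
        """Pivot a 2-axis sweep into a (first axis x second axis) matrix."""
        if len(self.axes) != 2:
            raise ValueError("grid() requires a 2-axis sweep")
        (ax0, _), (ax1, _) = self.axes
        return self.table.pivot(index=ax0, columns=ax1, values=value)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_sweep(config: SimulationConfig, axes: list[tuple[str, list[int]]]) -> SweepResult:
    """Run every grid cell x replicates and average per cell.

    ``axes`` is a list of (variable, levels) with distinct variables among
    k1..k4.  The per-cell scalar E is the mean of E(tau) over the saturation
    window; total jam frequency is averaged over replicates likewise.
    """
    names = [name for name, _ in axes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate axis variable")
    for name in names:
        if name not in ("k1", "k2", "k3", "k4"):
            raise ValueError(f"unknown sweep variable {name!r}")
    level_lists = [levels for _, levels in axes]
    rows = []
    cell_index = 0
    for combo in _product(level_lists):
        cell_cfg = replace(config, **dict(zip(names, combo)))
        results = run_replicates(cell_cfg, cell_index)
        summary = metrics.average_over_replicates(results)
        E_sat = float(
            np.mean(
                [
                    r.efficiency.saturation_mean(config.saturation_window)
                    for r in results
                ]
            )
        )
        row = dict(zip(names, combo))
        row.update(
            E_sat=E_sat,
            E_final=float(summary.mean_E[-1]),
            total_jams=summary.mean_total_jams,
            total_food=summary.mean_total_food,
            n_replicates=len(results),
            cell_index=cell_index,
        )
        rows.append(row)
        cell_index += 1
    return SweepResult(
        axes=tuple((n, tuple(ls)) for n, ls in axes), table=pd.DataFrame(rows)
    )


def _product(level_lists):
    import itertools

    return itertools.product(*level_lists)


def plan_full_factorial(
    levels: tuple[int, ...] = ALL_LEVELS, replicates: int = 10
) -> sensitivity.SampleDesign:
    """The full-factorial experiment plan over k1..k4 (146,410 runs at the
    default 11 levels x 10 replicates)."""
    return sensitivity.full_factorial(levels=levels, k=4, replicates=replicates)


def run_prcc_experiment(
    config: SimulationConfig,
    scheme: str = "factorial",
    levels: tuple[int, ...] = ALL_LEVELS,
    n: int | None = None,
    per_replicate: bool = False,
) -> tuple[sensitivity.SensitivityResult, pd.DataFrame]:
    """Run a design over (k1..k4) and compute the PRCC of E against each level.

    ``scheme`` is "factorial" (all combinations of ``levels``) or "lhs" (``n``
    stratified samples).  The response per design row is the saturation-window
    E, replicate-averaged by default (``per_replicate=False``); with
    ``per_replicate=True`` every replicate contributes its own row.

    Returns the sensitivity result and the run table
    (k1,k2,k3,k4,replicate,E,total_jams).
    """
    if scheme == "factorial":
        design = sensitivity.full_factorial(levels=levels, k=4, replicates=config.replicates)
    elif scheme == "lhs":
        if n is None:
            raise ValueError("lhs scheme requires n")
        design = sensitivity.lhs_sample(
            n, 4, child_rng(config.seed, 0xD0E), replicates=config.replicates
        )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    records = []
    for i, row in enumerate(design.rows):
        cfg = replace(config, k1=int(row[0]), k2=int(row[1]), k3=int(row[2]), k4=int(row[3]))
        for r, res in enumerate(run_replicates(cfg, i)):
            records.append(
                {
                    "k1": cfg.k1,
                    "k2": cfg.k2,
                    "k3": cfg.k3,
                    "k4": cfg.k4,
                    "replicate": r,
                    "E": res.efficiency.saturation_mean(config.saturation_window),
                    "total_jams": res.total_jams,
                }
            )
    table = pd.DataFrame(records)
    if per_replicate:
        X = table[["k1", "k2", "k3", "k4"]].to_numpy()
        y = table["E"].to_numpy()
    else:
        agg = table.groupby(["k1", "k2", "k3", "k4"], as_index=False)["E"].mean()
        X = agg[["k1", "k2", "k3", "k4"]].to_numpy()
        y = agg["E"].to_numpy()
    result = sensitivity.prcc(X, y, names=("k1", "k2", "k3", "k4"))
    return result, table


def write_run_outputs(result: metrics.RunResult, outdir) -> None:
    """Write efficiency.csv, jams.csv and a JSON sidecar for one run."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "efficiency.csv").write_text(result.efficiency_csv())
    (out / "jams.csv").write_text(result.jam_csv())
    sidecar = {
        "config": result.config,
        "seed_path": list(result.seed_path),
        "total_food": result.total_food,
        "total_jams": result.total_jams,
        "E_saturation_mean": result.efficiency.saturation_mean(),
        "counters": result.counters,
    }
    (out / "run.json").write_text(json.dumps(sidecar, indent=2))
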