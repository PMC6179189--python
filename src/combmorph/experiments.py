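"""Run orchestration: single simulations, replicate sets, parameter sweeps.

A *run* is one full simulation: the target-update / extrusion schedule is
applied every ``dt`` mcs and ``flips_per_mcs`` Metropolis attempts are made
each mcs, for ``duration`` (default 2000) mcs; morphometrics are computed on
the final state.  A *set* is a group of replicate runs sharing parameters
but differing in RNG seed.  A *sweep* is the Cartesian product of comb
length x J(SCT, SCT) x EP1 expansion delay, each cell of which is a set.
Seeds are derived deterministically from the condition and replicate index,
so the same plan always produces the same results and delayed/non-delayed
conditions can be compared pair-by-pair at matched seeds.
"""

from __future__ import annotations


import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import comb_metrics, cpm_core
from .comb_configs import CombLayoutSpec, ParamBundle, default_params, generate_initial_lattice
from .comb_metrics import MetricsRecord, SetSummary
from .cpm_core import LatticeState, run_mcs, seed_rng
from .morphodynamics import apply_extrusion, update_targets

DEFAULT_J_GRID = (-4000.0, -2000.0, 0.0, 1000.0, 2000.0, 4000.0, 6000.0, 8000.0, 10000.0)


@dataclass(frozen=True)
class RunConfig:
    layout: CombLayoutSpec
    bundle: ParamBundle
    ep1_delay: int = 0
    seed: int = 0
    snapshot_every: int = 100

    def __post_init__(self):
        if self.bundle.sim.duration < self.snapshot_every:
            raise ValueError("duration must be at least snapshot_every")


@dataclass(frozen=True)
class SweepPlan:
    n_teeth: Sequence[int] = (5, 7, 9, 11)
    j_grid: Sequence[float] = DEFAULT_J_GRID
    delays: Sequence[int] = (0,)
    replicates: int = 48
    base_seed: int = 0
    duration: int = 2000

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class RunResult:
    config: RunConfig
    final: LatticeState
    metrics: MetricsRecord
    snapshots: list[tuple[int, np.ndarray]]  # (time, grid copy)


def make_run_config(
    n_teeth: int,
    j_sct_sct: float,
    seed: int = 0,
    ep1_delay: int = 0,
    layout: CombLayoutSpec | None = None,
    bundle: ParamBundle | None = None,
    duration: int = 2000,
    snapshot_every: int | None = None,
    **layout_kw,
) -> RunConfig:
    """Convenience constructor with the calibrated default layout."""
    if layout is None:
        layout = CombLayoutSpec(n_teeth=n_teeth, **layout_kw)
    if bundle is None:
        bundle = default_params(n_teeth, j_sct_sct, seed=seed, duration=duration)
    if snapshot_every is None:
        snapshot_every = min(100, bundle.sim.duration)
    return RunConfig(
        layout=layout,
        bundle=bundle,
        ep1_delay=ep1_delay,
        seed=seed,
        snapshot_every=snapshot_every,
    )


def run_simulation(config: RunConfig, keep_snapshots: bool = False) -> RunResult:
    """Execute one simulation to completion and measure the final comb."""
    schedule = config.bundle.schedule
    if config.ep1_delay:
        schedule = schedule.with_delay("EP1", config.ep1_delay)
    lattice = generate_initial_lattice(config.layout, config.bundle)
    seed_rng(config.seed)
    snapshots: list[tuple[int, np.ndarray]] = []
    if keep_snapshots:
        snapshots.append((0, lattice.grid.copy()))
    duration = config.bundle.sim.duration
    dt = schedule.dt
    for t in range(1, duration + 1):
        if t % dt == 0 and t < duration:
            # schedule tick: targets first, then the extrusion check
            update_targets(lattice, schedule, t)
            apply_extrusion(lattice, schedule)
        run_mcs(lattice)
        if keep_snapshots and t % config.snapshot_every == 0:
            snapshots.append((t, lattice.grid.copy()))
    metrics = comb_metrics.measure(lattice)
    return RunResult(config=config, final=lattice, metrics=metrics, snapshots=snapshots)


def run_set(
    config: RunConfig,
    replicates: int = 48,
    base_seed: int | None = None,
) -> tuple[SetSummary, list[MetricsRecord]]:
    """Replicate ``config`` with seeds base_seed + k and aggregate.

    Individual run failures are recorded as None entries and excluded from
    the summary counts (n_runs still reports attempted replicates).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if base_seed is None:
        base_seed = config.seed
    records: list[MetricsRecord | None] = []
    for k in range(replicates):
        cfg = replace(config, seed=(base_seed + k) & 0x7FFFFFFF)
        try:
            records.append(run_simulation(cfg).metrics)
        except Exception as exc:  # pragma: no cover - defensive
            import warnings

            warnings.warn(f"replicate {k} (seed {cfg.seed}) failed: {exc}")
            records.append(None)
    ok = [r for r in records if r is not None]
    summary = SetSummary(
        n_runs=replicates,
        n_intact=sum(r.intact for r in ok),
        abasct_sd_distribution=[r.abasct_sd for r in ok if r.intact],
        alpha_distribution=[r.alpha for r in ok],
    )
    return summary, records


def intact_ratio_profile(
    n_teeth: int,
    j_values: Sequence[float],
    replicates: int = 12,
    base_seed: int = 0,
    ep1_delay: int = 0,
) -> dict[float, SetSummary]:
    """Replicate sets across a J(SCT, SCT) grid; the workhorse behind the
    breaking-statistics comparisons."""
    out = {}
    for j in j_values:
        cfg = make_run_config(n_teeth, j, ep1_delay=ep1_delay)
        base = condition_seed(base_seed, n_teeth, j, ep1_delay)
        summary, _ = run_set(cfg, replicates, base_seed=base)
        out[float(j)] = summary
    return out


def condition_seed(base_seed: int, n_teeth: int, j_sct: float, delay: int) -> int:
    """Deterministic per-condition seed; replicate k uses this + k.

    The delay is excluded from the hash so delayed and non-delayed sets of
    the same condition run with matched seeds (paired comparison)."""
    key = f"{n_teeth}|{j_sct:g}".encode()
    return (int(base_seed) * 1_000_003 + zlib.crc32(key)) & 0x3FFFFFFF


def sweep(plan: SweepPlan, layout_kw: dict | None = None) -> pd.DataFrame:
    """Run the full condition grid; one row per replicate (tidy CSV form)."""
    layout_kw = layout_kw or {}
    rows = []
    for n in plan.n_teeth:
        for j in plan.j_grid:
            for delay in plan.delays:
                cfg = make_run_config(
                    n, j, ep1_delay=delay, duration=plan.duration, **layout_kw
                )
                base = condition_seed(plan.base_seed, n, j, delay)
                _, records = run_set(cfg, plan.replicates, base_seed=base)
                for k, rec in enumerate(records):
                    if rec is None:
                        continue
                    rows.append(
                        {
                            "run_id": f"n{n}_j{j:g}_d{delay}_r{k}",
                            "seed": base + k,
                            "n_teeth": n,
                            "j_sct": j,
                            "delay": delay,
                            "alpha": rec.alpha,
                            "abasct_sd": rec.abasct_sd,
                            "intact": rec.intact,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Per-condition intact ratio and ABASCT SD stats (intact runs only)."""
    out = []
    for (n, j, d), g in df.groupby(["n_teeth", "j_sct", "delay"]):
        intact = g["intact"].astype(bool)
        out.append(
            {
                "n_teeth": n,
                "j_sct": j,
                "delay": d,
                "n_runs": len(g),
                "n_intact": int(intact.sum()),
                "intact_ratio": float(intact.mean()),
                "abasct_sd_median": float(g.loc[intact, "abasct_sd"].median()) if intact.any() else float("nan"),
                "alpha_mean": float(g["alpha"].mean()),
            }
        )
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# VTK snapshot output
# --------------------------------------------------------------------------

VTK_TYPE_CODES = {"EP1": 1, "EP2": 2, "EP3": 3, "SCT": 4, "BA": 5}


def write_vtk_snapshot(lattice: LatticeState, path) -> str:
    """Legacy-VTK STRUCTURED_POINTS ASCII snapshot with two scalar point
    fields: the cell index sigma and the type code (EP1:1 .. BA:5).  Points
    are written x-fastest, matching the VTK structured-points convention."""
    nx, ny = lattice.grid.shape
    sigma = lattice.grid.T.ravel()  # x varies fastest
    ctype = lattice.ctype[sigma]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"combmorph snapshot t={lattice.time} mcs\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write("SPACING 1 1 1\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        fh.write("SCALARS sigma int 1\n")
        fh.write("LOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(v)) for v in sigma))
        fh.write("\nSCALARS ctype int 1\n")
        fh.write("LOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(v)) for v in ctype))
        fh.write("\n")
    return str(path)


def read_vtk_snapshot(path) -> tuple[np.ndarray, np.ndarray]:
    """Read back a snapshot written by :func:`write_vtk_snapshot`; returns
    (sigma grid, type-code grid)."""
    with open(path) as fh:
        lines = [l.strip() for l in fh]
    dims = next(l for l in lines if l.startswith("DIMENSIONS")).split()
    nx, ny = int(dims[1]), int(dims[2])
    fields = {}
    i = 0
    while i < len(lines):
        if lines[i].startswith("SCALARS"):
            name = lines[i].split()[1]
            vals = []
            i += 2  # skip LOOKUP_TABLE
            while i < len(lines) and len(vals) < nx * ny:
                if lines[i]:
                    vals.extend(int(v) for v in lines[i].split())
                i += 1
            fields[name] = np.array(vals).reshape(ny, nx).T
        else:
            i += 1
    return fields["sigma"], fields["ctype"]
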