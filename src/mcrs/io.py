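"""CSV writers/readers for time series and lattice snapshots, and the
replicate-averaged parameter sweep runner.

Every output file embeds a short hash of the full parameter set (and the
seed that produced it) in a ``#`` header line, so that files from different
configurations can never be confused and finished sweep runs can be detected
and skipped on resume.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import RunResult, run_simulation
from .lattice import Lattice, format_fixture, parse_fixture
from .metrics import (CensusRecord, record_columns, record_from_row,
                      record_to_row)
from .params import Params, replicate_seeds, serialize_params

__all__ = [
    "params_hash",
    "write_timeseries",
    "read_timeseries",
    "write_snapshot",
    "read_snapshot",
    "SweepCell",
    "run_sweep",
]

log = logging.getLogger("mcrs")


def params_hash(params: Params) -> str:
    """Stable 12-hex-digit digest of the full parameter set."""
    return hashlib.sha256(serialize_params(params).encode()).hexdigest()[:12]


def write_timeseries(records, path, params: Params | None = None,
                     A: int | None = None, seed: int | None = None) -> None:
    """Write census records as CSV, one row per census.

    The header comment carries the params hash and the run seed when
    ``params`` is given; the column line matches
    :func:`mcrs.metrics.record_columns`.
    """
    if A is None:
        if params is not None:
            A = params.A
        elif records:
            A = records[0].A
        else:
            raise ValueError("need params or A to write an empty time series")
    path = Path(path)
    with open(path, "w") as fh:
        if params is not None:
            fh.write(f"# mcrs timeseries params_hash={params_hash(params)} "
                     f"seed={params.seed if seed is None else seed}\n")
        fh.write(",".join(record_columns(A)) + "\n")
        for rec in records:
            fh.write(",".join(_fmt(v) for v in record_to_row(rec)) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def read_timeseries(path) -> list[CensusRecord]:
    """Read a time-series CSV back into census records (lossless)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    ncol = len(df.columns)
    # columns: 2 + (A+1) + 3 + A + 2**A  ->  solve for A
    A = 1
    while 2 + (A + 1) + 3 + A + 2**A < ncol:
        A += 1
    if 2 + (A + 1) + 3 + A + 2**A != ncol:
        raise ValueError(f"cannot infer A from {ncol} columns")
    return [record_from_row(row, A) for row in df.itertuples(index=False)]


def write_snapshot(lattice: Lattice, path, params: Params | None = None) -> None:
    """Write one CSV row per occupied site: x, y, expressed, E_1..E_A, k.

    The header records the side length, the 0-based (row, col) convention,
    and the params hash; :func:`read_snapshot` reproduces the lattice
    exactly.
    """
    extra = f"params_hash={params_hash(params)}" if params is not None else ""
    Path(path).write_text(format_fixture(lattice, extra_header=extra))


def read_snapshot(path) -> Lattice:
    """Rebuild a lattice from a snapshot file."""
    return parse_fixture(Path(path).read_text())


@dataclass
class SweepCell:
    """Aggregated result of one parameter setting in a sweep.

    Final-census statistics are averaged over the replicates that survived;
    extinct replicates count only toward ``survival_fraction`` (their G and
    trait means are undefined).
    """

    overrides: dict
    n_replicates: int
    n_completed: int
    survival_fraction: float
    mean_G: float  # NaN if no replicate survived
    mean_parasite_fraction: float
    mean_occupancy: float


def _cell_params(base: Params, overrides: dict) -> Params:
    return base.replace(**overrides)


def run_sweep(base: Params, grid, n_replicates: int, outdir,
              write_runs: bool = True) -> pd.DataFrame:
    """Run every parameter setting in ``grid`` with replicate averaging.

    ``grid`` is an iterable of override dicts (subsets of :class:`Params`
    fields).  Each cell runs ``n_replicates`` simulations on seeds derived
    deterministically from the cell's own parameter set; per-run time series
    are written under ``outdir`` and finished runs (matching file, matching
    params hash) are skipped on resume.  Returns the summary table, which is
    also written to ``outdir/summary.csv``.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = []
    for idx, overrides in enumerate(grid):
        params = _cell_params(base, dict(overrides))
        h = params_hash(params)
        seeds = replicate_seeds(params, n_replicates)
        finals: list[CensusRecord] = []
        n_completed = 0
        for j, seed in enumerate(seeds):
            run_path = outdir / f"cell{idx:03d}_rep{j}_{h}.csv"
            final = None
            if run_path.exists():
                final = _resume_final(run_path, h)
            if final is None:
                try:
                    result = run_simulation(params, seed=seed)
                except Exception:
                    log.exception("run failed: cell %d replicate %d", idx, j)
                    continue
                if write_runs:
                    write_timeseries(result.records, run_path, params=params,
                                     seed=seed)
                final = result.records[-1]
            n_completed += 1
            finals.append(final)
        survived = [r for r in finals if r.occupancy > 0]
        cells.append(SweepCell(
            overrides=dict(overrides),
            n_replicates=n_replicates,
            n_completed=n_completed,
            survival_fraction=(len(survived) / n_completed) if n_completed else math.nan,
            mean_G=float(np.mean([r.G for r in survived])) if survived else math.nan,
            mean_parasite_fraction=(float(np.mean([r.parasite_fraction
                                                   for r in survived]))
                                    if survived else math.nan),
            mean_occupancy=(float(np.mean([r.occupancy for r in survived]))
                            if survived else 0.0),
        ))
    rows = []
    for idx, cell in enumerate(cells):
        row = {"cell": idx, "overrides": json.dumps(cell.overrides, sort_keys=True),
               "n_replicates": cell.n_replicates, "n_completed": cell.n_completed,
               "survival_fraction": cell.survival_fraction, "mean_G": cell.mean_G,
               "mean_parasite_fraction": cell.mean_parasite_fraction,
               "mean_occupancy": cell.mean_occupancy}
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "summary.csv", index=False)
    return summary


def _resume_final(run_path: Path, expected_hash: str) -> CensusRecord | None:
    """Final census of a previously written run, if its hash matches."""
    try:
        with open(run_path) as fh:
            header = fh.readline()
        if f"params_hash={expected_hash}" not in header:
            return None
        records = read_timeseries(run_path)
        return records[-1] if records else None
    except (OSError, ValueError):
        return None
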