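"""Reading and writing runs: time-series CSV, XYZ snapshots, bond JSON.

A persisted run directory contains::

    config.json      full configuration + seed + config hash
    timeseries.csv   time_ns and the four bond-type counts
    final.xyz        group coordinates of the final state (XYZ format)
    bonds.json       live bonds of the final state
    molecules.csv    final molecule poses (for exact re-ingestion)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import (
    TS_COLUMNS,
    RunResult,
    SystemState,
    bond_list,
    group_coordinates,
    make_state,
)
from .model import SimulationConfig, Species, config_hash

__all__ = ["write_run", "read_run", "write_xyz", "read_bonds", "LoadedRun"]


def write_xyz(path, state: SystemState, comment: str = "") -> None:
    """Write the group coordinates of a state as one XYZ frame."""
    labels, coords = group_coordinates(state)
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n{comment}\n")
        for label, (gx, gy, gz) in zip(labels, coords):
            fh.write(f"{label} {float(gx)!r} {float(gy)!r} {float(gz)!r}\n")


def _bond_records(state: SystemState) -> list[dict]:
    return [
        {
            "mol_a": i, "site_a": si, "mol_b": j, "site_b": sj,
            "type": rule, "formation_time_ns": t,
        }
        for (i, si, j, sj, rule, t) in bond_list(state)
    ]


def write_run(result: RunResult, path) -> Path:
    """Persist a completed run; returns the directory path."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(result.config)
    cfg["disabled_rules"] = list(result.config.disabled_rules)
    with open(out / "config.json", "w") as fh:
        json.dump(
            {"config": cfg, "seed": result.seed, "config_hash": result.config_hash},
            fh, indent=2,
        )
    result.time_series.to_csv(out / "timeseries.csv", index=False)
    state = result.final_state
    write_xyz(out / "final.xyz", state, comment=f"t={state.t}ns")
    with open(out / "bonds.json", "w") as fh:
        json.dump(_bond_records(state), fh)
    mols = pd.DataFrame(
        {
            "species": [Species(s).name for s in state.sp],
            "x": [repr(float(v)) for v in state.x],
            "y": [repr(float(v)) for v in state.y],
            "theta_deg": [repr(float(v)) for v in np.degrees(state.th)],
        }
    )
    mols.to_csv(out / "molecules.csv", index=False)
    return out


@dataclasses.dataclass
class LoadedRun:
    """A run read back from disk."""

    config: SimulationConfig
    seed: int
    config_hash: str
    time_series: pd.DataFrame
    final_state: SystemState


def read_bonds(path) -> list[tuple]:
    """Bond list from a ``bonds.json`` file as ((mol, site), (mol, site))."""
    with open(path) as fh:
        records = json.load(fh)
    for k, r in enumerate(records):
        missing = {"mol_a", "site_a", "mol_b", "site_b"} - set(r)
        if missing:
            raise ValueError(f"bonds.json record {k}: missing fields {missing}")
    return [
        ((r["mol_a"], r["site_a"]), (r["mol_b"], r["site_b"])) for r in records
    ]


def read_run(path) -> LoadedRun:
    """Re-ingest a persisted run; the bond graph and time series are
    reconstructed exactly (counts bit-identical to the written run)."""
    src = Path(path)
    try:
        with open(src / "config.json") as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{src / 'config.json'}: malformed JSON ({exc})") from exc
    raw = meta["config"]
    raw["copy_numbers"] = {k: int(v) for k, v in raw["copy_numbers"].items()}
    raw["disabled_rules"] = tuple(raw.get("disabled_rules", ()))
    cfg = SimulationConfig(**raw)
    if config_hash(cfg) != meta["config_hash"]:
        raise ValueError(f"{src}: config hash mismatch (corrupt or edited config)")
    ts = pd.read_csv(src / "timeseries.csv")
    missing = set(TS_COLUMNS) - set(ts.columns)
    if missing:
        raise ValueError(f"{src / 'timeseries.csv'}: missing columns {missing}")
    mols = pd.read_csv(src / "molecules.csv")
    placements = [
        (row.species, float(row.x), float(row.y), float(row.theta_deg))
        for row in mols.itertuples()
    ]
    bonds = read_bonds(src / "bonds.json")
    state = make_state(cfg, placements, bonds)
    state.t = float(ts["time_ns"].iloc[-1])
    return LoadedRun(
        config=state.config,
        seed=int(meta["seed"]),
        config_hash=meta["config_hash"],
        time_series=ts,
        final_state=state,
    )
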