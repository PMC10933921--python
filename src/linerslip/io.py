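"""CSV / YAML readers and writers.

All tabular interchange is comma-separated UTF-8 with a mandatory header
row and '.' decimal separator.  Binary slip flags are encoded 0/1 with an
empty cell meaning "method not assessed".
"""

from __future__ import annotations

import pathlib
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .simulate import FLAG_COLUMNS, SimulationConfig, SlipEvent, VacuumTrace

__all__ = [
    "load_observations",
    "write_observations",
    "load_events",
    "write_events",
    "load_trace",
    "write_trace",
    "load_sim_config",
    "write_sim_config",
]

PathLike = Union[str, pathlib.Path]

OBSERVATION_COLUMNS = [
    "observation_id", "cow_id", "lactation_number", "dim", "milk_yield_kg",
    "two_min_yield_kg", "unit_on_s", "avg_flow_kg_min", *FLAG_COLUMNS,
]

EVENT_COLUMNS = [
    "observation_id", "start_s", "duration_s", "magnitude_kpa",
    "max_drop_rate_kpa_s", "phase_label",
]


def write_observations(observations: pd.DataFrame, path: PathLike) -> None:
    df = observations.copy()
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observations missing columns: {missing}")
    df[OBSERVATION_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def load_observations(path: PathLike) -> pd.DataFrame:
    """Load an observation table; slip-flag columns become nullable Int64.

    A flag column absent from the file loads as all-missing (method not
    assessed).  Any flag value other than 0, 1 or empty raises with the
    offending row number (1-based, excluding the header).
    """
    df = pd.read_csv(path, encoding="utf-8")
    for col in FLAG_COLUMNS:
        if col not in df.columns:
            df[col] = pd.array([pd.NA] * len(df), dtype="Int64")
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & ~vals.isin([0, 1])
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
            raise ValueError(
                f"{path}: column {col!r} row {row}: value {df[col][bad].iloc[0]!r} "
                "is not a binary 0/1 flag"
            )
        df[col] = vals.astype("Int64")
    return df


def write_events(events: pd.DataFrame, path: PathLike) -> None:
    df = events.copy()
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events missing columns: {missing}")
    df[EVENT_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def load_events(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: events file missing columns: {missing}")
    return df


def events_to_objects(events: pd.DataFrame) -> dict[str, list[SlipEvent]]:
    """Group an events table into per-observation SlipEvent lists."""
    out: dict[str, list[SlipEvent]] = {}
    for row in events.itertuples(index=False):
        out.setdefault(row.observation_id, []).append(
            SlipEvent(
                start_s=float(row.start_s),
                duration_s=float(row.duration_s),
                magnitude_kpa=float(row.magnitude_kpa),
                max_drop_rate_kpa_s=float(row.max_drop_rate_kpa_s),
                phase_label=str(row.phase_label),
            )
        )
    return out


def write_trace(trace: VacuumTrace, path: PathLike) -> None:
    trace.to_frame().to_csv(path, index=False, encoding="utf-8")


def load_trace(path: PathLike, observation_id: str | None = None) -> VacuumTrace:
    df = pd.read_csv(path, encoding="utf-8")
    for col in ("time_s", "smt_vacuum_kpa", "airbleed_index"):
        if col not in df.columns:
            raise ValueError(f"{path}: trace file missing column {col!r}")
    oid = observation_id or pathlib.Path(path).stem
    return VacuumTrace(
        time_s=df["time_s"].to_numpy(float),
        smt_vacuum_kpa=df["smt_vacuum_kpa"].to_numpy(float),
        airbleed_index=df["airbleed_index"].to_numpy(float),
        observation_id=oid,
    )


def write_sim_config(config: SimulationConfig, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_sim_config(path: PathLike) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: simulation config must be a YAML mapping")
    return SimulationConfig.from_dict(data)
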