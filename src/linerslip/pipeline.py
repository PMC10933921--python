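"""End-to-end pipeline: simulate a herd, run every detector, compute the
agreement layer, and write a reproducible report directory."""

from __future__ import annotations

import hashlib
import json
import pathlib
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .agreement import RaterAgreement
from .detect import (
    DEFAULT_OBSERVER_WINDOWS,
    FluctuationRule,
    MeterRule,
    ObserverWindow,
    TYPE1_RULE,
    TYPE2_RULE,
    classify_slp_v,
    detect_irregular_fluctuations,
    detect_meter_slip,
    detect_observer,
)
from .io import write_events, write_observations
from .simulate import (
    FLAG_COLUMNS,
    SimulationConfig,
    _draw_observation,
    _events_frame,
    _make_observation,
    _synthesize_trace,
)

__all__ = ["PipelineConfig", "run_pipeline", "SchemaError"]

PathLike = Union[str, pathlib.Path]

# method pairs reported by the pipeline: (test flag, gold flag)
REPORT_PAIRS = [
    ("slp_mm", "slp_ob1"),
    ("slp_mm", "slp_ob2"),
    ("slp_mm", "slp_ob3"),
    ("slp_mm", "slp_any"),
    ("slp_mm", "slp_v1"),
    ("slp_mm", "slp_v2"),
]


class SchemaError(ValueError):
    """Malformed pipeline configuration."""


class PipelineConfig:
    """Validated pipeline configuration.

    YAML schema (all sections optional except ``n``)::

        n: 200
        seed: 7                # overrides simulation.seed
        simulation: {...}      # SimulationConfig fields
        detection:
          meter: {slip_limit: 175, min_duration_s: 30}
          type1: {drop_rate_kpa_s: 100, magnitude_kpa: 21}
          type2: {drop_rate_kpa_s: 56, magnitude_kpa: 14}
        observers:
          miss_prob: 0.0
          windows: {1: [0.0, 0.25], 2: [0.25, 0.85], 3: [0.85, 1.0]}
        write_traces: false
    """

    TOP_KEYS = {"n", "seed", "simulation", "detection", "observers", "write_traces"}

    def __init__(self, raw: dict):
        if not isinstance(raw, dict):
            raise SchemaError("pipeline config must be a mapping")
        unknown = sorted(set(raw) - self.TOP_KEYS)
        if unknown:
            raise SchemaError(f"unknown pipeline config keys: {unknown}")
        if "n" not in raw:
            raise SchemaError("pipeline config requires 'n'")
        self.n = int(raw["n"])
        if self.n < 1:
            raise SchemaError(f"n={self.n} must be >= 1")
        sim = dict(raw.get("simulation") or {})
        if "seed" in raw:
            sim["seed"] = int(raw["seed"])
        try:
            self.simulation = SimulationConfig.from_dict(sim)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"bad simulation section: {exc}") from exc
        det = raw.get("detection") or {}
        unknown = sorted(set(det) - {"meter", "type1", "type2"})
        if unknown:
            raise SchemaError(f"unknown detection keys: {unknown}")
        try:
            self.meter_rule = MeterRule(**(det.get("meter") or {}))
            t1 = det.get("type1")
            self.type1_rule = (
                FluctuationRule(name="type1", **t1) if t1 else TYPE1_RULE
            )
            t2 = det.get("type2")
            self.type2_rule = (
                FluctuationRule(name="type2", **t2) if t2 else TYPE2_RULE
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"bad detection section: {exc}") from exc
        obs = raw.get("observers") or {}
        unknown = sorted(set(obs) - {"miss_prob", "windows"})
        if unknown:
            raise SchemaError(f"unknown observers keys: {unknown}")
        self.miss_prob = float(obs.get("miss_prob",
                                       self.simulation.observer_miss_prob))
        windows = obs.get("windows")
        if windows:
            try:
                self.windows = tuple(
                    ObserverWindow(int(k), float(v[0]), float(v[1]))
                    for k, v in sorted(windows.items())
                )
            except (TypeError, ValueError, IndexError) as exc:
                raise SchemaError(f"bad observer windows: {exc}") from exc
        else:
            self.windows = DEFAULT_OBSERVER_WINDOWS
        self.write_traces = bool(raw.get("write_traces", False))
        self.raw = raw

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh) or {})


def run_pipeline(config: Union[PipelineConfig, dict, PathLike],
                 out_dir: PathLike,
                 seed: Optional[int] = None) -> dict:
    """Simulate, detect, and analyse one full study; write the report.

    Writes ``observations.csv``, ``truth_events.csv``, ``tables.csv``,
    ``stats.json`` and ``run.log`` into ``out_dir``.  Fully deterministic:
    the same configuration and seed produce byte-identical files.
    Returns the statistics dictionary.
    """
    if isinstance(config, (str, pathlib.Path)):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig(config)
    else:
        cfg = config
    sim = cfg.simulation if seed is None else cfg.simulation.replace(seed=seed)

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces_dir = out / "traces"
    if cfg.write_traces:
        traces_dir.mkdir(exist_ok=True)

    rows = []
    all_events = []
    import dataclasses

    for i in range(cfg.n):
        draw = _draw_observation(sim, i)
        trace, flow, _phases = _synthesize_trace(sim, draw)
        obs = _make_observation(sim, draw, flow, trace.time_s)
        obs.slp_mm = detect_meter_slip(trace, cfg.meter_rule)
        obs.slp_v1 = classify_slp_v(
            detect_irregular_fluctuations(trace, cfg.type1_rule)
        )
        obs.slp_v2 = classify_slp_v(
            detect_irregular_fluctuations(trace, cfg.type2_rule)
        )
        flags = {}
        for w in cfg.windows:
            flags[w.observer_id] = detect_observer(
                draw.events, w, draw.unit_on_s, cfg.miss_prob, sim.seed,
                observation_index=i,
            )
        obs.slp_ob1 = flags.get(1)
        obs.slp_ob2 = flags.get(2)
        obs.slp_ob3 = flags.get(3)
        present = [f for f in (obs.slp_ob1, obs.slp_ob2, obs.slp_ob3) if f is not None]
        obs.slp_any = int(any(present)) if present else None
        rows.append(dataclasses.asdict(obs))
        all_events.extend((obs.observation_id, ev) for ev in draw.events)
        if cfg.write_traces:
            trace.to_frame().to_csv(traces_dir / f"{obs.observation_id}.csv",
                                    index=False)

    observations = pd.DataFrame(rows)
    for col in FLAG_COLUMNS:
        observations[col] = observations[col].astype("Int64")
    events = _events_frame(all_events)

    stats: dict = {"n": cfg.n, "seed": sim.seed, "version": __version__,
                   "comparisons": {}}
    table_rows = []
    for test, gold in REPORT_PAIRS:
        res = RaterAgreement.from_dataframe(observations, test, gold).fit()
        key = f"{test}_vs_{gold}"
        stats["comparisons"][key] = res.to_dict()
        t = res.table
        table_rows.append({"comparison": key, "a": t.a, "b": t.b, "c": t.c,
                           "d": t.d, "n": t.n, "kappa": res.kappa})
    tables = pd.DataFrame(table_rows)

    write_observations(observations, out / "observations.csv")
    write_events(events, out / "truth_events.csv")
    tables.to_csv(out / "tables.csv", index=False)
    with open(out / "stats.json", "w", encoding="utf-8") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")

    cfg_bytes = yaml.safe_dump(cfg.raw, sort_keys=True).encode()
    log_lines = [
        f"linerslip version: {__version__}",
        f"seed: {sim.seed}",
        f"n: {cfg.n}",
        f"config sha256: {hashlib.sha256(cfg_bytes).hexdigest()}",
        "outputs: observations.csv truth_events.csv tables.csv stats.json",
    ]
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return stats
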