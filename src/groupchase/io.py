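"""Plain-text persistence and configuration handling.

Everything is CSV or JSON: a run is fully reproducible from its summary
JSON alone (config echo + seed), and all outputs are inspectable with
standard tools.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .core import Model, SimulationConfig
from .engine import RunResult
from .observables import FitnessTable, NashAnalysis

__all__ = [
    "load_config",
    "config_to_dict",
    "write_capture_log",
    "read_capture_log",
    "write_strategy_series",
    "read_strategy_series",
    "write_fitness_table",
    "write_nash_report",
    "write_run_summary",
    "read_run_summary",
    "write_run",
    "get_logger",
]

logger = logging.getLogger("groupchase")


def get_logger(quiet: bool = False) -> logging.Logger:
    """Package logger with a stable, parseable line format."""
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter(
            "%(levelname)s %(name)s t=%(asctime)s %(message)s",
            datefmt="%H:%M:%S"))
        logger.addHandler(h)
    logger.setLevel(logging.ERROR if quiet else logging.INFO)
    return logger


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["model"] = cfg.model.value
    return d


def load_config(source: Union[str, Path, dict],
                **overrides) -> SimulationConfig:
    """Build a configuration from a YAML/JSON file or a mapping, with
    keyword overrides taking precedence (mirrors the published parameter
    symbols: R, N_C, N_T, v_T, v_D, v_G, delta_t, r_min, r_haz, r_learn,
    T_hunt, T_rest, T_max, model, seed)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
    else:
        data = dict(source)
    data.update(overrides)
    if "model" in data:
        data["model"] = Model(data["model"])
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**data)


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def write_capture_log(captures: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    captures.to_csv(path, index=False)
    return path


def read_capture_log(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def write_strategy_series(result: RunResult, path: Union[str, Path]) -> Path:
    path = Path(path)
    n_gcs = result.series_n_gcs
    pd.DataFrame({
        "t": result.series_t,
        "n_gcs": n_gcs,
        "n_dcs": result.config.N_C - n_gcs,
    }).to_csv(path, index=False)
    return path


def read_strategy_series(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fitness_table(table: FitnessTable, path: Union[str, Path],
                        max_n: Optional[int] = None) -> Path:
    path = Path(path)
    table.to_frame(max_n=max_n).to_csv(path, index=False, na_rep="")
    return path


def write_nash_report(analysis: NashAnalysis, path: Union[str, Path]) -> Path:
    path = Path(path)
    pd.DataFrame(analysis.arrows,
                 columns=["n_G", "n_D", "arrow"]).to_csv(path, index=False)
    return path


def write_run_summary(result: RunResult, path: Union[str, Path]) -> Path:
    caps = result.captures
    from .core import Strategy
    summary = {
        "config": config_to_dict(result.config),
        "seed": int(result.seed),
        "n_steps": int(result.n_steps),
        "total_captures": int(len(caps)),
        "captures_gcs": int((caps["strategy"] == int(Strategy.GCS)).sum()),
        "captures_dcs": int((caps["strategy"] == int(Strategy.DCS)).sum()),
        "fixation_outcome": result.fixation_outcome,
        "fixation_time": (None if result.fixation_time is None
                          else float(result.fixation_time)),
        "window": list(result.window),
    }
    path = Path(path)
    path.write_text(json.dumps(summary, indent=2))
    return path


def read_run_summary(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def write_run(result: RunResult, out_dir: Union[str, Path],
              prefix: str = "run") -> dict[str, Path]:
    """Write the capture log, strategy series and summary JSON of a run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return {
        "captures": write_capture_log(result.captures,
                                      out / f"{prefix}_captures.csv"),
        "series": write_strategy_series(result,
                                        out / f"{prefix}_strategies.csv"),
        "summary": write_run_summary(result, out / f"{prefix}_summary.json"),
    }
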