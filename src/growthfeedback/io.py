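"""Readers, writers, and configuration plumbing for the analysis pipeline.

Unit conventions at the I/O boundary: concentrations in ug/ml, times in
minutes, rates in 1/h. Tabular data are long-format CSV/TSV; fit summaries
are JSON carrying parameters, uncertainties, the seed, and a configuration
hash so reruns are attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("growthfeedback")

__all__ = [
    "read_long_table",
    "write_report",
    "config_hash",
    "PipelineConfig",
    "load_pipeline_config",
    "LONG_TABLE_SCHEMA",
    "CURVE_SCHEMA",
    "SCREEN_SCHEMA",
]

# column name -> (dtype, lower bound or None)
LONG_TABLE_SCHEMA = {
    "well": (str, None),
    "condition_id": (str, None),
    "time_min": (float, 0.0),
    "signal": (float, None),
    "signal_kind": (str, None),
}
CURVE_SCHEMA = {
    "condition_id": (str, None),
    "conc_ug_ml": (float, 0.0),
    "growth_h": (float, None),
}
SCREEN_SCHEMA = {
    "strain_id": (str, None),
    "g0_h": (float, None),
    "g_drug_h": (float, None),
}


def read_long_table(path: str | Path, schema: Mapping[str, tuple],
                    delimiter: Optional[str] = None) -> pd.DataFrame:
    """Read a long-format CSV/TSV and validate it against a column schema.

    The delimiter is sniffed unless forced. Missing required columns raise
    immediately, naming the column; malformed rows (unparsable numerics or
    bound violations) are logged with line numbers, skipped, and counted in
    ``df.attrs['n_skipped']``.
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else None  # None => sniff
    df = pd.read_csv(path, sep=sep, engine="python")
    for col in schema:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")
    bad = pd.Series(False, index=df.index)
    for col, (dtype, low) in schema.items():
        if dtype is float:
            coerced = pd.to_numeric(df[col], errors="coerce")
            invalid = coerced.isna() & df[col].notna()
            if low is not None:
                invalid |= coerced < low
            bad |= invalid | df[col].isna()
            df[col] = coerced
        else:
            bad |= df[col].isna()
    if bad.any():
        for idx in df.index[bad]:
            logger.warning("%s: skipping malformed row at line %d",
                           path.name, idx + 2)  # +2: header and 1-based
    out = df[~bad].reset_index(drop=True)
    out.attrs["n_skipped"] = int(bad.sum())
    return out


_PIPELINE_SECTIONS = {
    "model": {"omega_R", "omega_C", "K_Mc", "chi_demand", "K_Ma"},
    "regulation": {"chi_max", "slope_lambda", "converge_level", "clamp_c"},
    "fit": {"hill_min_rate", "n_starts", "drug_free_max_c", "clamp_c"},
    "growth": {"od_window_low", "od_window_high", "min_rate", "max_time",
               "lum_low", "lum_high", "hill_min_rate", "rate_match_tol"},
    "stages": None,  # free-form mapping of stage name -> bool
    "paths": None,  # free-form mapping of label -> path
    "seed": None,
    "out_dir": None,
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration loaded from JSON or YAML.

    Sections: [model] and [regulation] override the shipped calibrated
    parameters, [fit] and [growth] tune the fitting stages, ``stages``
    toggles pipeline steps, ``paths`` maps inputs/outputs, plus a global
    seed and output directory. Unknown sections or keys are rejected
    before any stage runs.
    """

    model: Dict[str, float] = dataclasses.field(default_factory=dict)
    regulation: Dict[str, float] = dataclasses.field(default_factory=dict)
    fit: Dict[str, Any] = dataclasses.field(default_factory=dict)
    growth: Dict[str, Any] = dataclasses.field(default_factory=dict)
    stages: Dict[str, bool] = dataclasses.field(default_factory=dict)
    paths: Dict[str, str] = dataclasses.field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."

    def hash(self) -> str:
        return config_hash(self)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load and schema-validate a pipeline config file (JSON or YAML)."""
    import yaml

    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)  # YAML is a superset of JSON
    if not isinstance(raw, dict):
        raise ValueError("pipeline config must be a mapping")
    for section, value in raw.items():
        if section not in _PIPELINE_SECTIONS:
            raise ValueError(f"unknown config section: {section!r}")
        allowed = _PIPELINE_SECTIONS[section]
        if allowed is not None and isinstance(value, dict):
            unknown = set(value) - allowed
            if unknown:
                raise ValueError(
                    f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "value") and isinstance(getattr(obj, "value"), str):
        return obj.value  # enums
    return obj


def config_hash(config: Any) -> str:
    """Stable short hash of a configuration object (dataclass or mapping)."""
    canonical = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_report(results: Any, path: str | Path, format: Optional[str] = None) -> Path:
    """Write a stage result to CSV (tabular) or JSON (fit summaries).

    DataFrames go to CSV at full precision; everything else is serialized
    to JSON via dataclass/numpy-aware conversion so a re-read reproduces
    the values exactly.
    """
    path = Path(path)
    if format is None:
        format = "csv" if isinstance(results, pd.DataFrame) else "json"
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        results.to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(_jsonable(results), fh, indent=2)
    else:
        raise ValueError(f"unknown format: {format!r}")
    return path
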