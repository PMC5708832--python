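"""File I/O and configuration for the pipeline.

All tables are UTF-8 CSV with a header row and ISO dates; configuration is
YAML.  Readers validate schemas and report offending rows so a malformed
input fails loudly at the door rather than mid-pipeline.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .synthetic_data import ScenarioConfig, SyntheticDataset

__all__ = [
    "read_table",
    "load_dataset",
    "save_scenario_config",
    "load_scenario_config",
    "TABLE_SCHEMAS",
]

TABLE_SCHEMAS = {
    "survey": ["site", "year", "pass", "length_mm"],
    "temperature": ["site", "date", "temp_C"],
    "annual": ["year", "adults", "captives_released", "translocated", "flow_cfs"],
    "captive_lengths": ["year", "length_mm"],
}


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and schema-check one of the four pipeline tables."""
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path)
    missing = set(TABLE_SCHEMAS[kind]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[TABLE_SCHEMAS[kind]].isna().any(axis=1)
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad][:10]]  # 1-based incl. header
        raise ValueError(f"{path}: missing values at file rows {rows}")
    if kind == "temperature":
        df["date"] = pd.to_datetime(df["date"])
    return df


def load_dataset(directory) -> SyntheticDataset:
    """Load the four tables (and truth, if present) from a directory."""
    d = Path(directory)
    tables = {k: read_table(d / f"{k}.csv", k) for k in TABLE_SCHEMAS}
    truth = {}
    truth_path = d / "truth.json"
    if truth_path.exists():
        import json

        truth = json.loads(truth_path.read_text())
    return SyntheticDataset(
        survey=tables["survey"],
        temperature=tables["temperature"],
        annual=tables["annual"],
        captive_lengths=tables["captive_lengths"],
        truth=truth,
    )


def save_scenario_config(cfg: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_listify(cfg.to_dict()), sort_keys=False))


def load_scenario_config(path) -> ScenarioConfig:
    return ScenarioConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj
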