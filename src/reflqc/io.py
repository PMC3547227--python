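"""Tab-separated reflection tables and YAML simulation configs.

Unmerged reflection TSV schema (header line, then one observation per
row): ``h k l batch I sigma d flags`` — ``flags`` is a semicolon-joined
subset of {rejected_outlier, rejected_ice, rejected_lowres} or ``-`` when
clear.  Merged TSV: ``h k l I_mean sigma_mean n d``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .merging import FLAG_COLUMNS, MergedData, observations_frame
from .simulate import IceContamination, NoiseModel, SimulationConfig
from .symmetry import UnitCell

__all__ = [
    "write_reflections",
    "read_reflections",
    "write_merged",
    "load_config",
    "dump_config",
]


def write_reflections(df: pd.DataFrame, path: str | Path) -> None:
    df = observations_frame(df)
    flags = []
    flag_arr = {c: df[c].to_numpy(dtype=bool) for c in FLAG_COLUMNS}
    for i in range(len(df)):
        active = [c for c in FLAG_COLUMNS if flag_arr[c][i]]
        flags.append(";".join(active) if active else "-")
    out = df[["h", "k", "l", "batch", "I", "sigma", "d"]].copy()
    out["flags"] = flags
    # default float formatting round-trips exactly through read_csv
    out.to_csv(path, sep="\t", index=False)


def read_reflections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"h", "k", "l", "batch", "I", "sigma", "d"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reflection TSV missing columns: {sorted(missing)}")
    flags = df.pop("flags") if "flags" in df.columns else pd.Series("-", index=df.index)
    for col in FLAG_COLUMNS:
        df[col] = flags.fillna("-").str.contains(col)
    return df


def write_merged(merged: MergedData, path: str | Path) -> None:
    merged.groups.to_csv(path, sep="\t", index=False)


def _cfg_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["cell"] = dataclasses.asdict(cfg.cell)
    d["noise"] = dataclasses.asdict(cfg.noise)
    d["ice_windows"] = [dataclasses.asdict(w) for w in cfg.ice_windows]
    return d


def dump_config(cfg: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_cfg_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "cell" in kwargs:
        kwargs["cell"] = UnitCell(**kwargs["cell"])
    if "noise" in kwargs:
        kwargs["noise"] = NoiseModel(**kwargs["noise"])
    if "ice_windows" in kwargs:
        kwargs["ice_windows"] = tuple(IceContamination(**w) for w in kwargs["ice_windows"])
    return SimulationConfig(**kwargs)
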