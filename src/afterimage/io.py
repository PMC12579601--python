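"""File I/O: measurements CSV, YAML/JSON configuration, exports.

Measurements CSV schema (UTF-8, header required, '.' decimal):
experiment, participant, block, trial, space, inducer_hue_deg,
inducer_chroma, inducer_Lstar, response_hue_deg, response_chroma,
skipped (0/1).  Skipped rows may leave the response fields empty.
A ``column_map`` lets externally deposited files with different headers
be ingested without bespoke parsers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .colorimetry import ChromaticityY, MonitorModel, monitor_from_dict, DEFAULT_MONITOR
from .models import AdaptationConfig, HeringPrototypes
from .observer import ObserverConfig

__all__ = [
    "MEASUREMENT_COLUMNS",
    "read_measurements",
    "write_measurements",
    "write_predictions",
    "load_config",
]

MEASUREMENT_COLUMNS = [
    "experiment",
    "participant",
    "block",
    "trial",
    "space",
    "inducer_hue_deg",
    "inducer_chroma",
    "inducer_Lstar",
    "response_hue_deg",
    "response_chroma",
    "skipped",
]

_NUMERIC = [
    "inducer_hue_deg",
    "inducer_chroma",
    "inducer_Lstar",
    "response_hue_deg",
    "response_chroma",
]


class MeasurementSchemaError(ValueError):
    """Raised for malformed measurement files, with row numbers."""


def read_measurements(path, column_map: dict = None) -> pd.DataFrame:
    """Read and validate a measurements CSV into typed records.

    ``column_map`` maps source column names to the documented schema
    (e.g. {"hue_resp": "response_hue_deg"}).  Rows violating the schema
    raise with 1-based data row numbers.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"participant", "space", "inducer_hue_deg", "inducer_chroma", "skipped"}
    missing = required - set(df.columns)
    if missing:
        raise MeasurementSchemaError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col in _NUMERIC else ""
    bad = []
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        nonnum = df[col].notna() & coerced.isna() & (df[col].astype(str).str.strip() != "")
        bad.extend((i + 1, f"non-numeric {col}") for i in df.index[nonnum])
        df[col] = coerced
    df["skipped"] = pd.to_numeric(df["skipped"], errors="coerce").fillna(0).astype(int)
    hue_bad = df["response_hue_deg"].notna() & (
        (df["response_hue_deg"] < 0) | (df["response_hue_deg"] >= 360)
    )
    bad.extend((i + 1, "response hue outside [0, 360)") for i in df.index[hue_bad])
    resp_missing = (df["skipped"] == 0) & df["response_hue_deg"].isna()
    bad.extend(
        (i + 1, "non-skipped row without response hue") for i in df.index[resp_missing]
    )
    if bad:
        msgs = "; ".join(f"row {r}: {m}" for r, m in bad[:20])
        raise MeasurementSchemaError(f"{path}: {msgs}")
    return df[MEASUREMENT_COLUMNS]


def write_measurements(df: pd.DataFrame, path):
    df[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def write_predictions(df: pd.DataFrame, path):
    df.to_csv(path, index=False, float_format="%.6g")


def _section(cfg, name, default=None):
    v = cfg.get(name, default)
    return {} if v is None else v


def load_config(path) -> dict:
    """Load the global YAML/JSON config into constructed objects.

    Sections: ``monitor`` (primaries, gamma, white, background_Lstar),
    ``adaptation`` (AdaptationConfig fields), ``observer`` (ObserverConfig
    fields), ``hering_prototypes`` (red/yellow/green/blue azimuths),
    ``munsell_table`` (path), ``seed``.  Returns a dict with the built
    objects plus the raw mapping under "raw".
    """
    text = Path(path).read_text()
    cfg = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    ) or {}
    out = {"raw": cfg, "seed": int(cfg.get("seed", 0))}
    out["monitor"] = (
        monitor_from_dict(cfg["monitor"]) if "monitor" in cfg else DEFAULT_MONITOR
    )
    out["adaptation"] = AdaptationConfig(**_section(cfg, "adaptation"))
    obs = _section(cfg, "observer")
    if obs:
        obs = dict(obs)
        obs["adaptation"] = out["adaptation"]
        out["observer"] = ObserverConfig(**obs)
    proto = cfg.get("hering_prototypes")
    if proto:
        out["hering_prototypes"] = HeringPrototypes(**proto)
    if cfg.get("munsell_table"):
        from .munsell import read_munsell_renotation

        out["munsell_table"] = read_munsell_renotation(cfg["munsell_table"])
    return out
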