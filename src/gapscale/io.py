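"""CSV and config I/O with schema validation, plus run manifests.

All tabular interchange is RFC-4180 CSV (UTF-8, '.' decimal); configs are
YAML.  Profile tables carry exactly 50 bin columns ``bin_00..bin_49``.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthgen import N_BINS

BIN_COLUMNS = [f"bin_{i:02d}" for i in range(N_BINS)]
PROFILE_META_COLUMNS = ["embryo_id", "line", "length_um", "cycle", "gene"]
STAGING_COLUMNS = [
    "embryo_id", "n_nuclei_dorsal", "nuclear_length_um", "invagination_pct",
]


class SchemaError(ValueError):
    """A table or config violates its documented schema."""


def validate_profiles(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the profile-table schema; returns the frame unchanged."""
    for col in PROFILE_META_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"profile table missing column {col!r}")
    present = [c for c in df.columns if c.startswith("bin_")]
    if sorted(present) != BIN_COLUMNS:
        missing = sorted(set(BIN_COLUMNS) - set(present))
        extra = sorted(set(present) - set(BIN_COLUMNS))
        raise SchemaError(
            f"profile table must have exactly the 50 bin columns; "
            f"missing={missing} extra={extra}"
        )
    if (df["length_um"] <= 0).any():
        bad = df.index[df["length_um"] <= 0][0]
        raise SchemaError(f"non-positive embryo length at row {bad}")
    return df


def read_profiles(path) -> pd.DataFrame:
    return validate_profiles(pd.read_csv(path))


def write_profiles(df: pd.DataFrame, path) -> None:
    validate_profiles(df)
    df.to_csv(path, index=False)


def read_staging(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in STAGING_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"staging table missing column {col!r}")
    return df


def write_staging(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_config(path) -> dict:
    """Load a YAML config file as a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"config {path} must be a YAML mapping")
    return cfg


def config_hash(obj) -> str:
    """Stable short hash of a config (for manifests)."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(
    out_dir, stage: str, config: dict, seed: int | None, outputs: list[str]
) -> Path:
    """Write a run manifest tying outputs to config hash, seed and time."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config_hash": config_hash(config),
        "seed": seed,
        "outputs": outputs,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def profiles_to_records(df: pd.DataFrame):
    """Yield (metadata row, 50-bin array) pairs from a profile table."""
    validate_profiles(df)
    bins = df[BIN_COLUMNS].to_numpy(dtype=float)
    for (_, row), b in zip(df.iterrows(), bins):
        yield row, np.asarray(b)
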