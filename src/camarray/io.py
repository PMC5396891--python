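"""CSV interchange for the pipeline's tidy tables.

Every table written by the pipeline carries a one-line ``#`` header comment
holding the run's config hash, so outputs are traceable to the exact
configuration that produced them; readers skip comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "read_deployments",
    "read_events",
    "read_detections",
    "serialize_cameras",
    "parse_cameras",
]


def config_hash(config_dict: dict) -> str:
    """Short stable hash of a JSON-serializable configuration mapping."""
    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def serialize_cameras(cams: tuple) -> str:
    return ";".join(cams)


def parse_cameras(text: str) -> tuple:
    return tuple(text.split(";")) if text else ()


def write_table(df: pd.DataFrame, path: "str | Path", cfg_hash: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = df.copy()
    if "contributing_cameras" in df.columns:
        df["contributing_cameras"] = df["contributing_cameras"].map(
            lambda v: serialize_cameras(v) if isinstance(v, tuple) else v
        )
    with open(path, "w") as fh:
        if cfg_hash:
            fh.write(f"# camarray config={cfg_hash}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: "str | Path", **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def read_deployments(path: "str | Path") -> pd.DataFrame:
    dep = read_table(path)
    for col in ("active_start", "active_end"):
        dep[col] = pd.to_datetime(dep[col]).dt.date
    return dep


def read_events(path: "str | Path") -> pd.DataFrame:
    events = read_table(path)
    events["timestamp"] = pd.to_datetime(events["timestamp"])
    return events


def read_detections(path: "str | Path") -> pd.DataFrame:
    det = read_table(path)
    for col in ("timestamp_first", "timestamp_last"):
        det[col] = pd.to_datetime(det[col])
    det["contributing_cameras"] = det["contributing_cameras"].map(parse_cameras)
    return det
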