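"""Configuration loading, result writers and run manifests.

Configs are JSON or YAML documents mirroring :class:`NetworkConfig`; unknown
keys are rejected.  All CSV output uses a header row, UTF-8 and full-precision
(round-trippable) floats; nested metadata goes to JSON sidecars.  Every CLI
run emits one ``manifest.json`` capturing the config snapshot, seeds and
output paths, written last so a manifest implies a complete run.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import ValidationError

from . import __version__
from .model import Trace
from .params import NetworkConfig, preset

__all__ = [
    "load_config",
    "save_config",
    "load_preset_file",
    "write_trace",
    "write_response_curve",
    "write_bursts",
    "write_manifest",
    "read_trace_csv",
    "packaged_efficiencies",
]


def load_config(path: str | Path) -> NetworkConfig:
    """Load and validate a network config from JSON or YAML.

    The document may contain a top-level ``preset: dominant|subordinate`` key;
    remaining keys override the preset's fields (dotted paths allowed under
    ``overrides``).
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config document must be a mapping")
    preset_name = data.pop("preset", None)
    overrides = data.pop("overrides", {})
    try:
        if preset_name is not None:
            cfg = preset(preset_name)
            if data:
                merged = cfg.model_dump()
                _deep_update(merged, data)
                cfg = NetworkConfig.model_validate(merged)
        else:
            cfg = NetworkConfig.model_validate(data)
    except ValidationError as err:
        bad = ", ".join(
            "/".join(str(p) for p in e["loc"]) or "<root>" for e in err.errors()
        )
        raise ValueError(f"{path}: invalid config (offending keys: {bad})") from err
    if overrides:
        cfg = cfg.with_overrides(**overrides)
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def save_config(cfg: NetworkConfig, path: str | Path) -> Path:
    path = Path(path)
    doc = cfg.model_dump()
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2) + "\n")
    return path


def load_preset_file(name: str) -> NetworkConfig:
    """Load one of the shipped preset files (``dominant`` / ``subordinate``)."""
    ref = resources.files("mcellnet").joinpath(f"data/preset_{name}.json")
    with resources.as_file(ref) as p:
        return load_config(p)


def packaged_efficiencies() -> pd.DataFrame:
    """The published primer-efficiency table shipped with the package."""
    ref = resources.files("mcellnet").joinpath("data/primer_efficiencies.csv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def write_trace(trace: Trace, path: str | Path) -> Path:
    """Trace to CSV (t_ms + one column per state variable) with a JSON
    metadata sidecar."""
    path = Path(path)
    _float_csv(trace.to_dataframe(), path)
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(_jsonable(trace.meta), indent=2) + "\n")
    return path


def read_trace_csv(path: str | Path, dt: float | None = None) -> Trace:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["t_ms"].to_numpy()
    data = df.drop(columns=["t_ms"]).to_numpy()
    if dt is None:
        dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    meta_path = Path(path).with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Trace(time=t, data=data, dt=dt, meta=meta)


def write_response_curve(curve, path: str | Path) -> Path:
    path = Path(path)
    _float_csv(curve.to_dataframe(), path)
    return path


def write_bursts(result, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "onset_ms": e.onset_ms,
            "offset_ms": e.offset_ms,
            "duration_ms": e.duration_ms,
            "p2p_mV": e.peak_to_peak_mV,
        }
        for e in result.events
    ]
    _float_csv(pd.DataFrame(rows, columns=["onset_ms", "offset_ms", "duration_ms", "p2p_mV"]), path)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_manifest(
    out_dir: str | Path,
    command: str,
    config_snapshot: dict | None = None,
    seed: int | None = None,
    outputs: list | None = None,
) -> Path:
    """Write the run manifest; call after all other outputs succeed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "argv": sys.argv,
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": _jsonable(config_snapshot) if config_snapshot else None,
        "outputs": [str(p) for p in (outputs or [])],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
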