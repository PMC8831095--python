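"""CSV / JSON / YAML input-output for the localization pipeline.

All tables are comma-separated UTF-8 with a header row; coordinates are
projected metres (UTM-style) and timestamps ISO-8601 UTC.  Errors on
malformed inputs name the file and the offending column.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .localization import FilterSpec, NodeNetwork
from .propagation import RssDecayModel
from .simulation import NetworkConfig, NoiseModel

__all__ = [
    "read_nodes_csv",
    "read_detections_csv",
    "read_calibration_csv",
    "write_estimates_csv",
    "SimulationPlan",
    "load_simulation_plan",
    "write_manifest",
]

CALIBRATION_COLUMNS = ("node_id", "node_x", "node_y", "test_x", "test_y", "mean_rss")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_nodes_csv(path: str | Path, avg_spacing_m: float | None = None) -> NodeNetwork:
    """Read a node table (node_id, x, y) into a :class:`NodeNetwork`."""
    df = pd.read_csv(path)
    _require_columns(df, ("node_id", "x", "y"), path)
    df["node_id"] = df["node_id"].astype(str)
    return NodeNetwork.from_frame(df, avg_spacing_m=avg_spacing_m)


def read_detections_csv(path: str | Path) -> pd.DataFrame:
    """Read a detection log (tag_id, node_id, rss, timestamp) with UTC times."""
    df = pd.read_csv(path)
    _require_columns(df, ("tag_id", "node_id", "rss", "timestamp"), path)
    out = pd.DataFrame(
        {
            "tag_id": df["tag_id"].astype(str),
            "node_id": df["node_id"].astype(str),
            "rss": pd.to_numeric(df["rss"], errors="raise"),
            "time": pd.to_datetime(df["timestamp"], utc=True),
        }
    )
    return out.sort_values("time", kind="stable").reset_index(drop=True)


def read_calibration_csv(path: str | Path) -> pd.DataFrame:
    """Read a calibration table and derive node-transmitter distances.

    Expects ``node_id, node_x, node_y, test_x, test_y, mean_rss``; returns a
    frame with ``node_id, distance_m, rss_db`` (Euclidean distances computed
    from the projected coordinates).
    """
    df = pd.read_csv(path)
    _require_columns(df, CALIBRATION_COLUMNS, path)
    dx = df["node_x"].astype(float) - df["test_x"].astype(float)
    dy = df["node_y"].astype(float) - df["test_y"].astype(float)
    return pd.DataFrame(
        {
            "node_id": df["node_id"].astype(str),
            "distance_m": (dx * dx + dy * dy) ** 0.5,
            "rss_db": df["mean_rss"].astype(float),
        }
    )


def write_estimates_csv(path: str | Path, rows: pd.DataFrame) -> None:
    """Write localization estimates (tag_id, window_start, x, y, ...)."""
    rows.to_csv(path, index=False)


@dataclass(frozen=True)
class SimulationPlan:
    """Parsed simulation config: network, decay model, noise, filters, sizes."""

    network: NetworkConfig
    model: RssDecayModel
    noise: NoiseModel
    filters: tuple[FilterSpec, ...]
    n_locations: int = 100
    n_reps: int = 1000
    seed: int = 0


def load_simulation_plan(path: str | Path) -> SimulationPlan:
    """Load a YAML simulation config.

    Expected keys: ``network`` (layout/spacing_m/extent_m/seed), ``model``
    (a/S/K or a path under ``path``), ``noise`` (NoiseModel fields),
    ``filters`` (list of strings like ``none``, ``rss:-80``, ``dist:1.25``,
    ``dist:315m``), ``n_locations``, ``n_reps``, ``seed``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: simulation config must be a mapping")
    try:
        network = NetworkConfig(**raw.get("network", {}))
        model_spec = raw.get("model", {})
        if isinstance(model_spec, str):
            model = RssDecayModel.from_json(Path(path).parent / model_spec)
        else:
            model = RssDecayModel.from_dict(model_spec)
        noise_spec = dict(raw.get("noise", {}))
        cal_path = noise_spec.pop("calibration_csv", None)
        if cal_path is not None:
            noise_spec["calibration"] = read_calibration_csv(
                Path(path).parent / cal_path
            )
        noise = NoiseModel(**noise_spec)
        filters = tuple(FilterSpec.parse(f) for f in raw.get("filters", ["none"]))
    except (TypeError, KeyError) as exc:
        raise ValueError(f"{path}: invalid simulation config: {exc}") from exc
    return SimulationPlan(
        network=network,
        model=model,
        noise=noise,
        filters=filters,
        n_locations=int(raw.get("n_locations", 100)),
        n_reps=int(raw.get("n_reps", 1000)),
        seed=int(raw.get("seed", 0)),
    )


def write_manifest(
    out_path: str | Path,
    inputs: Sequence[str | Path] = (),
    outputs: Sequence[str | Path] = (),
    seed: int | None = None,
    config_text: str | None = None,
) -> Path:
    """Write a run manifest (JSON) alongside an output file.

    Records the package version, a SHA-256 hash of the configuration text,
    the seed, a timestamp and the input/output paths, so any run can be
    traced and reproduced.
    """
    out_path = Path(out_path)
    manifest = {
        "package": "nodeloc",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "seed": seed,
        "config_sha256": (
            hashlib.sha256(config_text.encode()).hexdigest() if config_text else None
        ),
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
    }
    mpath = Path(str(out_path) + ".manifest.json")
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    return mpath
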