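"""Synthetic fixture files exercising every pipeline stage offline.

Real deployments produce a calibration campaign, a node table and detection
logs downloaded from base stations.  ``make_fixtures`` writes small synthetic
stand-ins for all three -- generated from the packaged decay curve plus
noise -- so the fit / localize / simulate / evaluate commands can be run
end-to-end without any field data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import GUAM_DECAY_MODEL
from .simulation import NetworkConfig, NoiseModel, generate_rss, make_network

__all__ = ["make_fixtures"]

_SIM_YAML = """\
# Small demonstration simulation (synthetic).
network:
  layout: uniform
  spacing_m: 250
  extent_m: 1250
model:
  a: {a}
  S: {S}
  K: {K}
noise:
  mode: parametric
filters: [none, "dist:1.25", "rss:-90"]
n_locations: 10
n_reps: 20
seed: {seed}
"""


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write synthetic calibration, node, detection and config fixtures.

    Returns a mapping of fixture name to path.  Deterministic per seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    model = GUAM_DECAY_MODEL
    noise = NoiseModel()

    # Node table: a 5x5 grid at 100 m spacing.
    network = make_network(NetworkConfig(layout="uniform", spacing_m=100.0, extent_m=400.0))
    nodes_path = out / "nodes.csv"
    network.to_frame().to_csv(nodes_path, index=False)

    # Calibration campaign: stationary test locations at a ladder of offsets
    # from randomly chosen nodes, window-averaged RSS from the decay curve
    # plus noise (sd ~ 3 dB after averaging ~4 pulses at sigma 6 dB).
    offsets = np.array([1.0, 10.0, 20.0, 50.0, 75.0, 100.0, 125.0, 250.0, 500.0, 1000.0])
    rows = []
    for tx_off in offsets:
        for _ in range(6):
            i = rng.integers(len(network))
            nx, ny = network.xy[i]
            theta = rng.uniform(0, 2 * np.pi)
            tx, ty = nx + tx_off * np.cos(theta), ny + tx_off * np.sin(theta)
            # every node may log the test transmitter, not just the focal one
            d_all = np.hypot(network.xy[:, 0] - tx, network.xy[:, 1] - ty)
            mean_rss = (
                model.a * np.exp(-model.S * d_all)
                + model.K
                + rng.normal(0.0, 3.0, size=d_all.shape)
            )
            keep = rng.random(d_all.shape) < 1.0 / (
                1.0 + np.exp((d_all - noise.detect_d50_m) / noise.detect_slope_m)
            )
            for j in np.flatnonzero(keep):
                rows.append(
                    {
                        "node_id": network.ids[j],
                        "node_x": network.xy[j, 0],
                        "node_y": network.xy[j, 1],
                        "test_x": tx,
                        "test_y": ty,
                        "mean_rss": float(np.clip(mean_rss[j], -120.0, -30.0)),
                    }
                )
    calibration_path = out / "calibration.csv"
    pd.DataFrame(rows).to_csv(calibration_path, index=False)

    # Detection log: one tag pulsing every 15 s at three stationary spots.
    spots = [(120.0, 140.0), (210.0, 260.0), (330.0, 180.0)]
    t0 = pd.Timestamp("2021-06-01T00:00:00Z")
    det_rows = []
    for si, (tx, ty) in enumerate(spots):
        d_all = np.hypot(network.xy[:, 0] - tx, network.xy[:, 1] - ty)
        for k in range(20):  # 5-min window, one pulse per 15 s
            t = t0 + pd.Timedelta(minutes=5 * si, seconds=15 * k)
            rss = generate_rss(d_all, model, noise, rng)
            for j in np.flatnonzero(np.isfinite(rss)):
                det_rows.append(
                    {
                        "tag_id": "tag01",
                        "node_id": network.ids[j],
                        "rss": round(float(rss[j]), 2),
                        "timestamp": t.isoformat(),
                    }
                )
    detections_path = out / "detections.csv"
    pd.DataFrame(det_rows).to_csv(detections_path, index=False)

    model_path = out / "model.json"
    model.to_json(model_path)

    sim_path = out / "sim.yaml"
    sim_path.write_text(
        _SIM_YAML.format(a=model.a, S=model.S, K=model.K, seed=seed)
    )

    return {
        "nodes": nodes_path,
        "calibration": calibration_path,
        "detections": detections_path,
        "model": model_path,
        "sim_config": sim_path,
    }
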