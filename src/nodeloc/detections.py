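"""Turn raw detection logs into per-node, per-window mean RSS inputs.

A node network logs one row per received transmitter pulse: tag id, node id,
RSS (dB) and a GPS-disciplined UTC timestamp.  Localization operates on a
coarser unit -- for one tag and one time window, the mean RSS at every node
that detected the tag.  Averaging within a window damps outlier RSS readings
caused by signal bounce and multipathing; trimming the window edges guards
against clock mismatch at the start and end of a stationary test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "NodeSignal",
    "LocalizationInput",
    "trim_window",
    "average_by_node",
    "iter_localization_inputs",
]

#: Required columns of a detection log.
DETECTION_COLUMNS = ("tag_id", "node_id", "rss", "time")


@dataclass(frozen=True)
class NodeSignal:
    """Window-averaged signal at one node: mean RSS (dB) and detection count."""

    mean_rss: float
    n: int


@dataclass(frozen=True)
class LocalizationInput:
    """One tag's per-node mean RSS over one time window -- the unit of estimation."""

    tag_id: str
    window_start: pd.Timestamp
    window_end: pd.Timestamp
    signals: Mapping[str, NodeSignal] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_end <= self.window_start:
            raise ValueError("window_end must be after window_start")

    def __len__(self) -> int:
        return len(self.signals)

    @property
    def node_ids(self) -> list[str]:
        return list(self.signals)

    def strongest_node(self) -> str:
        """Node id with the maximum mean RSS; ties broken by smallest node id."""
        if not self.signals:
            raise ValueError("no signals in this localization input")
        return min(self.signals, key=lambda n: (-self.signals[n].mean_rss, n))

    def with_signals(self, signals: Mapping[str, NodeSignal]) -> "LocalizationInput":
        return LocalizationInput(self.tag_id, self.window_start, self.window_end, dict(signals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tag_id": self.tag_id,
                "window_start": self.window_start,
                "node_id": list(self.signals),
                "mean_rss": [s.mean_rss for s in self.signals.values()],
                "n": [s.n for s in self.signals.values()],
            }
        )


def _check_columns(detections: pd.DataFrame) -> None:
    missing = [c for c in DETECTION_COLUMNS if c not in detections.columns]
    if missing:
        raise ValueError(f"detection log is missing column(s): {', '.join(missing)}")


def trim_window(
    detections: pd.DataFrame,
    window_start: pd.Timestamp,
    window_end: pd.Timestamp,
    trim_s: float,
) -> pd.DataFrame:
    """Keep detections in ``[start + trim_s, end - trim_s]``.

    An empty result is valid (all detections fell inside the trimmed
    margins); a window shorter than ``2 * trim_s`` is an input error.
    """
    _check_columns(detections)
    if trim_s < 0:
        raise ValueError("trim_s must be >= 0")
    window_start = pd.Timestamp(window_start)
    window_end = pd.Timestamp(window_end)
    if 2 * pd.Timedelta(seconds=trim_s) >= window_end - window_start:
        raise ValueError(
            f"window of {(window_end - window_start).total_seconds():.0f} s cannot "
            f"be trimmed by {trim_s:.0f} s at each end"
        )
    lo = window_start + pd.Timedelta(seconds=trim_s)
    hi = window_end - pd.Timedelta(seconds=trim_s)
    return detections[(detections["time"] >= lo) & (detections["time"] <= hi)]


def average_by_node(
    detections: pd.DataFrame,
    tag_id: str,
    window_start: pd.Timestamp,
    window_end: pd.Timestamp,
) -> LocalizationInput:
    """Arithmetic mean RSS per node for one tag over one (already trimmed) window.

    Nodes with no detections are simply absent from the result.  An empty
    input yields an empty :class:`LocalizationInput`; whether that is
    estimable is decided downstream.
    """
    _check_columns(detections)
    sub = detections[detections["tag_id"] == tag_id]
    grouped = sub.groupby("node_id")["rss"].agg(["mean", "size"])
    signals = {
        str(node): NodeSignal(mean_rss=float(row["mean"]), n=int(row["size"]))
        for node, row in grouped.iterrows()
    }
    return LocalizationInput(
        tag_id=tag_id,
        window_start=pd.Timestamp(window_start),
        window_end=pd.Timestamp(window_end),
        signals=signals,
    )


def iter_localization_inputs(
    detections: pd.DataFrame,
    window_s: float = 60.0,
    stride_s: float = 60.0,
    trim_s: float = 0.0,
) -> Iterator[LocalizationInput]:
    """Slice a detection log into per-tag sliding windows.

    Windows of ``window_s`` seconds are laid out per tag starting at the
    tag's first detection, advancing by ``stride_s``; each window is trimmed
    by ``trim_s`` at both ends and averaged per node.  Windows with no
    surviving detections are skipped.
    """
    _check_columns(detections)
    if window_s <= 0 or stride_s <= 0:
        raise ValueError("window_s and stride_s must be positive")
    window = pd.Timedelta(seconds=window_s)
    stride = pd.Timedelta(seconds=stride_s)
    for tag_id, sub in detections.groupby("tag_id", sort=True):
        start = sub["time"].min()
        last = sub["time"].max()
        while start <= last:
            end = start + window
            trimmed = trim_window(sub, start, end, trim_s)
            if len(trimmed):
                yield average_by_node(trimmed, str(tag_id), start, end)
            start = start + stride
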