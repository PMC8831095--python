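"""Node selection filters and nonlinear least-squares trilateration.

Each detecting node constrains the transmitter to a circle: centre at the
node, radius the distance implied by inverting the RSS-decay curve.  Noise,
bounce and obstruction keep those circles from intersecting in a point, so
the location is estimated by minimizing the range-residual objective

    f(p) = sum_i ( ||p - node_i|| - d_i )^2

with a Gauss-Newton iteration seeded at the node with the strongest signal.
Far nodes report RSS near the noise floor, where the RSS-distance
relationship is nearly flat; including them drags estimates toward the
network centroid.  Two node-exclusion filters counter this: an RSS filter
(keep nodes above a dB cutoff) and a distance filter (keep nodes within a
radius -- a multiple of the average network spacing -- of the strongest-signal
node).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .detections import LocalizationInput
from .propagation import RSS_REPORTING_RANGE, RssDecayModel, invert_to_distance

__all__ = [
    "Node",
    "NodeNetwork",
    "FilterSpec",
    "LocationEstimate",
    "apply_rss_filter",
    "apply_distance_filter",
    "trilaterate",
    "localize",
]

#: Trilateration needs at least this many nodes.
MIN_NODES = 3


@dataclass(frozen=True)
class Node:
    """A fixed receiver: id plus planar projected coordinates in metres."""

    node_id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"node {self.node_id!r} has non-finite coordinates")


class NodeNetwork:
    """A collection of receiver nodes with its geometry.

    Parameters
    ----------
    nodes
        Iterable of :class:`Node`.  At least 3, unique ids, non-degenerate
        bounding box.
    avg_spacing_m
        Nominal spacing between neighbouring nodes in metres.  For uniform
        grids this is the grid spacing; when omitted it is computed as the
        mean distance from each node to its six nearest neighbours, the
        convention used to characterize irregular field networks.
    """

    def __init__(self, nodes: Iterable[Node], avg_spacing_m: float | None = None):
        nodes = list(nodes)
        if len(nodes) < MIN_NODES:
            raise ValueError(f"a network needs at least {MIN_NODES} nodes, got {len(nodes)}")
        ids = [n.node_id for n in nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("node ids must be unique within a network")
        self._nodes = nodes
        self.ids = np.array(ids, dtype=object)
        self.xy = np.array([[n.x, n.y] for n in nodes], dtype=float)
        self._index = {nid: i for i, nid in enumerate(ids)}
        xmin, ymin = self.xy.min(axis=0)
        xmax, ymax = self.xy.max(axis=0)
        if xmax - xmin <= 0 or ymax - ymin <= 0:
            raise ValueError("network extent is degenerate (all nodes collinear on an axis)")
        self.extent = (float(xmin), float(ymin), float(xmax), float(ymax))
        if avg_spacing_m is None:
            avg_spacing_m = self.mean_six_nearest_spacing()
        if avg_spacing_m <= 0:
            raise ValueError("avg_spacing_m must be positive")
        self.avg_spacing_m = float(avg_spacing_m)

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self):
        return iter(self._nodes)

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"node {node_id!r} is not in the network table") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def coords(self, node_id: str) -> np.ndarray:
        return self.xy[self.index_of(node_id)]

    def mean_six_nearest_spacing(self) -> float:
        """Mean distance from each node to its six nearest neighbours."""
        dm = squareform(pdist(self.xy))
        np.fill_diagonal(dm, np.inf)
        k = min(6, len(self._nodes) - 1)
        nearest = np.sort(dm, axis=1)[:, :k]
        return float(nearest.mean())

    @property
    def diameter_m(self) -> float:
        return float(pdist(self.xy).max())

    @classmethod
    def from_frame(cls, df: pd.DataFrame, avg_spacing_m: float | None = None) -> "NodeNetwork":
        """Build from a table with ``node_id``, ``x``, ``y`` columns."""
        missing = [c for c in ("node_id", "x", "y") if c not in df.columns]
        if missing:
            raise ValueError(f"node table is missing column(s): {', '.join(missing)}")
        nodes = [
            Node(str(r.node_id), float(r.x), float(r.y)) for r in df.itertuples(index=False)
        ]
        return cls(nodes, avg_spacing_m=avg_spacing_m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_id": list(self.ids), "x": self.xy[:, 0], "y": self.xy[:, 1]}
        )


@dataclass(frozen=True)
class FilterSpec:
    """Node-exclusion filter applied before trilateration.

    ``kind`` is one of ``"none"``, ``"rss"`` (keep nodes with mean RSS
    strictly above ``rss_cutoff_db``) or ``"distance"`` (keep nodes within a
    radius of the strongest-signal node).  The distance radius is either
    ``distance_multiplier`` times the network's average spacing, or the
    absolute ``radius_m`` when given -- the latter supports replicating
    published filter radii directly.
    """

    kind: str = "none"
    rss_cutoff_db: float | None = None
    distance_multiplier: float | None = None
    radius_m: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "rss", "distance"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "rss":
            lo, hi = RSS_REPORTING_RANGE
            if self.rss_cutoff_db is None or not lo <= self.rss_cutoff_db <= hi:
                raise ValueError(f"rss filter needs a cutoff in [{lo}, {hi}] dB")
        if self.kind == "distance":
            if self.radius_m is not None:
                if self.radius_m <= 0:
                    raise ValueError("radius_m must be positive")
            elif self.distance_multiplier is None or self.distance_multiplier <= 0:
                raise ValueError("distance filter needs a positive multiplier or radius_m")

    def resolved_radius_m(self, network: NodeNetwork) -> float:
        """Filter radius in metres for the given network (distance kind only)."""
        if self.kind != "distance":
            raise ValueError("only distance filters have a radius")
        if self.radius_m is not None:
            return float(self.radius_m)
        return float(self.distance_multiplier * network.avg_spacing_m)

    @property
    def label(self) -> str:
        if self.kind == "none":
            return "none"
        if self.kind == "rss":
            return f"rss_{self.rss_cutoff_db:g}dB"
        if self.radius_m is not None:
            return f"dist_{self.radius_m:g}m"
        return f"dist_{self.distance_multiplier:g}x"

    @classmethod
    def parse(cls, text: str) -> "FilterSpec":
        """Parse ``"none"``, ``"rss:-80"``, ``"dist:1.25"`` or ``"dist:315m"``."""
        text = text.strip()
        if text == "none":
            return cls(kind="none")
        try:
            kind, value = text.split(":", 1)
        except ValueError:
            raise ValueError(f"cannot parse filter spec {text!r}") from None
        if kind == "rss":
            return cls(kind="rss", rss_cutoff_db=float(value))
        if kind == "dist":
            if value.endswith("m"):
                return cls(kind="distance", radius_m=float(value[:-1]))
            return cls(kind="distance", distance_multiplier=float(value))
        raise ValueError(f"cannot parse filter spec {text!r}")


@dataclass(frozen=True)
class LocationEstimate:
    """Result of one trilateration attempt.

    ``status`` is ``"ok"`` (converged, >= 3 nodes), ``"too_few_nodes"``
    (no coordinates) or ``"no_convergence"`` (best iterate kept, flagged).
    ``nodes_used`` maps each contributing node id to its estimated distance.
    """

    x: float = math.nan
    y: float = math.nan
    status: str = "too_few_nodes"
    nodes_used: Mapping[str, float] = field(default_factory=dict)
    converged: bool = False
    n_iterations: int = 0
    residual_norm: float = math.nan
    ill_conditioned: bool = False

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


def apply_rss_filter(inp: LocalizationInput, cutoff_db: float) -> LocalizationInput:
    """Keep nodes whose mean RSS is strictly greater than the cutoff."""
    kept = {n: s for n, s in inp.signals.items() if s.mean_rss > cutoff_db}
    return inp.with_signals(kept)


def apply_distance_filter(
    inp: LocalizationInput, network: NodeNetwork, spec: FilterSpec
) -> LocalizationInput:
    """Keep nodes within the filter radius of the strongest-signal node.

    The anchor (strongest mean RSS, ties to the smallest node id) is always
    retained.  Raises ``KeyError`` if the anchor is absent from the network
    table.
    """
    if not inp.signals:
        raise ValueError("cannot distance-filter an empty localization input")
    radius = spec.resolved_radius_m(network)
    anchor = inp.strongest_node()
    axy = network.coords(anchor)
    kept = {}
    for node_id, sig in inp.signals.items():
        if node_id == anchor:
            kept[node_id] = sig
            continue
        if node_id in network:
            dx, dy = network.coords(node_id) - axy
            if math.hypot(dx, dy) <= radius:
                kept[node_id] = sig
    return inp.with_signals(kept)


def gauss_newton_trilaterate(
    xy: np.ndarray,
    distances: np.ndarray,
    start: np.ndarray,
    tol_m: float = 1e-6,
    max_iter: int = 200,
) -> tuple[float, float, bool, int, float]:
    """Minimize the range-residual objective from ``start`` by Gauss-Newton.

    Returns ``(x, y, converged, n_iterations, residual_norm)``.  Each step
    solves the normal equations of the linearized residuals and is halved
    until the objective decreases; convergence is declared when the accepted
    step is shorter than ``tol_m`` metres.
    """
    p = np.asarray(start, dtype=float).copy()
    diff = p - xy
    rng = np.hypot(diff[:, 0], diff[:, 1])
    r = rng - distances
    f0 = float(r @ r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        safe = np.maximum(rng, 1e-12)
        J = diff / safe[:, None]
        J[rng < 1e-12] = 0.0  # coincident with a node: no usable direction
        g = J.T @ r
        H = J.T @ J
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -r, rcond=None)[0]
        # Step-halving line search.
        t = 1.0
        accepted = False
        while t >= 2.0 ** -20:
            q = p + t * step
            diff_q = q - xy
            rng_q = np.hypot(diff_q[:, 0], diff_q[:, 1])
            r_q = rng_q - distances
            f_q = float(r_q @ r_q)
            if f_q < f0:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            # No descent direction left: at a (possibly flat) minimum.
            converged = True
            break
        f_prev = f0
        p, diff, rng, r, f0 = q, diff_q, rng_q, r_q, f_q
        if t * float(np.hypot(*step)) < tol_m:
            converged = True
            break
        # A zero estimated distance puts a kink in the objective at that
        # node; the iteration can zigzag there with tiny objective gains.
        # Treat a negligible relative decrease as convergence.
        if f_prev - f0 <= 1e-10 * max(f_prev, 1.0):
            converged = True
            break
    return float(p[0]), float(p[1]), converged, it, math.sqrt(f0)


def _collinear(xy: np.ndarray) -> bool:
    centered = xy - xy.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    return bool(sv[-1] < 1e-9 * max(sv[0], 1.0))


def trilaterate(
    nodes_with_distances: Sequence[tuple[float, float, float]] | np.ndarray,
    start_xy: Sequence[float],
    node_ids: Sequence[str] | None = None,
    tol_m: float = 1e-6,
    max_iter: int = 200,
) -> LocationEstimate:
    """Estimate a 2-D location from >= 3 (x, y, estimated distance) triples.

    With fewer than 3 nodes the result carries status ``too_few_nodes`` and
    no coordinates.  An exactly collinear node set is still solved but
    flagged ``ill_conditioned``.
    """
    arr = np.asarray(nodes_with_distances, dtype=float).reshape(-1, 3)
    xy, dists = arr[:, :2], arr[:, 2]
    if node_ids is None:
        node_ids = [str(i) for i in range(len(arr))]
    used = {str(n): float(d) for n, d in zip(node_ids, dists)}
    if len(arr) < MIN_NODES:
        return LocationEstimate(status="too_few_nodes", nodes_used=used)
    if np.allclose(pdist(xy), 0.0):
        return LocationEstimate(status="too_few_nodes", nodes_used=used)
    x, y, converged, n_iter, resid = gauss_newton_trilaterate(
        xy, dists, np.asarray(start_xy, dtype=float), tol_m=tol_m, max_iter=max_iter
    )
    return LocationEstimate(
        x=x,
        y=y,
        status="ok" if converged else "no_convergence",
        nodes_used=used,
        converged=converged,
        n_iterations=n_iter,
        residual_norm=resid,
        ill_conditioned=_collinear(xy),
    )


def localize(
    inp: LocalizationInput,
    network: NodeNetwork,
    model: RssDecayModel,
    spec: FilterSpec = FilterSpec(kind="none"),
    tol_m: float = 1e-6,
    max_iter: int = 200,
) -> LocationEstimate:
    """Filter nodes, convert mean RSS to distances, and trilaterate.

    The Gauss-Newton iteration is seeded at the coordinates of the strongest
    retained node.  Nodes whose RSS falls in the asymptote guard of the decay
    model (distance unidentifiable) are dropped rather than included at a
    huge distance.  Never raises on too few nodes -- the status says so.
    """
    if spec.kind == "rss":
        inp = apply_rss_filter(inp, spec.rss_cutoff_db)
    elif spec.kind == "distance":
        if not inp.signals:
            return LocationEstimate(status="too_few_nodes")
        inp = apply_distance_filter(inp, network, spec)

    ids, rows = [], []
    for node_id, sig in inp.signals.items():
        if node_id not in network:
            continue
        d_est = invert_to_distance(model, sig.mean_rss)
        if not np.isfinite(d_est):
            continue  # asymptote region: non-informative
        x, y = network.coords(node_id)
        ids.append(node_id)
        rows.append((x, y, d_est))
    if len(rows) < MIN_NODES:
        return LocationEstimate(
            status="too_few_nodes",
            nodes_used={n: d for n, (_, _, d) in zip(ids, rows)},
        )
    strongest = max(ids, key=lambda n: (inp.signals[n].mean_rss, n))
    # Tie-break above favours the larger id only among exact float ties;
    # re-anchor deterministically to the smallest id among the maxima.
    best_rss = max(inp.signals[n].mean_rss for n in ids)
    strongest = min(n for n in ids if inp.signals[n].mean_rss == best_rss)
    start = network.coords(strongest)
    return trilaterate(rows, start, node_ids=ids, tol_m=tol_m, max_iter=max_iter)
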