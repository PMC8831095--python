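"""Exponential decay model linking received signal strength (RSS) to distance.

Radio signal strength decays rapidly with distance from the transmitter.  In
structurally complex outdoor environments a three-parameter negative
exponential,

    RSS(d) = a * exp(-S * d) + K,

captures the empirical RSS-distance relationship better than the indoor
log-distance path-loss family: ``a`` is the drop between the zero-distance
signal and the noise floor, ``S`` the per-metre decay rate, and ``K`` the
horizontal asymptote that received values approach far from the transmitter.
Fitting this curve to calibration data (known transmitter-to-receiver
distances) and inverting it is the bridge from raw RSS detections to the
per-node distance estimates that trilateration consumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RSS_REPORTING_RANGE",
    "RssDecayModel",
    "CalibrationObservation",
    "DecayFitResult",
    "FitError",
    "fit_decay_model",
    "predict_rss",
    "invert_to_distance",
]

#: Reporting range of the node radio receivers, dB.
RSS_REPORTING_RANGE = (-120.0, -30.0)


class FitError(RuntimeError):
    """Nonlinear least-squares fit of the decay curve failed to converge."""


@dataclass(frozen=True)
class RssDecayModel:
    """Parameters of the exponential RSS-decay curve ``a*exp(-S*d) + K``.

    Parameters
    ----------
    a : float
        Intercept term in dB: the gap between RSS at distance zero and the
        asymptote.  Positive for any physically meaningful fit.
    S : float
        Decay rate per metre.  Stored positive and applied with an explicit
        negative sign in the exponent.
    K : float
        Horizontal asymptote in dB -- effectively the noise floor the
        received values approach at large distance.
    """

    a: float
    S: float
    K: float

    def __post_init__(self) -> None:
        for name in ("a", "S", "K"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"decay model parameter {name!r} must be finite")
        if self.a <= 0:
            raise ValueError(f"intercept a must be positive, got {self.a}")
        if self.S <= 0:
            raise ValueError(f"decay rate S must be positive, got {self.S}")

    @property
    def rss_at_zero(self) -> float:
        """Modelled RSS at distance zero, ``a + K`` (dB)."""
        return self.a + self.K

    def to_dict(self) -> dict:
        return {"a": self.a, "S": self.S, "K": self.K}

    @classmethod
    def from_dict(cls, d: dict) -> "RssDecayModel":
        return cls(a=float(d["a"]), S=float(d["S"]), K=float(d["K"]))

    def to_json(self, path: str | Path, **extra) -> None:
        """Persist the model (plus optional fit diagnostics) as JSON."""
        payload = {**self.to_dict(), **extra}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RssDecayModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CalibrationObservation:
    """One window-averaged RSS reading at a known node-transmitter distance."""

    node_id: str
    distance_m: float
    rss_db: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.distance_m) or self.distance_m < 0:
            raise ValueError(f"distance_m must be finite and >= 0, got {self.distance_m}")
        if not math.isfinite(self.rss_db):
            raise ValueError("rss_db must be finite")


@dataclass(frozen=True)
class DecayFitResult:
    """Fitted decay model together with least-squares diagnostics."""

    model: RssDecayModel
    residual_sd: float
    n_obs: int
    converged: bool
    stderr: tuple[float, float, float] = field(default=(np.nan, np.nan, np.nan))

    def to_json(self, path: str | Path) -> None:
        self.model.to_json(
            path,
            residual_sd=self.residual_sd,
            n_obs=self.n_obs,
            converged=self.converged,
        )


def _decay(d, a, S, K):
    return a * np.exp(-S * np.asarray(d, dtype=float)) + K


def _as_arrays(observations) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame (distance_m/rss_db columns) or observation records."""
    if isinstance(observations, pd.DataFrame):
        return (
            observations["distance_m"].to_numpy(dtype=float),
            observations["rss_db"].to_numpy(dtype=float),
        )
    obs = list(observations)
    return (
        np.array([o.distance_m for o in obs], dtype=float),
        np.array([o.rss_db for o in obs], dtype=float),
    )


def _self_start(d: np.ndarray, rss: np.ndarray) -> tuple[float, float, float]:
    # Closed-form asymptotic self-start: pin the asymptote just below the
    # weakest reading, take the intercept from the strongest, and estimate the
    # rate from the log-linearised curve.
    K0 = float(rss.min()) - 1.0
    a0 = max(float(rss.max()) - K0, 1e-6)
    z = (rss - K0) / a0
    mask = z > 1e-8
    if mask.sum() >= 2 and np.ptp(d[mask]) > 0:
        slope = np.polyfit(d[mask], np.log(z[mask]), 1)[0]
        S0 = -slope if slope < 0 else 1.0 / max(float(np.median(d)), 1.0)
    else:
        S0 = 1.0 / max(float(np.median(d)), 1.0)
    return a0, max(S0, 1e-8), K0


def fit_decay_model(
    observations: pd.DataFrame | Iterable[CalibrationObservation],
    initial_guess: RssDecayModel | None = None,
    weights: Sequence[float] | None = None,
) -> DecayFitResult:
    """Fit the exponential decay curve by nonlinear least squares.

    Parameters
    ----------
    observations
        Either a DataFrame with ``distance_m`` and ``rss_db`` columns or an
        iterable of :class:`CalibrationObservation`.
    initial_guess
        Optional starting parameters; when omitted a closed-form self-start
        heuristic is used (asymptote from the minimum RSS, intercept from the
        maximum, rate from the log-linearised slope).
    weights
        Optional per-observation weights (e.g. detection counts behind each
        window average).  Unweighted by default.

    Returns
    -------
    DecayFitResult
        Least-squares estimates of ``(a, S, K)`` with residual standard
        deviation, parameter standard errors and a convergence flag.

    Raises
    ------
    ValueError
        Fewer than 4 observations, fewer than 2 distinct distances, or RSS
        outside the receiver reporting range.
    FitError
        The optimizer failed to converge.
    """
    d, rss = _as_arrays(observations)
    if d.size < 4:
        raise ValueError(f"need at least 4 calibration observations, got {d.size}")
    if np.unique(d).size < 2:
        raise ValueError("calibration observations must span at least 2 distinct distances")
    lo, hi = RSS_REPORTING_RANGE
    if rss.min() < lo - 1e-9 or rss.max() > hi + 1e-9:
        raise ValueError(
            f"RSS outside receiver reporting range [{lo}, {hi}]: "
            f"[{rss.min():.2f}, {rss.max():.2f}]"
        )

    if initial_guess is not None:
        p0 = (initial_guess.a, initial_guess.S, initial_guess.K)
    else:
        p0 = _self_start(d, rss)

    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != d.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match the observations")
        sigma = 1.0 / np.sqrt(w)

    try:
        popt, pcov = curve_fit(
            _decay, d, rss, p0=p0, sigma=sigma, absolute_sigma=False, maxfev=20000
        )
    except RuntimeError as exc:  # scipy raises RuntimeError on non-convergence
        raise FitError(f"decay-model fit did not converge (start={p0}): {exc}") from exc

    model = RssDecayModel(a=float(popt[0]), S=float(popt[1]), K=float(popt[2]))
    resid = rss - _decay(d, *popt)
    dof = max(d.size - 3, 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    stderr = tuple(float(s) for s in np.sqrt(np.diag(pcov)))
    return DecayFitResult(
        model=model,
        residual_sd=residual_sd,
        n_obs=int(d.size),
        converged=True,
        stderr=stderr,
    )


def predict_rss(model: RssDecayModel, distance_m):
    """Evaluate the decay curve: expected RSS (dB) at the given distance(s).

    Accepts a scalar or array of non-negative distances.
    """
    d = np.asarray(distance_m, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValueError("distances must be finite and non-negative")
    out = model.a * np.exp(-model.S * d) + model.K
    return float(out) if np.isscalar(distance_m) else out


def invert_to_distance(
    model: RssDecayModel,
    rss_db,
    eps_db: float = 0.5,
    max_distance_m: float = np.inf,
):
    """Invert the decay curve: distance estimate (m) for the given RSS.

    The closed-form inverse ``d = -ln((rss - K)/a) / S`` applies on the
    informative branch ``K < rss <= a + K``.  Degenerate readings map to
    documented sentinels rather than NaN:

    - ``rss > a + K`` (stronger than the modelled zero-distance value) -> 0;
    - ``rss <= K + eps_db`` (at or below the asymptote guard) ->
      ``max_distance_m`` (default infinity), because distance is
      unidentifiable once the signal sits in the noise floor.

    Accepts scalars or arrays.
    """
    rss = np.asarray(rss_db, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (rss - model.K) / model.a
        d = -np.log(z) / model.S
    d = np.where(rss > model.rss_at_zero, 0.0, d)
    d = np.where(rss <= model.K + eps_db, max_distance_m, d)
    return float(d) if np.isscalar(rss_db) else d
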