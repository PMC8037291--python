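"""Clearance distances and EN 50499 zone classification.

The weighted-peak index measured along a straight departure line from the
gantry mouth falls off with distance approximately as an offset power law

    I(d) = A * (d + d0)^(-n)

where ``d`` is the distance from the gantry mouth (cm), ``d0`` an effective
offset locating the equivalent source centre behind the mouth (cm) and
``n`` a near-field-like decay exponent.  The *clearance distance* is where
the fitted index crosses a compliance threshold (100% by default):

    d_clear = (A / threshold)^(1/n) - d0

Fitting is done by unweighted least squares on log(index) against
log(d + d0); the offset ``d0`` is profiled out by a bounded 1-D search, so
the fit is deterministic and, with exactly three points, reduces to the
exact interpolant.

Zones follow the EN 50499 workplace classification: Zone 0 complies with
the general-public reference levels (RLs), Zone 1a exceeds the RLs but
complies with the occupational low ALs, Zone 1b complies with the high ALs
only, Zone 2 exceeds the high ALs.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DistanceProfile",
    "DecayFit",
    "ClearanceResult",
    "Zone",
    "fit_decay",
    "clearance_distance",
    "classify_zone",
    "zone_boundary_map",
    "BOUNDARY_LABELS",
]

#: zone boundary crossed where the index against each curve falls to 100%
BOUNDARY_LABELS = {
    "RL_B": "Zone 0 / Zone 1a",
    "LOW_AL_B": "Zone 1a / Zone 1b",
    "HIGH_AL_B": "Zone 1b / Zone 2",
}

_D0_BOUNDS = (1e-2, 1e5)  # cm, search window for the source-centre offset


class Zone(Enum):
    """EN 50499 workplace classification for EMF exposure."""

    ZONE0 = "Zone0"
    ZONE1A = "Zone1a"
    ZONE1B = "Zone1b"
    ZONE2 = "Zone2"


@dataclass(frozen=True)
class DistanceProfile:
    """Weighted-peak indices sampled along the departure line.

    ``points`` are ``(distance_cm, index_percent)`` pairs against the curve
    named by ``curve_id``; ``height`` is the probe height above the floor.
    """

    points: tuple[tuple[float, float], ...]
    height: float | None = None
    sequence_label: str = ""
    curve_id: str = "RL_B"

    def __post_init__(self) -> None:
        pts = tuple((float(d), float(i)) for d, i in self.points)
        object.__setattr__(self, "points", pts)
        d = self.distances
        if len(pts) and (np.any(d < 0) or np.any(np.diff(d) <= 0)):
            raise ValueError("distances must be non-negative and strictly increasing")
        if len(pts) and np.any(self.indices <= 0):
            raise ValueError("indices must be positive")

    @property
    def distances(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def scaled(self, k: float) -> "DistanceProfile":
        return DistanceProfile(
            tuple((d, i * k) for d, i in self.points),
            height=self.height,
            sequence_label=self.sequence_label,
            curve_id=self.curve_id,
        )


@dataclass(frozen=True)
class DecayFit:
    """Fitted offset power law I(d) = A (d + d0)^(-n)."""

    A: float
    d0: float
    n: float
    rms_log_residual: float
    n_points: int

    def index_at(self, d: float | np.ndarray) -> float | np.ndarray:
        return self.A * (np.asarray(d, dtype=float) + self.d0) ** (-self.n)

    def crossing(self, threshold: float = 100.0) -> float:
        """Distance where the fitted index equals ``threshold`` (may be < 0)."""
        return (self.A / threshold) ** (1.0 / self.n) - self.d0


@dataclass(frozen=True)
class ClearanceResult:
    """Clearance distance with half-width uncertainty, reported as d ± u cm."""

    distance: float
    uncertainty: float
    threshold: float = 100.0
    boundary_label: str | None = None
    compliant_everywhere: bool = False
    extrapolated: bool = False

    def __str__(self) -> str:
        if self.compliant_everywhere:
            return f"compliant everywhere (index <= {self.threshold:g}% at all distances)"
        s = f"{self.distance:.0f} ± {self.uncertainty:.0f} cm"
        if self.boundary_label:
            s += f" ({self.boundary_label})"
        return s


def _profiled_fit(d: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Fit log I = log A - n log(d + d0); returns (logA, n, d0, rss).

    For fixed d0 the fit is linear in (log A, n); d0 is profiled out by a
    bounded scalar minimisation of the residual sum of squares, which is
    deterministic and finds the interpolating d0 exactly when 3 points are
    given.
    """

    def rss_at(u: float) -> float:
        x = np.log(d + np.exp(u))
        X = np.vstack([np.ones_like(x), x]).T
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    sol = minimize_scalar(
        rss_at,
        bounds=(np.log(_D0_BOUNDS[0]), np.log(_D0_BOUNDS[1])),
        method="bounded",
        options={"xatol": 1e-13},
    )
    d0 = float(np.exp(sol.x))
    x = np.log(d + d0)
    X = np.vstack([np.ones_like(x), x]).T
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[0]), float(-beta[1]), d0, rss_at(sol.x)


def fit_decay(profile: DistanceProfile) -> DecayFit:
    """Least-squares fit of the offset power law to a distance profile.

    The fit is unweighted in log space over all points.  With exactly three
    points the returned curve interpolates them (zero residual); degenerate
    profiles (non-decreasing indices) are rejected.
    """
    d = profile.distances
    I = profile.indices
    if len(d) < 3:
        raise ValueError("decay fit needs at least 3 points (three-parameter model)")
    if np.allclose(I, I[0], rtol=1e-12):
        raise ValueError("degenerate profile: all indices equal, no decay to fit")
    logA, n, d0, rss = _profiled_fit(d, np.log(I))
    if n <= 0:
        raise ValueError(f"fitted decay exponent non-positive (n={n:.3g}); profile does not decay")
    return DecayFit(
        A=float(np.exp(logA)),
        d0=d0,
        n=n,
        rms_log_residual=float(np.sqrt(rss / len(d))),
        n_points=len(d),
    )


def _crossing_of(points: Sequence[tuple[float, float]], threshold: float) -> float:
    prof = DistanceProfile(tuple(points))
    return fit_decay(prof).crossing(threshold)


def clearance_distance(
    fit: DecayFit,
    threshold: float = 100.0,
    profile: DistanceProfile | None = None,
) -> ClearanceResult:
    """Distance at which the fitted index falls to ``threshold`` percent.

    If the fitted index is at or below the threshold already at the gantry
    mouth (d = 0), the clearance is 0 with ``compliant_everywhere`` set —
    the whole room is on the compliant side.

    When the originating ``profile`` is supplied, an uncertainty half-width
    is attached: the half-range of leave-one-out refit crossings when the
    profile has at least 4 points, else the half-range of crossings under
    a ±5% perturbation of each index in turn (a convention of this package;
    the underlying survey reports ±3 cm without stating its recipe).  The
    result is flagged ``extrapolated`` when the crossing lies outside the
    sampled distance range.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    at_mouth = fit.index_at(0.0)
    if at_mouth <= threshold:
        return ClearanceResult(0.0, 0.0, threshold, compliant_everywhere=True)
    dist = fit.crossing(threshold)

    unc = 0.0
    extrapolated = False
    label = None
    if profile is not None:
        pts = list(profile.points)
        crossings: list[float] = []
        try:
            if fit.n_points >= 4:
                for k in range(len(pts)):
                    crossings.append(_crossing_of(pts[:k] + pts[k + 1 :], threshold))
            else:
                for k in range(len(pts)):
                    for eps in (-0.05, 0.05):
                        pert = list(pts)
                        pert[k] = (pert[k][0], pert[k][1] * (1 + eps))
                        crossings.append(_crossing_of(pert, threshold))
        except ValueError:
            crossings = []
        if crossings:
            unc = 0.5 * (max(crossings) - min(crossings))
        d = profile.distances
        extrapolated = not (d.min() <= dist <= d.max())
        label = BOUNDARY_LABELS.get(profile.curve_id)
    return ClearanceResult(
        distance=max(dist, 0.0),
        uncertainty=unc,
        threshold=threshold,
        boundary_label=label,
        extrapolated=extrapolated,
    )


def classify_zone(index_rl: float, index_lowal: float, index_highal: float) -> Zone:
    """EN 50499 zone of an assessment point from its three indices (%).

    Zone 0 if the general-public RL index is within 100%; else Zone 1a if
    the low-AL index is within 100%; else Zone 1b if the high-AL index is
    within 100%; else Zone 2.  Compliance is inclusive (index == 100 is
    compliant).  The indices should be ordered RL >= low AL >= high AL
    (limits are ordered the other way at every frequency); a violation is
    only warned about, since measurement noise can produce small inversions.
    """
    vals = (index_rl, index_lowal, index_highal)
    if any(v < 0 for v in vals):
        raise ValueError("indices must be non-negative")
    if not (index_rl >= index_lowal >= index_highal):
        _warnings.warn(
            "index ordering RL >= LowAL >= HighAL violated "
            f"({index_rl}, {index_lowal}, {index_highal}); measurement noise?",
            stacklevel=2,
        )
    if index_rl <= 100.0:
        return Zone.ZONE0
    if index_lowal <= 100.0:
        return Zone.ZONE1A
    if index_highal <= 100.0:
        return Zone.ZONE1B
    return Zone.ZONE2


def zone_boundary_map(
    profiles: Sequence[DistanceProfile],
    threshold: float = 100.0,
) -> list[tuple[str, ClearanceResult]]:
    """Zone boundary distances along the departure line.

    Takes the profiles of one measurement geometry against the RL, low-AL
    and high-AL curves (matching distances and height) and returns, for
    each curve whose index exceeds the threshold anywhere, the boundary
    label and fitted clearance, ordered outward-in (RL boundary farthest).
    """
    by_curve = {p.curve_id: p for p in profiles}
    ref = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.distances, ref.distances) or p.height != ref.height:
            raise ValueError("profiles must share distances and measurement height")

    results: list[tuple[str, ClearanceResult]] = []
    last = np.inf
    for cid in ("RL_B", "LOW_AL_B", "HIGH_AL_B"):
        if cid not in by_curve:
            continue
        prof = by_curve[cid]
        res = clearance_distance(fit_decay(prof), threshold, profile=prof)
        if res.compliant_everywhere:
            continue
        if res.distance > last + 1e-9:
            raise ValueError(
                f"zone boundaries out of order: {cid} crossing at {res.distance:.1f} cm "
                f"beyond the previous boundary at {last:.1f} cm"
            )
        last = res.distance
        results.append((BOUNDARY_LABELS[cid], res))
    return results
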