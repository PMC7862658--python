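"""Fluctuation-tolerant track smoothing.

Manual spot tracking jitters on the scale of a few µm; naive per-step speed
or angle statistics then quantify the tracker's hand rather than the cell.
The smoother treats every measured spot as the center of a ball of fixed
radius (default 10 µm) and seeks the path of smallest turning angles that
stays inside those balls.

The optimizer is a sequential midpoint relaxation: in each sweep every
interior point moves to the midpoint of its current neighbors and is then
clamped back onto the ball around its ORIGINAL measured position, so
smoothing error can never accumulate beyond the ball radius.  A sweep is
accepted only if it does not increase the total turning angle, which makes
the objective monotonically non-increasing by construction; this is a
deterministic, parameter-free approximation of the global minimal-angle
path, not a claim of global optimality.  Endpoints stay fixed by default so
endpoint-based statistics (e.g. net displacement along the organ axis) are
unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SmoothingConfig", "SmoothedTrack", "turning_angles", "smooth_track"]


@dataclass
class SmoothingConfig:
    """radius: ball radius in µm around each measured spot.
    iterations: number of relaxation sweeps (a fixed count, not a
        convergence criterion).
    endpoint_policy: 'fixed' pins the first/last spot to its measurement;
        'clamped' lets endpoints relax toward their neighbor within the
        ball.
    """

    radius: float = 10.0
    iterations: int = 30
    endpoint_policy: str = "fixed"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.endpoint_policy not in ("fixed", "clamped"):
            raise ValueError(f"unknown endpoint_policy {self.endpoint_policy!r}")


@dataclass
class SmoothedTrack:
    """Result of :func:`smooth_track`: original and smoothed positions
    (same shape, 2D or 3D), with per-point displacement."""

    times: np.ndarray
    original: np.ndarray
    smoothed: np.ndarray

    @property
    def displacement(self) -> np.ndarray:
        return np.linalg.norm(self.smoothed - self.original, axis=1)


def turning_angles(positions: np.ndarray) -> np.ndarray:
    """Angle at each interior point between successive displacement
    vectors, in ``[0, pi]``; zero-length segments contribute angle 0.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or len(pos) < 3:
        raise ValueError("need an (n >= 3, dim) array of positions")
    seg = np.diff(pos, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    a, b = seg[:-1], seg[1:]
    na, nb = norms[:-1], norms[1:]
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(denom > 0, (a * b).sum(axis=1) / denom, 1.0)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _total_turning(pos: np.ndarray) -> float:
    if len(pos) < 3:
        return 0.0
    return float(turning_angles(pos).sum())


def _clamp_to_ball(point: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    d = point - center
    dist = np.linalg.norm(d)
    if dist <= radius:
        return point
    return center + d * (radius / dist)


def smooth_track(
    times: np.ndarray,
    positions: np.ndarray,
    config: SmoothingConfig | None = None,
) -> SmoothedTrack:
    """Smooth one track (2D or 3D positions) under the ball constraint.

    Single-sample tracks are returned unchanged.  The total turning angle
    is non-increasing across sweeps; every smoothed point stays within
    ``config.radius`` of its original measured position; timestamps are
    untouched.
    """
    config = config or SmoothingConfig()
    times = np.asarray(times, dtype=float)
    original = np.asarray(positions, dtype=float)
    if original.ndim != 2:
        raise ValueError("positions must be (n, dim)")
    if len(times) != len(original):
        raise ValueError("times and positions length mismatch")
    n = len(original)
    if n < 3:
        return SmoothedTrack(times, original.copy(), original.copy())

    current = original.copy()
    total = _total_turning(current)
    for _ in range(config.iterations):
        proposal = current.copy()
        if config.endpoint_policy == "clamped":
            proposal[0] = _clamp_to_ball(proposal[1], original[0], config.radius)
        for i in range(1, n - 1):
            mid = 0.5 * (proposal[i - 1] + proposal[i + 1])
            proposal[i] = _clamp_to_ball(mid, original[i], config.radius)
        if config.endpoint_policy == "clamped":
            proposal[-1] = _clamp_to_ball(proposal[-2], original[-1], config.radius)
        new_total = _total_turning(proposal)
        if new_total > total + 1e-12:
            break  # clamping would start to fold the path; converged
        current = proposal
        total = new_total
    return SmoothedTrack(times, original.copy(), current)
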