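"""Central-axis estimation and cylindrical ("Mercator-style") unwrapping of 3D tracks.

Nascent myotubes migrate on the curved surface of the pupal testis, an
approximately prolate-ellipsoidal organ.  Planar directionality statistics
(biased angle, meandering distance, ...) assume Euclidean 2D geometry, so
3D+time trajectories recorded on the organ surface must first be unwrapped
into a plane.  The procedure implemented here:

1. estimate the organ's central axis from the pooled track point cloud and
   rigidly realign the cloud so the axis coincides with the x-axis
   (:func:`estimate_central_axis`);
2. compute, for every point, the central angle ``theta`` of its yz-position
   about the axis via three quadrant-specific arccos branches
   (:func:`central_angle`);
3. map ``theta`` to a new planar y-coordinate linearly, scaled by the
   dataset's maximal radius (:func:`mercator_y`);
4. compensate the x-coordinate for the locally smaller circumference at
   radii below the maximum (:func:`correct_x`).

The mapping is angle-preserving on a constant-radius tube (where it is an
isometry of the unrolled cylinder) and approximate elsewhere; it is not a
true Mercator projection (no logarithmic latitude stretch — the y-map is
linear in the central angle by design).

Angle convention
----------------
``theta`` lives in ``(-pi/2, 3*pi/2]``.  The seam of the unwrapping is the
``+z`` line above the axis; the line straight below the axis (``-z``) maps
to ``theta = pi/2`` and hence unwrapped ``y = 0``.  Internally the quadrant
branches consume the yz-vector *from the axis to the point*; see
:class:`RadialVector`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Point3D",
    "Track3D",
    "CentralAxis",
    "RadialVector",
    "ProjectionConfig",
    "AxisEstimationReport",
    "DegenerateGeometryError",
    "circumcenter_yz",
    "estimate_central_axis",
    "central_angle",
    "central_angle_wrapped",
    "mercator_y",
    "correct_x",
    "project_tracks",
]

THETA_LOW = -math.pi / 2.0
THETA_HIGH = 3.0 * math.pi / 2.0


class DegenerateGeometryError(ValueError):
    """Raised when geometry needed by the projection is degenerate."""


@dataclass(frozen=True)
class Point3D:
    """A position in µm."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x, self.y, self.z))):
            raise ValueError(f"non-finite coordinate in {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Track3D:
    """One cell's time-ordered 3D positions.

    ``samples`` is a list of ``(time_min, Point3D)`` with strictly
    increasing times.
    """

    track_id: str
    samples: list[tuple[float, Point3D]]

    def __post_init__(self) -> None:
        if len(self.samples) < 1:
            raise ValueError(f"track {self.track_id!r} has no samples")
        times = [t for t, _ in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"track {self.track_id!r}: times not strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.samples], dtype=float)

    @property
    def positions(self) -> np.ndarray:
        return np.array([[p.x, p.y, p.z] for _, p in self.samples], dtype=float)


@dataclass(frozen=True)
class CentralAxis:
    """The organ's central axis: a line in the original coordinate frame."""

    anchor: Point3D
    direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        norm = math.hypot(*self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction must be a unit vector, |d| = {norm}")


@dataclass(frozen=True)
class RadialVector:
    """The yz-vector between a point and the central axis.

    ``dy, dz`` are the components of the vector from the *axis* to the
    *point* (``dy = y_point - y_axis``).  The quadrant branches of
    :func:`central_angle` are phrased in terms of the point's position
    relative to the axis, so ``y_point < y_axis`` corresponds to
    ``dy < 0``.  The magnitude is the point's radius about the axis.
    """

    dy: float
    dz: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.dy, self.dz)


@dataclass
class ProjectionConfig:
    """Tunables of axis estimation and unwrapping.

    n_subsets: number of equal-count x-bins used to sample the axis.
    axis_iterations: how often estimate-and-realign is repeated.
    r_max_policy: 'dataset_max' uses the maximal radius over all points;
        'user_supplied' takes ``r_max_value`` (for cross-dataset work).
    equal_width_bins: bin by equal x-width instead of equal point count.
    """

    n_subsets: int = 10
    axis_iterations: int = 3
    r_max_policy: str = "dataset_max"
    r_max_value: float | None = None
    equal_width_bins: bool = False

    def __post_init__(self) -> None:
        if self.n_subsets < 2:
            raise ValueError("n_subsets must be >= 2")
        if self.axis_iterations < 1:
            raise ValueError("axis_iterations must be >= 1")
        if self.r_max_policy not in ("dataset_max", "user_supplied"):
            raise ValueError(f"unknown r_max_policy {self.r_max_policy!r}")
        if self.r_max_policy == "user_supplied" and not (
            self.r_max_value and self.r_max_value > 0
        ):
            raise ValueError("user_supplied r_max_policy needs r_max_value > 0")


@dataclass
class AxisEstimationReport:
    """Per-iteration diagnostics of the axis fit."""

    iterations: int
    residuals: list[float] = field(default_factory=list)  # mean |yz| of bin centers
    degenerate_bins: int = 0


def circumcenter_yz(
    p_a: Sequence[float], p_b: Sequence[float], p_c: Sequence[float], *, context: str = ""
) -> np.ndarray:
    """Circumcenter of three points in the yz-plane.

    Raises :class:`DegenerateGeometryError` for (near-)collinear input; the
    message names ``context`` (e.g. which x-subset) when given.
    """
    a = np.asarray(p_a, dtype=float)
    b = np.asarray(p_b, dtype=float)
    c = np.asarray(p_c, dtype=float)
    # 2x signed triangle area
    d = 2.0 * ((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
    scale = max(
        np.abs(b - a).max(), np.abs(c - a).max(), np.abs(c - b).max(), 1e-300
    )
    if abs(d) <= 1e-12 * scale * scale:
        where = f" in {context}" if context else ""
        raise DegenerateGeometryError(
            f"collinear points{where}: {tuple(a)}, {tuple(b)}, {tuple(c)}"
        )
    a2, b2, c2 = (a * a).sum(), (b * b).sum(), (c * c).sum()
    ux = (a2 * (b[1] - c[1]) + b2 * (c[1] - a[1]) + c2 * (a[1] - b[1])) / d
    uy = (a2 * (c[0] - b[0]) + b2 * (a[0] - c[0]) + c2 * (b[0] - a[0])) / d
    return np.array([ux, uy])


def _rotation_to_x(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the unit vector ``direction`` onto (1,0,0)."""
    d = direction / np.linalg.norm(direction)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(d, x)
    c = float(np.dot(d, x))
    s = np.linalg.norm(v)
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about z
        return np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def _bin_centers(points: np.ndarray, config: ProjectionConfig) -> tuple[np.ndarray, int]:
    """Axis sample points (x, y, z), one per x-bin, via circumcenter of the
    bin's extreme yz points (min-y, max-y, max-z).  Returns (centers,
    n_degenerate) where degenerate bins fell back to the bin yz-centroid.
    """
    order = np.argsort(points[:, 0], kind="stable")
    pts = points[order]
    n = len(pts)
    if config.equal_width_bins:
        edges = np.linspace(pts[0, 0], pts[-1, 0], config.n_subsets + 1)
        # right-inclusive last bin
        idx = np.clip(np.searchsorted(edges, pts[:, 0], side="right") - 1, 0, config.n_subsets - 1)
        groups = [pts[idx == i] for i in range(config.n_subsets)]
    else:
        groups = np.array_split(pts, config.n_subsets)
    centers = []
    n_degenerate = 0
    for i, g in enumerate(groups):
        if len(g) == 0:
            continue
        yz = g[:, 1:3]
        p_left = yz[np.argmin(yz[:, 0])]
        p_right = yz[np.argmax(yz[:, 0])]
        p_up = yz[np.argmax(yz[:, 1])]
        try:
            c = circumcenter_yz(p_left, p_right, p_up, context=f"x-subset {i}")
        except DegenerateGeometryError:
            c = yz.mean(axis=0)
            n_degenerate += 1
        centers.append([g[:, 0].mean(), c[0], c[1]])
    return np.asarray(centers), n_degenerate


def estimate_central_axis(
    points: np.ndarray | Sequence[Point3D], config: ProjectionConfig | None = None
) -> tuple[CentralAxis, np.ndarray, AxisEstimationReport]:
    """Estimate the organ's central axis and realign the cloud to it.

    Each iteration sorts the cloud by x, splits it into ``n_subsets``
    equal-count bins, approximates each bin's axis sample as the
    circumcenter of its extreme yz points, draws a straight line through
    the centroids ("points of gravity") of the first and last half of the
    bin samples, and rigidly moves the cloud so that line becomes the
    x-axis.  Repeated ``axis_iterations`` times.

    Returns ``(axis, aligned_points, report)`` with ``axis`` expressed in
    the ORIGINAL input frame and ``aligned_points`` in the realigned frame
    (axis = x-axis, i.e. y = z = 0).
    """
    config = config or ProjectionConfig()
    if len(points) and isinstance(points[0], Point3D):
        pts = np.array([[p.x, p.y, p.z] for p in points], dtype=float)
    else:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3 * config.n_subsets:
        raise ValueError(
            f"need at least {3 * config.n_subsets} points, got {len(pts)}"
        )
    x_span = pts[:, 0].max() - pts[:, 0].min()
    scene_span = max(np.ptp(pts, axis=0).max(), 1e-300)
    if x_span <= 1e-9 * scene_span:
        raise DegenerateGeometryError("all points lie in one x-plane; no axis")

    report = AxisEstimationReport(iterations=config.axis_iterations)
    # cumulative affine map p -> R_cum @ p + t_cum
    r_cum = np.eye(3)
    t_cum = np.zeros(3)
    aligned = pts.copy()
    for _ in range(config.axis_iterations):
        centers, n_deg = _bin_centers(aligned, config)
        report.degenerate_bins += n_deg
        half = len(centers) // 2
        g1 = centers[:half].mean(axis=0)
        g2 = centers[half:].mean(axis=0)
        d = g2 - g1
        if np.linalg.norm(d) < 1e-12:
            raise DegenerateGeometryError("axis endpoints coincide")
        rot = _rotation_to_x(d)
        # map axis line to y=z=0 while keeping the x-origin near g1.x
        shift = np.array([g1[0], 0.0, 0.0])
        aligned = (aligned - g1) @ rot.T + shift
        r_cum = rot @ r_cum
        t_cum = rot @ (t_cum - g1) + shift
        report.residuals.append(float(np.linalg.norm(_bin_centers(aligned, config)[0][:, 1:3], axis=1).mean()))

    # pull the aligned x-axis back to the original frame:
    # aligned = R p + t  =>  p = R^T (aligned - t)
    anchor = r_cum.T @ (np.zeros(3) - t_cum)
    direction = r_cum.T @ np.array([1.0, 0.0, 0.0])
    direction /= np.linalg.norm(direction)
    axis = CentralAxis(Point3D(*anchor), tuple(direction))
    return axis, aligned, report


def central_angle_wrapped(dy: np.ndarray, dz: np.ndarray) -> np.ndarray:
    """Single-formula central angle: ``-atan2(dz, dy)`` wrapped into
    ``(-pi/2, 3*pi/2]``.  Reference form for the quadrant branches of
    :func:`central_angle`; also used vectorised by the pipeline.
    """
    dy = np.asarray(dy, dtype=float)
    dz = np.asarray(dz, dtype=float)
    if np.any((dy == 0) & (dz == 0)):
        raise DegenerateGeometryError("point lies exactly on the central axis")
    theta = -np.arctan2(dz, dy)
    theta = np.where(theta <= THETA_LOW, theta + 2.0 * math.pi, theta)
    theta = np.where(theta > THETA_HIGH, theta - 2.0 * math.pi, theta)
    return theta


def central_angle(r: RadialVector, tie_policy: str = "default") -> float:
    """Central angle ``theta`` of a point about the axis, in radians.

    Three quadrant branches, phrased by the point's position relative to
    the axis (``dy = y_point - y_axis``, ``dz = z_point - z_axis``):

    - below the axis (``z_point < z_axis``):           ``theta = +arccos(dy/|r|)``
    - above, y beyond the axis (``y_point > y_axis``): ``theta = -arccos(dy/|r|)``
    - above, y short of the axis (``y_point < y_axis``): ``theta = 2*pi - arccos(dy/|r|)``

    Boundaries (``tie_policy='default'``): ``z_point == z_axis`` takes the
    below-axis branch; ``y_point == y_axis`` with ``z_point > z_axis`` (the
    seam, straight above the axis) takes the second branch and wraps to
    ``3*pi/2``.  The result always lies in ``(-pi/2, 3*pi/2]`` and equals
    :func:`central_angle_wrapped`.
    """
    if tie_policy != "default":
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    mag = r.magnitude
    if mag == 0.0:
        raise DegenerateGeometryError("point lies exactly on the central axis")
    cosang = min(1.0, max(-1.0, r.dy / mag))
    acos = math.acos(cosang)
    if r.dz < 0 or r.dz == 0:  # z_point <= z_axis
        theta = acos
    elif r.dy > 0:  # y_point > y_axis, z above
        theta = -acos
    else:  # y_point <= y_axis, z above (dy == 0 is the seam)
        theta = 2.0 * math.pi - acos
    # wrap the open boundary: exactly -pi/2 is represented as 3*pi/2
    if theta <= THETA_LOW:
        theta += 2.0 * math.pi
    elif theta > THETA_HIGH:
        theta -= 2.0 * math.pi
    return theta


def mercator_y(theta: np.ndarray | float, r_max: float) -> np.ndarray | float:
    """Unwrapped y-coordinate: ``((pi/2 - theta)/(pi/2)) * r_max * pi/2``.

    Linear in ``theta`` — arc length at the maximal radius.  ``theta =
    pi/2`` (straight below the axis) maps to ``y = 0``.
    """
    if r_max <= 0:
        raise ValueError("r_max must be > 0")
    return (math.pi / 2.0 - theta) / (math.pi / 2.0) * r_max * (math.pi / 2.0)


def correct_x(
    x1: np.ndarray,
    radii: np.ndarray,
    r_max: float,
    sort_keys: tuple[np.ndarray, ...] = (),
) -> np.ndarray:
    """Radius-compensated x-coordinates.

    All points (pooled across tracks and times) are sorted by raw ``x1``;
    the first keeps its coordinate, and each successive point advances by
    the raw x-increment scaled by ``r_max / r_n`` of the *current* point,
    compensating the smaller circumference at small radii.  ``sort_keys``
    (e.g. track id, time) break x-ties stably.  The result is returned in
    the input order.
    """
    x1 = np.asarray(x1, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise DegenerateGeometryError("zero or negative radius in x-correction")
    if r_max <= 0:
        raise ValueError("r_max must be > 0")
    order = np.lexsort(tuple(reversed(sort_keys)) + (x1,))
    xs = x1[order]
    rs = radii[order]
    increments = np.empty_like(xs)
    increments[0] = 0.0
    increments[1:] = np.diff(xs) * (r_max / rs[1:])
    x2_sorted = xs[0] + np.cumsum(increments)
    x2 = np.empty_like(x2_sorted)
    x2[order] = x2_sorted
    return x2


def project_tracks(
    tracks: Sequence[Track3D],
    config: ProjectionConfig | None = None,
    axis: CentralAxis | None = None,
) -> tuple[pd.DataFrame, CentralAxis, AxisEstimationReport | None]:
    """Unwrap 3D tracks into the plane.

    Full pipeline: axis estimation and realignment (skipped when a known
    ``axis`` is supplied), per-point radius and central angle, linear
    y-unwrapping with the dataset-wide maximal radius, and pooled
    x-correction.

    Returns ``(frame, axis, report)`` where ``frame`` has one row per spot
    with columns ``track_id, time_min, x_raw_um, x_corrected_um,
    y_unwrapped_um, theta_rad, radius_um`` in the input row order.
    """
    if not tracks:
        raise ValueError("no tracks to project")
    config = config or ProjectionConfig()
    track_ids = np.concatenate(
        [np.repeat(t.track_id, len(t.samples)) for t in tracks]
    )
    times = np.concatenate([t.times for t in tracks])
    pts = np.vstack([t.positions for t in tracks])

    report: AxisEstimationReport | None = None
    if axis is None:
        axis, aligned, report = estimate_central_axis(pts, config)
    else:
        d = np.asarray(axis.direction, dtype=float)
        anchor = axis.anchor.as_array()
        rot = _rotation_to_x(d)
        aligned = (pts - anchor) @ rot.T + np.array([anchor[0], 0.0, 0.0])

    dy = aligned[:, 1]
    dz = aligned[:, 2]
    radii = np.hypot(dy, dz)
    if np.any(radii == 0):
        raise DegenerateGeometryError("a point lies exactly on the central axis")
    theta = central_angle_wrapped(dy, dz)
    if config.r_max_policy == "user_supplied":
        r_max = float(config.r_max_value)  # validated in config
    else:
        r_max = float(radii.max())
    y_new = (math.pi / 2.0 - theta) * r_max
    # stable integer tie-keys for the pooled x-sort
    tid_codes = pd.factorize(track_ids)[0]
    x2 = correct_x(aligned[:, 0], radii, r_max, sort_keys=(tid_codes, times))
    frame = pd.DataFrame(
        {
            "track_id": track_ids,
            "time_min": times,
            "x_raw_um": aligned[:, 0],
            "x_corrected_um": x2,
            "y_unwrapped_um": y_new,
            "theta_rad": theta,
            "radius_um": radii,
        }
    )
    return frame, axis, report
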