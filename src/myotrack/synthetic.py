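"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study's data classes — 4D trajectories of cells
migrating on a tubular organ surface, star-shaped cells with filopodia
tips, cell-matrix adhesion event tables with an edge-class lifetime
asymmetry, and binary sheet masks with holes of scheduled size — while
recording the quantities the pipeline is supposed to recover (true axis,
unwrapped coordinates, drift speed and direction, lifetime ratio, hole
areas).  Everything is deterministic under a fixed seed.

Surface tracks are random walks in *parameter* space (axial coordinate,
azimuth), so generated points lie exactly on the surface by construction;
directional drift acts on the axial coordinate, then the scene is embedded
in 3D, rigidly transformed, and measurement noise is added.  Ground truth
is recorded pre-noise and pre-transform.

Default conditions mirror the study's imaging: frames every 5 min over a
7 h movie, drift along the organ axis of about 0.37 µm/min (roughly 130 µm
over the effective migration span), and a free-edge versus cell-cell-edge
adhesion lifetime ratio of 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CentralAxis, Point3D
from .metrics import AdhesionEvent, FilopodiaSet, SheetMask

__all__ = [
    "SurfaceTrackConfig",
    "GroundTruth",
    "generate_surface_tracks",
    "generate_surface_cloud",
    "HoleSpec",
    "generate_filopodia_cell",
    "generate_adhesion_events",
    "generate_sheet_masks",
]


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)


@dataclass
class SurfaceTrackConfig:
    """Conditions of the simulated 4D imaging experiment.

    surface: 'cylinder' (radius_um) or 'ellipsoid' (prolate; semi_axis_a_um
        along the organ axis, radius_um = equatorial semi-axis b = c).
    drift_speed_um_min: directional drift along the organ axis (apexward).
    angular_diffusion_rad2_min: variance rate of the azimuthal random walk.
    axial_diffusion_um2_min: variance rate of the axial random walk (on top
        of drift).
    noise_sd_um: isotropic 3D measurement noise on every spot.
    rotation_deg / rotation_axis / translation_um: rigid transform applied
        to the whole scene, emulating arbitrary mounting of the organ.
    """

    surface: str = "cylinder"
    radius_um: float = 40.0
    semi_axis_a_um: float = 150.0
    n_cells: int = 50
    duration_min: float = 420.0
    frame_interval_min: float = 5.0
    drift_speed_um_min: float = 0.37
    angular_diffusion_rad2_min: float = 1e-4
    axial_diffusion_um2_min: float = 0.05
    noise_sd_um: float = 2.0
    rotation_deg: float = 0.0
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    translation_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # cells occupy ~70% of the circumference, centered opposite the
    # unwrapping seam: wide enough that the per-bin extreme points form
    # proper triangles for axis estimation, while no track comes near the
    # seam.  azimuth 0 = the line straight below the axis.
    x_start_range_um: tuple[float, float] = (0.0, 60.0)
    azimuth_range_rad: tuple[float, float] = (-2.2, 2.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.surface not in ("cylinder", "ellipsoid"):
            raise ValueError(f"unknown surface {self.surface!r}")
        if self.radius_um <= 0 or self.semi_axis_a_um <= 0:
            raise ValueError("semi-axes must be > 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be > 0")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline should recover."""

    axis: CentralAxis
    unwrapped: pd.DataFrame  # track_id, time_min, x_true_um, y_true_um
    drift_speed_um_min: float
    drift_angle_deg: float  # angle of the true drift to the organ axis
    r_max_um: float


def _surface_radius(config: SurfaceTrackConfig, x: np.ndarray) -> np.ndarray:
    if config.surface == "cylinder":
        return np.full_like(x, config.radius_um, dtype=float)
    a, b = config.semi_axis_a_um, config.radius_um
    frac = np.clip(1.0 - (x / a) ** 2, 1e-6, None)
    return b * np.sqrt(frac)


def generate_surface_tracks(
    config: SurfaceTrackConfig | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate cells random-walking with axial drift on a tubular surface.

    Returns ``(tracks, truth)``: a tracks table with columns ``track_id,
    time_min, x_um, y_um, z_um`` (noisy, transformed — what an imaging
    export would contain) and the ground truth.  The embedding places the
    unwrapping seam on the ``+z`` line: azimuth 0 is the line straight
    below the axis, where the unwrapped y-coordinate is 0, and the true
    unwrapped y is ``radius * azimuth``.
    """
    config = config or SurfaceTrackConfig()
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration_min / config.frame_interval_min)) + 1
    dt = config.frame_interval_min
    times = np.arange(n_frames) * dt

    if config.surface == "ellipsoid":
        # keep tracks away from the poles, where the radius degenerates
        x0_lo = -0.5 * config.semi_axis_a_um
        x0_hi = -0.1 * config.semi_axis_a_um
    else:
        x0_lo, x0_hi = config.x_start_range_um
    x = rng.uniform(x0_lo, x0_hi, size=config.n_cells)
    psi = rng.uniform(*config.azimuth_range_rad, size=config.n_cells)

    ax_steps = rng.normal(
        config.drift_speed_um_min * dt,
        math.sqrt(config.axial_diffusion_um2_min * dt),
        size=(config.n_cells, n_frames - 1),
    )
    ang_steps = rng.normal(
        0.0,
        math.sqrt(config.angular_diffusion_rad2_min * dt),
        size=(config.n_cells, n_frames - 1),
    )
    xs = np.concatenate(
        [x[:, None], x[:, None] + np.cumsum(ax_steps, axis=1)], axis=1
    )
    psis = np.concatenate(
        [psi[:, None], psi[:, None] + np.cumsum(ang_steps, axis=1)], axis=1
    )
    if config.surface == "ellipsoid":
        xs = np.clip(xs, -0.95 * config.semi_axis_a_um, 0.95 * config.semi_axis_a_um)

    radii = _surface_radius(config, xs)
    # azimuth 0 points straight below the axis (-z); seam at +z
    y3 = radii * np.sin(psis)
    z3 = -radii * np.cos(psis)
    clean = np.stack([xs, y3, z3], axis=-1)  # (cells, frames, 3)

    rot = _rotation_matrix(
        np.asarray(config.rotation_axis), math.radians(config.rotation_deg)
    )
    trans = np.asarray(config.translation_um, dtype=float)
    noisy = clean @ rot.T + trans
    noisy = noisy + rng.normal(0.0, config.noise_sd_um, size=noisy.shape)

    cell_ids = np.repeat([f"cell{i}" for i in range(config.n_cells)], n_frames)
    t_col = np.tile(times, config.n_cells)
    tracks = pd.DataFrame(
        {
            "track_id": cell_ids,
            "time_min": t_col,
            "x_um": noisy[:, :, 0].ravel(),
            "y_um": noisy[:, :, 1].ravel(),
            "z_um": noisy[:, :, 2].ravel(),
        }
    )
    unwrapped = pd.DataFrame(
        {
            "track_id": cell_ids,
            "time_min": t_col,
            "x_true_um": xs.ravel(),
            "y_true_um": (radii * psis).ravel()
            if config.surface == "cylinder"
            else (config.radius_um * psis).ravel(),
        }
    )
    anchor = rot @ np.zeros(3) + trans
    direction = rot @ np.array([1.0, 0.0, 0.0])
    truth = GroundTruth(
        axis=CentralAxis(Point3D(*anchor), tuple(direction / np.linalg.norm(direction))),
        unwrapped=unwrapped,
        drift_speed_um_min=config.drift_speed_um_min,
        drift_angle_deg=0.0,
        r_max_um=float(radii.max()),
    )
    return tracks, truth


def generate_surface_cloud(
    surface: str = "cylinder",
    n_points: int = 2000,
    radius_um: float = 40.0,
    semi_axis_a_um: float = 150.0,
    x_range_um: tuple[float, float] = (0.0, 200.0),
    rotation_deg: float = 0.0,
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
    translation_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise_sd_um: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, CentralAxis]:
    """A static point cloud uniform over a tubular surface, rigidly
    transformed — the fixture for axis-recovery checks.  Returns
    ``(points, true_axis)`` with the axis in the transformed frame."""
    rng = np.random.default_rng(seed)
    psi = rng.uniform(-math.pi, math.pi, n_points)
    if surface == "cylinder":
        x = rng.uniform(*x_range_um, size=n_points)
        r = np.full(n_points, radius_um)
    elif surface == "ellipsoid":
        x = rng.uniform(-0.9 * semi_axis_a_um, 0.9 * semi_axis_a_um, n_points)
        r = radius_um * np.sqrt(1.0 - (x / semi_axis_a_um) ** 2)
    else:
        raise ValueError(f"unknown surface {surface!r}")
    pts = np.stack([x, r * np.sin(psi), -r * np.cos(psi)], axis=1)
    rot = _rotation_matrix(np.asarray(rotation_axis), math.radians(rotation_deg))
    trans = np.asarray(translation_um, dtype=float)
    pts = pts @ rot.T + trans
    if noise_sd_um > 0:
        pts = pts + rng.normal(0.0, noise_sd_um, size=pts.shape)
    direction = rot @ np.array([1.0, 0.0, 0.0])
    axis = CentralAxis(Point3D(*(rot @ np.zeros(3) + trans)), tuple(direction))
    return pts, axis


def generate_filopodia_cell(
    n_tips: int,
    front_edge_um: float = 20.0,
    rear_edge_um: float = 20.0,
    concentration: float = 0.0,
    mean_direction_deg: float = 0.0,
    tip_distance_um: float = 10.0,
    seed: int = 0,
) -> FilopodiaSet:
    """A star-shaped cell: tips at von-Mises-distributed bearings around
    the center of mass.  ``concentration`` 0 gives uniform bearings (no
    directional bias in filopodia assembly); large values concentrate tips
    around ``mean_direction_deg``."""
    if n_tips < 0:
        raise ValueError("n_tips must be >= 0")
    rng = np.random.default_rng(seed)
    if n_tips == 0:
        tips = np.empty((0, 2))
    else:
        ang = rng.vonmises(math.radians(mean_direction_deg), concentration, n_tips)
        dist = tip_distance_um * (0.75 + 0.5 * rng.random(n_tips))
        tips = np.stack([dist * np.cos(ang), dist * np.sin(ang)], axis=1)
    return FilopodiaSet(
        center_of_mass=np.zeros(2),
        tips=tips,
        front_edge_um=front_edge_um,
        rear_edge_um=rear_edge_um,
    )


def generate_adhesion_events(
    n_per_class: int = 1000,
    mean_lifetime_free_min: float = 10.0,
    mean_lifetime_cell_cell_min: float = 5.0,
    movie_length_min: float = 120.0,
    seed: int = 0,
) -> list[AdhesionEvent]:
    """Adhesion events with exponential lifetimes per edge class.

    Free-edge adhesions live on average twice as long as those at
    cell-cell edges under the defaults.  Births are uniform over the
    movie; an adhesion whose death falls beyond the movie end is censored
    at the end.
    """
    if mean_lifetime_free_min <= 0 or mean_lifetime_cell_cell_min <= 0:
        raise ValueError("mean lifetimes must be > 0")
    rng = np.random.default_rng(seed)
    events: list[AdhesionEvent] = []
    for cls, mean in (
        ("free_edge", mean_lifetime_free_min),
        ("cell_cell_edge", mean_lifetime_cell_cell_min),
    ):
        births = rng.uniform(0.0, movie_length_min, size=n_per_class)
        lifetimes = rng.exponential(mean, size=n_per_class)
        deaths = births + lifetimes
        for i, (b, d) in enumerate(zip(births, deaths)):
            censored = d > movie_length_min
            events.append(
                AdhesionEvent(
                    adhesion_id=f"{cls}_{i}",
                    birth_min=float(b),
                    death_min=float(min(d, movie_length_min)),
                    edge_class=cls,
                    censored=bool(censored),
                )
            )
    return events


@dataclass
class HoleSpec:
    """An axis-aligned rectangular hole: top-left pixel and pixel area
    (realized as the most-square rectangle of exactly that area)."""

    row: int
    col: int
    area_px: int


def _hole_shape(area_px: int) -> tuple[int, int]:
    best = (1, area_px)
    for h in range(1, int(math.isqrt(area_px)) + 1):
        if area_px % h == 0:
            best = (h, area_px // h)
    return best


def generate_sheet_masks(
    hole_schedule: list[list[HoleSpec]],
    shape: tuple[int, int] = (220, 120),
    pixel_size_um: float = 1.0,
    cell_count: int | None = 20,
) -> tuple[list[SheetMask], list[np.ndarray]]:
    """Rasterize a full foreground sheet with scheduled holes per frame.

    Returns ``(masks, true_areas)`` where ``true_areas[f]`` holds the
    realized hole areas (µm²) of frame ``f`` measured on the raster after
    carving, so overlapping holes appear merged with their true merged
    area.
    """
    from skimage.measure import label as _label

    masks: list[SheetMask] = []
    true_areas: list[np.ndarray] = []
    for frame in hole_schedule:
        raster = np.ones(shape, dtype=bool)
        for hole in frame:
            if hole.area_px < 0:
                raise ValueError("hole areas must be >= 0")
            if hole.area_px == 0:
                continue
            h, w = _hole_shape(hole.area_px)
            r0, c0 = hole.row, hole.col
            if r0 < 1 or c0 < 1 or r0 + h >= shape[0] or c0 + w >= shape[1]:
                raise ValueError("hole touches the raster border")
            raster[r0 : r0 + h, c0 : c0 + w] = False
        labeled = _label(~raster, connectivity=2)
        ids, counts = np.unique(labeled[labeled != 0], return_counts=True)
        true_areas.append(counts * pixel_size_um**2)
        masks.append(
            SheetMask(mask=raster, pixel_size_um=pixel_size_um, cell_count=cell_count)
        )
    return masks, true_areas
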