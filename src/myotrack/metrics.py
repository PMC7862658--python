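"""Collective-migration statistics for tracks, filopodia, adhesions and masks.

All functions emit plain numbers or tidy tables (one row per track / cell /
event / frame) so downstream statistical testing can happen in any external
tool.  Conventions:

- the organ's long axis is the x-axis (base at small x, apex/tip at large x
  after projection; in oriented still images the tip points left, i.e. the
  "front" of a cell is the side with the *smaller* axis coordinate);
- distances in µm, times in minutes, angles in degrees at this API surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage.measure import label
from skimage.segmentation import clear_border

from .geometry import Track3D

__all__ = [
    "NeighborSnapshot",
    "FilopodiaSet",
    "AdhesionEvent",
    "SheetMask",
    "MeanderResult",
    "distance_on_x",
    "neighbor_permanency",
    "biased_angle",
    "meandering_distance",
    "track_speed_mean",
    "filopodia_orientation",
    "filopodia_density",
    "adhesion_lifetimes",
    "sheet_mask_metrics",
    "gap_areas",
    "gap_sizes_over_time",
    "contact_distance",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class NeighborSnapshot:
    """Cell positions at the start and end of observation.

    ``positions_t0`` and ``positions_t1`` are (n_cells, dim) arrays in µm,
    row i being the same cell at both times.  ``k`` is the neighborhood
    size (six nearest cells by default).
    """

    positions_t0: np.ndarray
    positions_t1: np.ndarray
    k: int = 6

    def __post_init__(self) -> None:
        self.positions_t0 = np.asarray(self.positions_t0, dtype=float)
        self.positions_t1 = np.asarray(self.positions_t1, dtype=float)
        if self.positions_t0.shape != self.positions_t1.shape:
            raise ValueError("t0/t1 position arrays must have the same shape")
        if len(self.positions_t0) < self.k + 1:
            raise ValueError(
                f"need at least k+1 = {self.k + 1} cells, got {len(self.positions_t0)}"
            )


@dataclass
class FilopodiaSet:
    """Filopodia tip coordinates of one cell.

    ``center_of_mass``: (2,) µm; ``tips``: (n, 2) µm; ``front_edge_um`` /
    ``rear_edge_um``: membrane lengths of the front (toward the organ tip,
    smaller x in oriented images) and rear cell edge.
    """

    center_of_mass: np.ndarray
    tips: np.ndarray
    front_edge_um: float | None = None
    rear_edge_um: float | None = None

    def __post_init__(self) -> None:
        self.center_of_mass = np.asarray(self.center_of_mass, dtype=float).reshape(2)
        self.tips = np.asarray(self.tips, dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class AdhesionEvent:
    """One cell-matrix adhesion's observed life span.

    ``edge_class`` is ``'free_edge'`` or ``'cell_cell_edge'``; ``censored``
    marks adhesions still alive when the movie ended (their ``death_min``
    is the movie end, not a real death).
    """

    adhesion_id: str
    birth_min: float
    death_min: float
    edge_class: str
    censored: bool = False

    def __post_init__(self) -> None:
        if self.death_min < self.birth_min:
            raise ValueError(
                f"adhesion {self.adhesion_id!r}: death before birth"
            )
        if self.edge_class not in ("free_edge", "cell_cell_edge"):
            raise ValueError(f"unknown edge_class {self.edge_class!r}")


@dataclass
class SheetMask:
    """Binary raster of a cell sheet (foreground = cells) with physical
    pixel size.  ``cell_count`` is supplied by the user (counted manually
    in the original workflow) and only needed for area-per-cell."""

    mask: np.ndarray
    pixel_size_um: float
    cell_count: int | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1, True, False))):
            raise ValueError("mask must be binary (0/1); binarize on read")
        self.mask = self.mask.astype(bool)


@dataclass
class MeanderResult:
    """Meandering distances at spot, track and dataset granularity."""

    variant: str
    per_spot: pd.DataFrame  # track_id, time_min, d2_um
    per_track_median: pd.Series  # index track_id
    dataset_median: float  # median over pooled per-spot values


# ---------------------------------------------------------------------------
# track statistics


def distance_on_x(track: "Track3D | np.ndarray") -> float:
    """Net displacement along the organ axis: x(last) - x(first), signed.

    Computed on raw (unprojected, unsmoothed) data; only the endpoints
    enter, so it is insensitive to tracking jitter in between.
    """
    if isinstance(track, Track3D):
        xs = track.positions[:, 0]
    else:
        xs = np.asarray(track, dtype=float)
        if xs.ndim > 1:
            xs = xs[:, 0]
    if len(xs) < 2:
        raise ValueError("distance on x needs at least two samples")
    return float(xs[-1] - xs[0])


def _knn_sets(positions: np.ndarray, k: int) -> list[set[int]]:
    d = cdist(positions, positions)
    np.fill_diagonal(d, np.inf)
    # stable argsort makes distance ties deterministic (lowest index wins)
    order = np.argsort(d, axis=1, kind="stable")
    return [set(order[i, :k].tolist()) for i in range(len(positions))]


def neighbor_permanency(snapshot: NeighborSnapshot) -> np.ndarray:
    """Per cell, the fraction of its k nearest neighbors at t0 that are
    again among its k nearest at the end of observation.  1 means all
    neighbors were kept (fully cohesive sheet); rigid motion of the whole
    field gives 1 everywhere.
    """
    k = snapshot.k
    nn0 = _knn_sets(snapshot.positions_t0, k)
    nn1 = _knn_sets(snapshot.positions_t1, k)
    return np.array([len(a & b) / k for a, b in zip(nn0, nn1)])


def biased_angle(positions: np.ndarray) -> float:
    """Mean per-step unsigned angle (degrees, 0-180) between a track's
    displacement and the +x axis.

    Low values mean migration directed along the organ axis.  Zero-length
    steps are skipped; a track with only zero-length steps has no defined
    angle and returns NaN.  Comparable only across cells of similar net
    displacement, since slow cells' angles are jitter-dominated — smooth
    first.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or len(pos) < 2:
        raise ValueError("need at least two 2D samples")
    steps = np.diff(pos, axis=0)
    norms = np.linalg.norm(steps, axis=1)
    keep = norms > 0
    if not keep.any():
        return float("nan")
    cosang = np.clip(steps[keep, 0] / norms[keep], -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)).mean())


def meandering_distance(
    frame: pd.DataFrame,
    r_max: float | None = None,
    variant: str = "literal",
) -> MeanderResult:
    """Radius-scaled deviation of each track from its mean line.

    ``frame`` is a projected-track table with columns ``track_id``,
    ``time_min``, ``x_corrected_um``, ``y_unwrapped_um``, ``radius_um``.
    Per spot, the deviation ``|d1|`` is scaled by ``|r_n| / |r_max|`` to
    down-weight spots measured near the axis, where the unwrapping
    stretches the surface the most:

    - ``variant='literal'``: ``|d1| = |y_n - y_mean_per_track|`` (the
      x-component of the defining formula is identically zero);
    - ``variant='x_mean'``: ``|d1| = hypot(x_n - x_mean, y_n - y_mean)``.

    Returns medians per track and the median over pooled per-spot values.
    """
    if variant not in ("literal", "x_mean"):
        raise ValueError(f"unknown variant {variant!r}")
    required = {"track_id", "time_min", "y_unwrapped_um", "radius_um"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"frame lacks columns {sorted(missing)}")
    if frame["radius_um"].isna().any():
        raise ValueError("every spot needs a radius for meandering distance")
    if r_max is None:
        r_max = float(frame["radius_um"].max())
    if r_max <= 0:
        raise ValueError("r_max must be > 0")

    g = frame.groupby("track_id", sort=False)
    dy = frame["y_unwrapped_um"] - g["y_unwrapped_um"].transform("mean")
    if variant == "literal":
        d1 = dy.abs()
    else:
        dx = frame["x_corrected_um"] - g["x_corrected_um"].transform("mean")
        d1 = np.hypot(dx, dy)
    d2 = d1 * (frame["radius_um"] / r_max)
    per_spot = pd.DataFrame(
        {
            "track_id": frame["track_id"],
            "time_min": frame["time_min"],
            "d2_um": d2,
        }
    )
    per_track = per_spot.groupby("track_id", sort=False)["d2_um"].median()
    return MeanderResult(
        variant=variant,
        per_spot=per_spot,
        per_track_median=per_track,
        dataset_median=float(per_spot["d2_um"].median()),
    )


def track_speed_mean(times: np.ndarray, positions: np.ndarray) -> float:
    """Total path length over total elapsed time, in µm/min.

    Meant to run on smoothed positions; on raw manual-tracking data it
    largely measures click jitter.
    """
    times = np.asarray(times, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two samples")
    elapsed = times[-1] - times[0]
    if elapsed <= 0:
        raise ValueError("zero elapsed time")
    path = float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())
    return path / elapsed


def contact_distance(track_a: pd.DataFrame, track_b: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between two cells at each shared timepoint.

    Inputs are per-track tables with columns ``time_min, x_um, y_um``.
    """
    cols = ["time_min", "x_um", "y_um"]
    for name, t in (("a", track_a), ("b", track_b)):
        if not set(cols) <= set(t.columns):
            raise ValueError(f"track {name} lacks columns {cols}")
    merged = pd.merge(
        track_a[cols], track_b[cols], on="time_min", suffixes=("_a", "_b")
    )
    if merged.empty:
        raise ValueError("tracks share no timepoints")
    d = np.hypot(
        merged["x_um_a"] - merged["x_um_b"], merged["y_um_a"] - merged["y_um_b"]
    )
    return pd.DataFrame({"time_min": merged["time_min"], "distance_um": d})


# ---------------------------------------------------------------------------
# filopodia


def filopodia_orientation(
    fset: FilopodiaSet, n_bins: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tip bearing of (tip - center of mass), degrees in [0, 360)
    counter-clockwise from +x, plus binned counts for rose plots
    (``n_bins`` equal bins starting at 0°).  Tips coincident with the
    center have no bearing and are skipped.
    """
    if len(fset.tips) < 1:
        raise ValueError("need at least one filopodia tip")
    vec = fset.tips - fset.center_of_mass
    keep = np.linalg.norm(vec, axis=1) > 0
    angles = np.degrees(np.arctan2(vec[keep, 1], vec[keep, 0])) % 360.0
    # nudge off floating-point fuzz so bearings that are whole degrees do
    # not straddle bin edges
    angles = np.round(angles, 9) % 360.0
    counts, _ = np.histogram(angles, bins=n_bins, range=(0.0, 360.0))
    return angles, counts


def filopodia_density(fset: FilopodiaSet) -> tuple[float, float]:
    """Filopodia per µm membrane at the front vs the rear cell edge.

    Tips are partitioned by their x-coordinate relative to the center of
    mass under the oriented-image convention (organ tip pointing left):
    front = x strictly below the center's, ties go to the rear.
    """
    if not fset.front_edge_um or not fset.rear_edge_um:
        raise ValueError("front and rear edge lengths must be > 0")
    if fset.front_edge_um <= 0 or fset.rear_edge_um <= 0:
        raise ValueError("front and rear edge lengths must be > 0")
    front = int((fset.tips[:, 0] < fset.center_of_mass[0]).sum())
    rear = len(fset.tips) - front
    return front / fset.front_edge_um, rear / fset.rear_edge_um


# ---------------------------------------------------------------------------
# adhesions


def adhesion_lifetimes(
    events: "list[AdhesionEvent] | pd.DataFrame",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adhesion lifetimes grouped by edge class.

    Lifetime = death - birth for uncensored events; censored events are
    excluded from the lifetime table and tallied separately.  Returns
    ``(lifetimes, summary)``: a tidy per-event table and per-class
    ``n / n_censored / median / mean`` summaries.
    """
    if isinstance(events, pd.DataFrame):
        df = events.copy()
        required = {"adhesion_id", "birth_min", "death_min", "edge_class"}
        if not required <= set(df.columns):
            raise ValueError(f"events table lacks columns {sorted(required)}")
        if "censored" not in df.columns:
            df["censored"] = False
    else:
        if not events:
            raise ValueError("no adhesion events")
        df = pd.DataFrame(
            {
                "adhesion_id": [e.adhesion_id for e in events],
                "birth_min": [e.birth_min for e in events],
                "death_min": [e.death_min for e in events],
                "edge_class": [e.edge_class for e in events],
                "censored": [e.censored for e in events],
            }
        )
    if df.empty:
        raise ValueError("no adhesion events")
    if (df["death_min"] < df["birth_min"]).any():
        bad = df.loc[df["death_min"] < df["birth_min"], "adhesion_id"].iloc[0]
        raise ValueError(f"adhesion {bad!r}: death before birth")

    alive = df.loc[~df["censored"].astype(bool)].copy()
    alive["lifetime_min"] = alive["death_min"] - alive["birth_min"]
    lifetimes = alive[["adhesion_id", "edge_class", "lifetime_min"]].reset_index(
        drop=True
    )
    rows = []
    for cls, grp in df.groupby("edge_class", sort=True):
        life = lifetimes.loc[lifetimes["edge_class"] == cls, "lifetime_min"]
        rows.append(
            {
                "edge_class": cls,
                "n": int(len(life)),
                "n_censored": int(grp["censored"].astype(bool).sum()),
                "median_min": float(life.median()) if len(life) else float("nan"),
                "mean_min": float(life.mean()) if len(life) else float("nan"),
            }
        )
    return lifetimes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sheet masks


def _crack_perimeter(component: np.ndarray) -> int:
    """Boundary edge count of a binary blob (crack length in pixel edges).

    Every pixel edge between an inside and an outside pixel (image border
    counts as outside) contributes 1; a 5x5 square yields 20.
    """
    padded = np.pad(component.astype(np.int8), 1)
    edges = 0
    for axis in (0, 1):
        edges += int(np.abs(np.diff(padded, axis=axis)).sum())
    return edges


def _gap_components(mask: SheetMask) -> tuple[np.ndarray, int]:
    """Label the gaps: connected components (8-connectivity) of the
    inverted foreground that lie fully inside the raster (components
    touching the border are background outside the sheet, not gaps)."""
    gaps = ~mask.mask
    labeled = label(gaps, connectivity=2)
    labeled = clear_border(labeled)
    ids = np.unique(labeled)
    ids = ids[ids != 0]
    return labeled, len(ids)


def sheet_mask_metrics(mask: SheetMask) -> dict[str, float]:
    """Cohesion metrics of a binarized cell-sheet still.

    - ``gap_count``: number of holes, i.e. connected components of the
      inverted image fully inside the raster;
    - ``free_edge_um``: summed crack-length perimeters of those holes
      times the pixel size — the length of black-to-white border, which
      is the cell-free edge;
    - ``area_per_cell_um2``: total foreground area divided by the
      user-supplied cell count (NaN when no count was given).
    """
    labeled, n = _gap_components(mask)
    perim_px = sum(
        _crack_perimeter(labeled == lab) for lab in np.unique(labeled) if lab != 0
    )
    area_px = int(mask.mask.sum())
    area_um2 = area_px * mask.pixel_size_um**2
    per_cell = (
        area_um2 / mask.cell_count if mask.cell_count else float("nan")
    )
    return {
        "gap_count": float(n),
        "free_edge_um": perim_px * mask.pixel_size_um,
        "area_per_cell_um2": per_cell,
    }


def gap_areas(mask: SheetMask) -> np.ndarray:
    """Areas (µm²) of the individual gaps in one mask."""
    labeled, _ = _gap_components(mask)
    ids, counts = np.unique(labeled[labeled != 0], return_counts=True)
    return counts * mask.pixel_size_um**2


def gap_sizes_over_time(
    masks: "list[SheetMask]", min_area_um2: float = 20.0
) -> pd.DataFrame:
    """Per-frame total area of gaps strictly larger than ``min_area_um2``
    (default 20 µm²; smaller holes are treated as noise and ignored)."""
    if not masks:
        raise ValueError("no masks")
    px = masks[0].pixel_size_um
    if any(m.pixel_size_um != px for m in masks):
        raise ValueError("pixel size must be uniform across frames")
    rows = []
    for i, m in enumerate(masks):
        areas = gap_areas(m)
        big = areas[areas > min_area_um2]
        rows.append(
            {
                "frame": i,
                "n_gaps": int(len(big)),
                "total_gap_area_um2": float(big.sum()),
            }
        )
    return pd.DataFrame(rows)
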