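"""Agent-based model of filopodia-driven, contact-stimulated migration.

A simulated cell is not a single agent: it is a set of *protrusion points*
(filopodia tips).  The cell's position is the centroid of its members, so
the cell never stores a direction — all motion is emergent from protrusion
dynamics:

- protrusion points elongate radially away from the centroid at a fixed
  speed, depositing immobile *matrix adhesions* along the way;
- elongation is opposed by membrane resistance, which grows with distance
  from the centroid; the live adhesions of a filopodium provide static
  friction that counters it.  When resistance exceeds friction, the whole
  filopodium (point plus adhesions) is dragged back toward the centroid;
- protrusion points and adhesions have finite lifetimes;
- new protrusion points appear on a circle of fixed radius around the
  centroid ("gray circle", the adhesion radius) at the bearing where the
  local member density is lowest — there is no intrinsic asymmetry in
  where filopodia form;
- when a protrusion point touches another cell's gray circle, the contact
  rule fires.  In the default mode it loses its matrix adhesions (its grip
  on the matrix) and becomes a *shared adhesion*, a cell-cell junction
  counted in BOTH cells' centroids.  In the ``remove_point`` variant the
  protrusion simply vanishes with its adhesions, which turns the
  contact-stimulated cohesive behavior into dispersal very reminiscent of
  contact inhibition of locomotion (CIL).

A single cell therefore jiggles without net direction; in a confined
cluster, cells keep their matrix grip only on free-space-facing filopodia,
which breaks symmetry toward the free space and moves the cluster
collectively — the asymmetry lives in cell-matrix adhesion lifetime, not
in any directional parameter.  Filopodia pressed against an arena wall
cannot gain ground, deposit no further adhesions and lose their grip, so
walls are passively non-adhesive rather than explicitly repulsive.

No numeric parameter here is a measured quantity; defaults are chosen so a
single cell's protrusion turnover looks filopodia-like (protrusion
lifetime a few times the adhesion lifetime, spawn radius twice the
membrane rest distance, filopodia reaching roughly 1.5x the spawn radius)
and neighboring cells sit a little further apart than two contact radii,
so contacts occur at extended filopodia tips.  Every run is fully
determined by ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProtrusionPoint",
    "MatrixAdhesion",
    "SharedAdhesion",
    "Cell",
    "SimConfig",
    "SimState",
    "centroid",
    "largest_gap_bearing",
    "spawn_protrusion",
    "step",
    "run_simulation",
]


@dataclass
class ProtrusionPoint:
    pid: int
    x: float
    y: float
    owner: int
    age: int = 0
    adhesion_ids: list[int] = field(default_factory=list)
    outward_travel: float = 0.0  # µm gained since the last adhesion deposit

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class MatrixAdhesion:
    aid: int
    x: float
    y: float
    owner_pid: int
    age: int = 0

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class SharedAdhesion:
    sid: int
    x: float
    y: float
    owners: tuple[int, int]  # exactly two distinct cells
    age: int = 0

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class Cell:
    cid: int
    protrusion_ids: list[int] = field(default_factory=list)
    shared_ids: list[int] = field(default_factory=list)
    alive: bool = True


@dataclass
class SimConfig:
    """All lengths in µm, durations in steps; see the module docstring.

    arena: (xmin, xmax, ymin, ymax), the confined strip mimicking the
        unfolded organ surface.
    d_spawn: gray-circle radius — both the spawn distance of new
        protrusion points and the contact (adhesion) radius of a cell.
    elongation_speed: outward filopodium growth per step.
    resistance_k / rest_distance: membrane resistance
        ``R = k * max(0, d - d0) ** resistance_exponent``.
    friction_mu: static friction per live matrix adhesion of a filopodium.
    retraction_gain: fraction of the unbalanced force (R - F) converted to
        inward displacement per step when resistance wins.
    deposit_spacing: outward travel between successive adhesion deposits.
    contact_mode: 'lose_matrix_keep_point' (a cell-cell junction forms) or
        'remove_point' (the CIL-like variant).
    cluster_origin/cluster_extent: the box in which cells are seeded
        (default: the left arena end, spanning most of the strip height).
    """

    arena: tuple[float, float, float, float] = (0.0, 300.0, 0.0, 36.0)
    n_cells: int = 8
    target_protrusions: int = 12
    d_spawn: float = 6.0
    elongation_speed: float = 0.5
    resistance_k: float = 0.2
    rest_distance: float = 3.0
    resistance_exponent: float = 1.0
    friction_mu: float = 0.2
    retraction_gain: float = 0.5
    deposit_spacing: float = 1.0
    protrusion_lifetime: int = 60
    adhesion_lifetime: int = 20
    shared_lifetime: int = 60
    contact_mode: str = "lose_matrix_keep_point"
    n_steps: int = 1000
    seed: int = 0
    cluster_origin: tuple[float, float] | None = None
    cluster_extent: tuple[float, float] = (40.0, 30.0)

    def __post_init__(self) -> None:
        xmin, xmax, ymin, ymax = self.arena
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("degenerate arena")
        for name in (
            "d_spawn",
            "elongation_speed",
            "resistance_k",
            "rest_distance",
            "friction_mu",
            "retraction_gain",
            "deposit_spacing",
            "protrusion_lifetime",
            "adhesion_lifetime",
            "shared_lifetime",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.contact_mode not in ("lose_matrix_keep_point", "remove_point"):
            raise ValueError(f"unknown contact_mode {self.contact_mode!r}")


@dataclass
class SimState:
    step_index: int
    cells: dict[int, Cell]
    protrusions: dict[int, ProtrusionPoint]
    adhesions: dict[int, MatrixAdhesion]
    shared: dict[int, SharedAdhesion]
    rng: np.random.Generator
    next_id: int = 0
    events: list[dict] = field(default_factory=list)
    # one junction per cell pair: repeated contacts reinforce (refresh) it
    pair_junctions: dict[tuple[int, int], int] = field(default_factory=dict)

    def new_id(self) -> int:
        self.next_id += 1
        return self.next_id


def _centroid_xy(cell: Cell, state: SimState) -> tuple[float, float]:
    sx = sy = 0.0
    n = 0
    for pid in cell.protrusion_ids:
        pp = state.protrusions[pid]
        sx += pp.x
        sy += pp.y
        n += 1
    for sid in cell.shared_ids:
        sa = state.shared[sid]
        sx += sa.x
        sy += sa.y
        n += 1
    if n == 0:
        raise ValueError(f"cell {cell.cid} has no members")
    return sx / n, sy / n


def centroid(cell: Cell, state: SimState) -> np.ndarray:
    """Arithmetic mean of the cell's protrusion-point and shared-adhesion
    positions — the cell's perceived position."""
    return np.array(_centroid_xy(cell, state))


def largest_gap_bearing(bearings: np.ndarray) -> float:
    """Midpoint bearing (radians, in [0, 2*pi)) of the largest angular gap
    between the given bearings; ties broken toward the smallest resulting
    bearing.  With a single bearing the gap is the full circle and the
    spawn points opposite."""
    b = np.sort(np.asarray(bearings, dtype=float) % (2.0 * math.pi))
    if len(b) == 0:
        raise ValueError("no bearings")
    if len(b) == 1:
        return float((b[0] + math.pi) % (2.0 * math.pi))
    gaps = np.diff(b)
    wrap = 2.0 * math.pi - b[-1] + b[0]
    all_gaps = np.concatenate([gaps, [wrap]])
    max_gap = all_gaps.max()
    mids = []
    for i in np.flatnonzero(all_gaps >= max_gap - 1e-12):
        mids.append((b[i] + all_gaps[i] / 2.0) % (2.0 * math.pi))
    return float(min(mids))


def _member_bearings(cell: Cell, state: SimState, cx: float, cy: float) -> list[float]:
    out = []
    for pid in cell.protrusion_ids:
        pp = state.protrusions[pid]
        if pp.x != cx or pp.y != cy:
            out.append(math.atan2(pp.y - cy, pp.x - cx) % (2.0 * math.pi))
    for sid in cell.shared_ids:
        sa = state.shared[sid]
        if sa.x != cx or sa.y != cy:
            out.append(math.atan2(sa.y - cy, sa.x - cx) % (2.0 * math.pi))
    return out


def _gap_candidates(bearings: np.ndarray) -> list[float]:
    """Midpoints of all angular gaps, widest gap first; ties broken toward
    the smaller bearing (the first candidate equals
    :func:`largest_gap_bearing`)."""
    b = np.sort(np.asarray(bearings, dtype=float) % (2.0 * math.pi))
    if len(b) == 1:
        return [float((b[0] + math.pi) % (2.0 * math.pi))]
    gaps = np.concatenate([np.diff(b), [2.0 * math.pi - b[-1] + b[0]]])
    mids = (b + gaps / 2.0) % (2.0 * math.pi)
    order = sorted(range(len(b)), key=lambda i: (-gaps[i], mids[i]))
    return [float(mids[i]) for i in order]


def spawn_protrusion(
    cell: Cell,
    state: SimState,
    config: SimConfig,
    foreign_centroids: "list[tuple[float, float]] | None" = None,
) -> ProtrusionPoint | None:
    """Create one protrusion point on the gray circle around the cell's
    centroid, at the bearing of lowest local member density (midpoint of
    the largest angular gap, ties toward the smaller bearing); with no
    usable member bearings the angle is drawn uniformly from the
    simulation RNG.

    Membrane facing a touching neighbor is already engaged in cell-cell
    contact, so bearings whose spawn position would fall inside a foreign
    gray circle are skipped in favor of the next-widest gap; a fully
    surrounded cell spawns nothing (returns None).
    """
    cx, cy = _centroid_xy(cell, state)  # raises for memberless (dead) cells
    bearings = _member_bearings(cell, state, cx, cy)
    if not bearings:
        candidates = [
            float(state.rng.uniform(0.0, 2.0 * math.pi)) for _ in range(8)
        ]
    else:
        candidates = _gap_candidates(np.asarray(bearings))
    angle = None
    for cand in candidates:
        px = cx + config.d_spawn * math.cos(cand)
        py = cy + config.d_spawn * math.sin(cand)
        blocked = False
        for fx, fy in foreign_centroids or ():
            if math.hypot(px - fx, py - fy) <= config.d_spawn:
                blocked = True
                break
        if not blocked:
            angle = cand
            break
    if angle is None:
        return None
    pp = ProtrusionPoint(
        pid=state.new_id(),
        x=cx + config.d_spawn * math.cos(angle),
        y=cy + config.d_spawn * math.sin(angle),
        owner=cell.cid,
    )
    state.protrusions[pp.pid] = pp
    cell.protrusion_ids.append(pp.pid)
    state.events.append(
        {"step": state.step_index, "event": "spawn", "cell": cell.cid, "id": pp.pid}
    )
    return pp


def _remove_protrusion(state: SimState, pp: ProtrusionPoint) -> None:
    for aid in pp.adhesion_ids:
        state.adhesions.pop(aid, None)
    pp.adhesion_ids.clear()
    state.protrusions.pop(pp.pid, None)
    owner = state.cells[pp.owner]
    if pp.pid in owner.protrusion_ids:
        owner.protrusion_ids.remove(pp.pid)


def _kill_if_empty(state: SimState, cell: Cell) -> None:
    if cell.alive and not cell.protrusion_ids and not cell.shared_ids:
        cell.alive = False
        state.events.append(
            {"step": state.step_index, "event": "death", "cell": cell.cid, "id": -1}
        )


def step(state: SimState, config: SimConfig) -> SimState:
    """Advance the simulation by one synchronous step (in place).

    Sub-phase order (it matters for trajectories and is therefore fixed):
    cull expired members -> move filopodia against start-of-step centroids
    -> contact rule -> spawn to target count -> clamp to arena.  The
    movement and contact phases both see the centroids from the start of
    the step; centroids are recomputed before spawning.
    """
    state.step_index += 1
    xmin, xmax, ymin, ymax = config.arena

    # (1) age and cull
    for pp in list(state.protrusions.values()):
        pp.age += 1
        if pp.age > config.protrusion_lifetime:
            _remove_protrusion(state, pp)
    for ad in list(state.adhesions.values()):
        ad.age += 1
        if ad.age > config.adhesion_lifetime:
            owner = state.protrusions.get(ad.owner_pid)
            if owner is not None and ad.aid in owner.adhesion_ids:
                owner.adhesion_ids.remove(ad.aid)
            del state.adhesions[ad.aid]
    for sa in list(state.shared.values()):
        sa.age += 1
        if sa.age > config.shared_lifetime:
            for cid in sa.owners:
                cell = state.cells.get(cid)
                if cell and sa.sid in cell.shared_ids:
                    cell.shared_ids.remove(sa.sid)
            state.pair_junctions.pop(tuple(sorted(sa.owners)), None)
            del state.shared[sa.sid]
    for cell in state.cells.values():
        _kill_if_empty(state, cell)

    # start-of-step centroids of living cells
    centroids = {
        cid: _centroid_xy(c, state) for cid, c in state.cells.items() if c.alive
    }

    # (2) elongation vs retraction, adhesion deposition
    for pp in state.protrusions.values():
        cen = centroids.get(pp.owner)
        if cen is None:
            continue
        vx = pp.x - cen[0]
        vy = pp.y - cen[1]
        d = math.hypot(vx, vy)
        if d == 0.0:
            continue  # point sits on the centroid; direction undefined
        ux, uy = vx / d, vy / d
        resistance = config.resistance_k * max(0.0, d - config.rest_distance) ** config.resistance_exponent
        friction = config.friction_mu * len(pp.adhesion_ids)
        if resistance <= friction:
            # outward move, clipped at the arena wall; only ground actually
            # gained counts toward the next adhesion deposit
            nx = min(max(pp.x + config.elongation_speed * ux, xmin), xmax)
            ny = min(max(pp.y + config.elongation_speed * uy, ymin), ymax)
            gained = math.hypot(nx - pp.x, ny - pp.y)
            pp.x, pp.y = nx, ny
            pp.outward_travel += gained
            while pp.outward_travel >= config.deposit_spacing:
                pp.outward_travel -= config.deposit_spacing
                ad = MatrixAdhesion(
                    aid=state.new_id(), x=pp.x, y=pp.y, owner_pid=pp.pid
                )
                state.adhesions[ad.aid] = ad
                pp.adhesion_ids.append(ad.aid)
        else:
            pull = config.retraction_gain * (resistance - friction)
            pull = min(pull, d)  # never overshoot past the centroid
            sx, sy = -pull * ux, -pull * uy
            pp.x += sx
            pp.y += sy
            for aid in pp.adhesion_ids:
                ad = state.adhesions[aid]
                ad.x += sx
                ad.y += sy

    # (3) contact rule against foreign gray circles (start-of-step centroids)
    for pp in list(state.protrusions.values()):
        hit: int | None = None
        best = config.d_spawn
        for cid, cen in centroids.items():
            if cid == pp.owner:
                continue
            dist = math.hypot(pp.x - cen[0], pp.y - cen[1])
            if dist <= best:
                hit, best = cid, dist
        if hit is None:
            continue
        state.events.append(
            {
                "step": state.step_index,
                "event": "contact",
                "cell": pp.owner,
                "id": pp.pid,
                "other": hit,
            }
        )
        if config.contact_mode == "lose_matrix_keep_point":
            for aid in pp.adhesion_ids:
                state.adhesions.pop(aid, None)
            pp.adhesion_ids.clear()
            state.protrusions.pop(pp.pid)
            owner = state.cells[pp.owner]
            if pp.pid in owner.protrusion_ids:
                owner.protrusion_ids.remove(pp.pid)
            pair = tuple(sorted((pp.owner, hit)))
            existing = state.pair_junctions.get(pair)
            if existing is not None and existing in state.shared:
                # the junction between this pair already exists: the new
                # filopodial contact reinforces it (fresh age and position)
                sa = state.shared[existing]
                sa.age = 0
                sa.x, sa.y = pp.x, pp.y
            else:
                sa = SharedAdhesion(
                    sid=state.new_id(), x=pp.x, y=pp.y, owners=(pp.owner, hit)
                )
                state.shared[sa.sid] = sa
                state.pair_junctions[pair] = sa.sid
                owner.shared_ids.append(sa.sid)
                state.cells[hit].shared_ids.append(sa.sid)
        else:  # remove_point: CIL-like
            _remove_protrusion(state, pp)

    # (4) spawn to target count (centroids recomputed after the moves)
    live = [c for c in state.cells.values() if c.alive]
    post_centroids = {}
    for cell in live:
        try:
            post_centroids[cell.cid] = _centroid_xy(cell, state)
        except ValueError:
            _kill_if_empty(state, cell)
    for cell in live:
        if not cell.alive:
            continue
        foreign = [p for cid, p in post_centroids.items() if cid != cell.cid]
        while len(cell.protrusion_ids) < config.target_protrusions:
            if spawn_protrusion(cell, state, config, foreign) is None:
                break  # fully surrounded: no free membrane to protrude into

    # (5) clamp everything into the arena
    for pp in state.protrusions.values():
        pp.x = min(max(pp.x, xmin), xmax)
        pp.y = min(max(pp.y, ymin), ymax)
    for ad in state.adhesions.values():
        ad.x = min(max(ad.x, xmin), xmax)
        ad.y = min(max(ad.y, ymin), ymax)
    for sa in state.shared.values():
        sa.x = min(max(sa.x, xmin), xmax)
        sa.y = min(max(sa.y, ymin), ymax)
    return state


def _init_state(config: SimConfig) -> SimState:
    rng = np.random.default_rng(config.seed)
    state = SimState(
        step_index=0, cells={}, protrusions={}, adhesions={}, shared={}, rng=rng
    )
    xmin, xmax, ymin, ymax = config.arena
    if config.cluster_origin is None:
        # flush against the rear wall, centered across the strip: the sheet
        # starts at the organ base and is confined on three sides
        origin = (
            xmin + 2.0,
            max(ymin, (ymin + ymax) / 2.0 - config.cluster_extent[1] / 2.0),
        )
    else:
        origin = config.cluster_origin
    for i in range(config.n_cells):
        sx = min(max(origin[0] + rng.uniform(0.0, config.cluster_extent[0]), xmin), xmax)
        sy = min(max(origin[1] + rng.uniform(0.0, config.cluster_extent[1]), ymin), ymax)
        cell = Cell(cid=i)
        state.cells[i] = cell
        # an even fan at a random phase: the lowest-density spawn rule
        # applied around a fixed center, with no preferred direction
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        for j in range(config.target_protrusions):
            angle = phase + 2.0 * math.pi * j / config.target_protrusions
            # random initial ages desynchronize protrusion turnover so the
            # initial fan does not expire and respawn in lockstep
            pp = ProtrusionPoint(
                pid=state.new_id(),
                x=sx + config.d_spawn * math.cos(angle),
                y=sy + config.d_spawn * math.sin(angle),
                owner=i,
                age=int(rng.integers(0, config.protrusion_lifetime)),
            )
            state.protrusions[pp.pid] = pp
            cell.protrusion_ids.append(pp.pid)
    state.events.clear()  # initial placement is not part of the event log
    return state


def run_simulation(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the model and return centroid tracks plus the event log.

    The track table uses the same dialect the track metrics consume
    (``track_id, time_min, x_um, y_um`` — one step is one time unit), so
    simulated cells can be analyzed with exactly the statistics applied to
    imaged cells.  Identical config and seed give identical output.
    """
    state = _init_state(config)
    records: list[tuple[str, int, float, float]] = []

    def record() -> None:
        for cid in sorted(state.cells):
            cell = state.cells[cid]
            if not cell.alive:
                continue
            cx, cy = _centroid_xy(cell, state)
            records.append((f"cell{cid}", state.step_index, cx, cy))

    record()
    for _ in range(config.n_steps):
        step(state, config)
        record()
    tracks = pd.DataFrame(records, columns=["track_id", "time_min", "x_um", "y_um"])
    events = pd.DataFrame(
        state.events, columns=["step", "event", "cell", "id", "other"]
    )
    return tracks, events
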