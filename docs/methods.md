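# Methods

`myotrack` analyzes collective cell migration on curved organ surfaces —
the concrete system it models is the sheet of nascent myotubes that
migrates over the *Drosophila* pupal testis, a roughly prolate-ellipsoidal
organ — and ships an agent-based model of the filopodia/adhesion mechanics
proposed to drive that migration. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
does and does not establish.

## 1. Unwrapping 3D trajectories (`myotrack.geometry`)

Planar directionality statistics (biased angle, meandering, straightness)
assume Euclidean 2D geometry; a plain xy-projection of tracks on a curved
surface distorts angles near the silhouette. The unwrapping is a
cylindrical map about the organ's central axis, chosen for high angle
accuracy at the cost of distance accuracy away from the maximal radius.

**Axis estimation.** The pooled point cloud is sorted by x and cut into
`n_subsets` (default 10) equal-count bins. In each bin the extreme points
in the yz-plane — minimal-y, maximal-y, maximal-z — span a triangle whose
circumcenter approximates the tube center at that x (a degenerate triangle
falls back to the bin's yz-centroid and is counted in the report). A
straight line through the centroids of the first and last half of the bin
centers is taken as the axis; the cloud is rigidly moved so this line
becomes the x-axis, and the procedure is repeated `axis_iterations`
(default 3) times. Equal-count binning is robust to non-uniform sampling
along the axis (equal-width binning is available via config). The
composite transform is tracked so the axis is also reported in the
original frame.

The triangulation is well-posed only when the imaged band of the surface
covers *more* than half the circumference: then the y-extremes lie on the
organ's flanks and the z-extreme above them. A band narrower than half the
circumference puts the max-z point on the band edge, collinear-ish with
the y-extremes, and the fitted centers become unstable in z. This matches
the imaging reality the package targets (volumetric stacks through most of
the organ depth) and is how the synthetic generator is configured (§5).

**Central angle.** After alignment each point has a yz-offset
`(dy, dz)` from the axis (axis→point), radius `r = |(dy, dz)|`, and a
central angle computed by three quadrant branches of
`arccos(dy / r)`:

- below the axis (`dz < 0`, and the tie `dz = 0`): `θ = +arccos(dy/r)`
- above, `dy > 0`: `θ = −arccos(dy/r)`
- above, `dy ≤ 0`: `θ = 2π − arccos(dy/r)`

which together equal the single formula `θ = wrap(−atan2(dz, dy))` with
`θ ∈ (−π/2, 3π/2]` (checked to 1e-9 rad over 10⁵ random vectors in the
test suite). The seam of the map is the +z line above the axis; the −z
line below maps to `θ = π/2`.

**Planar coordinates.** The unwrapped ordinate is linear in the angle,
`y' = (π/2 − θ)·r_max`, i.e. arc length at the dataset's maximal radius
`r_max` (a user override of `r_max` exists for cross-dataset
comparability). On a constant-radius tube this makes the map an isometry
of the unrolled cylinder. The abscissa is compensated for radius: all
points, pooled across tracks, are sorted by aligned x (ties broken stably
by track and time) and accumulated as
`x'_n = x'_{n−1} + (x_n − x_{n−1})·(r_max / r_n)`,
with the current point's radius in the denominator. On a constant-radius
cloud this is the identity; on tapering surfaces it stretches axial
distances measured at small radii. Note the consequence: with measurement
noise, `r_max` is the maximal *noisy* radius, so corrected-x distances are
inflated by roughly `r_max/r̄`; net axial displacement is therefore best
measured on the aligned-but-uncorrected x (the endpoint statistic below is
defined on raw data for the same reason).

This is deliberately not a true Mercator projection (no logarithmic
latitude stretch), and no general mesh unwrapping is attempted.

## 2. Constrained smoothing (`myotrack.smoothing`)

Manual spot tracking fluctuates by a few µm; per-step speeds and angles on
raw tracks measure the tracker, not the cell. The smoother treats each
measured spot as the center of a ball of `radius` (default 10 µm) and
seeks a small-turning-angle path through the balls. The optimizer is
sequential midpoint relaxation: sweep the interior points in time order,
move each to the midpoint of its current neighbors, clamp it back onto the
ball around its *original* measurement (so error can never accumulate
beyond the radius), with endpoints fixed by default. A sweep that would
increase the total turning angle is rejected and iteration stops, making
the objective non-increasing by construction; `iterations` (default 30) is
a fixed sweep budget, not a convergence criterion. This is a deterministic,
parameter-free approximation of the global minimal-angle path; no claim is
made that it finds the global optimum, and the hard guarantees (ball
constraint, monotone objective, straight tracks as fixed points) are what
the tests assert.

## 3. Migration statistics (`myotrack.metrics`)

All statistics are emitted as tidy tables; hypothesis testing is left to
external tools by design.

- **distance on x**: x(last) − x(first) of the raw 3D track — an
  endpoint statistic immune to tracking jitter, preferred over speed for
  slow cells.
- **neighbor permanency**: for each cell, the fraction of its k = 6
  nearest neighbors at the start that are again among its k nearest at the
  end; 1 for a rigidly moving field. Nearest sets use stable index order
  on distance ties. The alternative reading (fixed identity list with a
  distance cutoff) is not implemented; k-nearest re-membership is
  symmetric and parameter-free.
- **biased angle**: mean per-step unsigned angle (0–180°) between the
  displacement and the organ axis; zero-length steps are skipped.
  Comparable only among cells of similar net displacement — jitter pushes
  slow cells toward 90° — hence computed on smoothed tracks.
- **meandering distance**: per spot, `|d₂| = |y − ȳ_track| · (r/r_max)`,
  i.e. the deviation from the track's mean line, down-weighted where the
  unwrapping stretched the surface most (small radius). The defining
  formula's x-component is identically zero; this literal form is the
  default and an `x_mean` variant (including `x − x̄_track`) is available
  behind a flag, with results labelled. Medians are reported per track
  and over the pooled per-spot values.
- **track speed mean**: path length / elapsed time on smoothed tracks.
- **filopodia orientation/density**: bearings of (tip − center of mass),
  binned (12 × 30° default) for rose plots; densities split tips at the
  center's axis coordinate (front = toward the organ tip, i.e. smaller
  coordinate in oriented images; ties to the rear) and divide by the
  respective membrane edge length.
- **adhesion lifetimes**: death − birth per uncensored event, grouped by
  free-edge vs cell-cell edge class; censored events are excluded and
  tallied.
- **sheet-mask metrics**: gaps are 8-connected components of the inverted
  foreground lying fully inside the raster (border-touching components
  are outside the sheet, not gaps). Free edge is the summed crack-length
  perimeter — the count of pixel edges between gap and sheet — times the
  pixel size, a bit-reproducible convention (a 5×5 px hole at 1 µm/px has
  free edge 20 µm). Area per cell divides the foreground area by the
  user-supplied cell count. The gap-size time series sums only gaps
  strictly larger than 20 µm² (configurable), treating smaller holes as
  segmentation noise. Grayscale rasters are binarized by an explicit
  [min, max] intensity window at read time (the original workflow used
  window (299, 300) on 16-bit data).

## 4. The agent model (`myotrack.abm`)

A cell is a set of protrusion points (filopodia tips); its position is the
centroid of its protrusion points plus its shared (cell-cell) adhesion
points. There is no directional state anywhere: motion is the centroid's
displacement as members appear, elongate, retract and disappear.

Per synchronous step, in fixed order (the order affects trajectories and
is therefore part of the model): **cull** members past their lifetimes →
**move** each filopodium against the start-of-step centroid → **contact
rule** → **spawn** up to the target count (against recomputed centroids)
→ **clamp** to the arena.

- *Elongation vs retraction*: a tip at distance d from the centroid feels
  membrane resistance `R = k·max(0, d − d₀)` (exponent configurable) and
  static friction `F = µ · (live matrix adhesions of the filopodium)`.
  If `R ≤ F` the tip advances outward by `v_e` and deposits an immobile
  matrix adhesion every `deposit_spacing` µm of ground actually gained
  (movement lost to the arena boundary does not count — so a filopodium
  pressed against a wall stops depositing, loses its adhesions to aging
  and retracts: walls are passively non-adhesive, never repulsive). If
  `R > F` the entire filopodium — tip and adhesions — is dragged toward
  the centroid by `retraction_gain · (R − F)`.
- *Contact rule*: a protrusion point inside a foreign cell's gray circle
  (radius `d_spawn` around that cell's centroid — the same circle new
  protrusions spawn on) loses its matrix adhesions. In the default
  `lose_matrix_keep_point` mode it becomes a shared adhesion recognized
  by both cells' centroids; in `remove_point` mode it simply vanishes —
  the variant whose dispersal phenotype resembles contact inhibition of
  locomotion.
- *Junctions are unique per cell pair*: a repeated filopodial contact
  between the same two cells refreshes the existing junction's age and
  position rather than adding a member. Without this cap, junction
  accumulation swamps the centroids (tens of junctions against twelve
  protrusion points) and clusters freeze into collapsed clumps.
- *Spawning*: new tips appear on the gray circle at the midpoint of the
  largest angular gap between existing members' bearings (ties toward the
  smaller bearing; a memberless-bearing situation draws a uniform angle
  from the run's RNG) — filopodia assembly has no built-in asymmetry.
  Bearings whose spawn position falls inside a foreign gray circle are
  skipped for the next-widest gap: membrane facing a touching neighbor is
  already engaged in contact. A fully surrounded cell spawns nothing that
  step. This rule is what prevents a contact-conversion avalanche when
  contact circles overlap.
- *Initialization*: cells are seeded in a box (default flush against one
  end of a 300 × 36 µm strip), each with an even fan of tips at a random
  phase and uniformly random initial ages, so turnover is desynchronized
  from step one.

Defaults (µm, steps): `d_spawn = 6 = 2·d₀`, `v_e = 0.5`, `k = 0.2`,
`µ = 0.2`, `deposit_spacing = 1`, lifetimes `T_p = 60`, `T_a = 20`,
`T_s = 60`, 12 tips per cell, 8 cells, 1000 steps. They are chosen so a
filopodium's steady-state reach is ~2× the spawn radius (≈ 12–13 µm), its
adhesion turnover is continuous, and neighboring cells sit slightly beyond
two contact radii so contacts occur at extended tips. None of these
numbers is a measurement; they are the package's own working regime.

Emergent behaviors under these defaults, asserted over seed ensembles in
the test suite: an isolated cell's net displacement is statistically
indistinguishable from zero along the migration axis; a cluster confined
on three sides migrates along the free axis (mean net displacement of a
few µm per 1000 steps, significantly above isolated-cell drift by rank
test); and at matched seeds the `remove_point` variant ends with a larger
mean nearest-neighbor distance than the junction-forming mode in an open
arena. The dispersal comparison uses an open arena because in the narrow
strip the walls bound nearest-neighbor distances for both modes. Known
artifact: in the narrow strip an isolated cell acquires a small (~3 µm per
1000 steps) transverse drift from the deterministic spawn tie-break
interacting with the non-adhesive walls; drift along the migration axis is
unbiased (checked over 40 seeds, and in an open arena both axes are
unbiased).

## 5. Synthetic data (`myotrack.synthetic`)

Generators produce every input class with recorded ground truth;
everything is deterministic under a seed.

- **Surface tracks**: random walks in parameter space (axial coordinate,
  azimuth) on a cylinder (default R = 40 µm) or prolate ellipsoid
  (a = 150, b = c = 40 µm), so points lie exactly on the surface by
  construction. Defaults mirror the imaging conditions the package
  targets: frames every 5 min for 7 h, axial drift 0.37 µm/min (so a
  ~130 µm displacement over the effective migration span), angular
  diffusion 1e-4 rad²/min, isotropic measurement noise of SD 2 µm, and an
  arbitrary rigid transform of the whole scene. Cells occupy azimuths
  (−2.2, 2.2) rad — about 70 % of the circumference, centered opposite
  the unwrap seam — wide enough for well-posed axis triangulation (§1)
  while keeping every track clear of the seam. Truth records the axis,
  per-point unwrapped coordinates, and the drift.
- **Surface clouds**: static uniform clouds over the full surface with a
  known rigid transform, for axis-recovery checks in isolation.
- **Filopodia cells**: tips at von-Mises bearings (concentration 0 =
  uniform, matching the absence of directional bias in filopodia
  assembly).
- **Adhesion events**: exponential lifetimes per edge class (defaults
  10 min free edge vs 5 min cell-cell — the 2× asymmetry), births uniform
  over the movie, right-censoring at the movie end. Lifetime
  distributions in real data are only known through summary plots;
  exponential is a modeling convenience, and the recovery tests compare
  ratios, which are robust to the distributional choice.
- **Sheet masks**: full-foreground rasters with scheduled rectangular
  holes of exact pixel area; overlapping holes merge and the truth
  records areas measured on the final raster.

What passing on synthetic data does *not* show: robustness to tracking
gaps and mistracks, to anisotropic (z-elongated) localization error, to
organs whose axis is appreciably curved (a single straight axis is fitted
per iteration), to azimuth bands near or across the seam, or to real
segmentation artifacts in masks. The generators emulate geometry and
sampling, not microscopy.

## 6. Numerical conventions

Angles are radians internally, degrees at the API/CLI boundary; lengths
µm, times minutes. θ ties: `dz = 0` joins the below-axis branch; the seam
value is represented as 3π/2, keeping θ in (−π/2, 3π/2]. Points exactly on
the axis are an error, never silently dropped. The x-sort in the
correction breaks ties stably by (track, time). Circumcenter degeneracy is
declared at relative triangle area ≤ 1e-12 and falls back to the bin
centroid inside axis estimation (reported), but is an error when called
directly. Rose-bin bearings are rounded to 1e-9 degrees so whole-degree
data does not straddle bin edges. The smoother's monotonicity tolerance is
1e-12 rad. Simulations use one `numpy` PCG64 stream per run; reruns with
the same config and seed are byte-identical, and CSV outputs carry
provenance headers (version, seed, config digest) as `#` comment lines.
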