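"""Unwrap 3D trajectories from a curved organ surface into the plane.

Cells are simulated migrating on a cylinder of radius 40 µm whose axis is
rotated and translated away from the coordinate axes (as a mounted organ
would be).  The pipeline estimates the central axis from the point cloud
alone, realigns it to x, and unwraps each point by its central angle.
"""

import numpy as np

from myotrack import geometry, synthetic
from myotrack.io import tracks_from_frame

config = synthetic.SurfaceTrackConfig(
    n_cells=30, rotation_deg=10.0, translation_um=(5.0, 7.0, -3.0), seed=42
)
tracks_df, truth = synthetic.generate_surface_tracks(config)

frame, axis, report = geometry.project_tracks(tracks_from_frame(tracks_df))

d = np.asarray(axis.direction)
true_d = np.asarray(truth.axis.direction)
angle_err = np.degrees(np.arccos(min(1.0, abs(float(d @ true_d)))))

print(f"tracks: {tracks_df.track_id.nunique()}, spots: {len(frame)}")
print(f"estimated axis direction: {np.round(d, 4)}")
print(f"axis angle error vs ground truth: {angle_err:.3f} deg")
print(f"per-iteration axis residuals (um): {np.round(report.residuals, 3)}")
print(frame.head(3).to_string(index=False))
print(
    "\nEach row is one spot: x_corrected_um/y_unwrapped_um are planar\n"
    "coordinates in which Euclidean directionality statistics are valid;\n"
    "theta_rad is the central angle about the organ axis and radius_um the\n"
    "spot's distance from it.  The residuals show the axis fit converging\n"
    "over the three realignment iterations."
)
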