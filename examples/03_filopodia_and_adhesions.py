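"""Filopodia orientation/density and adhesion-lifetime asymmetry.

A star-shaped cell with uniformly oriented filopodia tips is generated
(matching the observation that filopodia assembly has no directional
bias), binned for a rose plot, and split into front/rear densities.  An
adhesion event table with a 2x free-edge lifetime asymmetry — the
proposed symmetry-breaker of directional migration — is generated and the
asymmetry recovered.
"""

import numpy as np

from myotrack import metrics, synthetic

fset = synthetic.generate_filopodia_cell(
    n_tips=60, front_edge_um=25.0, rear_edge_um=30.0, concentration=0.0, seed=3
)
angles, rose = metrics.filopodia_orientation(fset)
front, rear = metrics.filopodia_density(fset)
print("rose bins (30 deg, from +x ccw):", rose.tolist())
print(f"filopodia density: front {front:.2f} / rear {rear:.2f} per um membrane")
print("(uniform orientation: no front/rear bias beyond counting noise)\n")

events = synthetic.generate_adhesion_events(
    n_per_class=1000, mean_lifetime_free_min=10.0,
    mean_lifetime_cell_cell_min=5.0, movie_length_min=240.0, seed=3,
)
lifetimes, summary = metrics.adhesion_lifetimes(events)
print(summary.to_string(index=False))
s = summary.set_index("edge_class")
ratio = s.loc["free_edge", "mean_min"] / s.loc["cell_cell_edge", "mean_min"]
print(
    f"\nrecovered free-edge / cell-cell lifetime ratio: {ratio:.2f} (true 2.0)\n"
    "Longer-lived matrix adhesions at free edges anchor protrusions there;\n"
    "the imbalance pulls cells toward free space."
)
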