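"""The filopodia/adhesion agent model: contact-stimulated migration.

Three conditions, three seeds each:
- a cluster confined in a narrow strip (closed behind and on the sides,
  free ahead) migrates collectively along the strip;
- an isolated cell jiggles without net direction;
- the CIL-like variant (protrusions vanish on contact instead of forming
  junctions) disperses more than the junction-forming mode.
"""

import numpy as np
from scipy.spatial.distance import cdist

from myotrack import abm

def net_dx(tracks):
    net = tracks.groupby("track_id").agg(dx=("x_um", lambda s: s.iloc[-1] - s.iloc[0]))
    return float(net.dx.mean())

def mean_nn(tracks):
    last = tracks[tracks.time_min == tracks.time_min.max()][["x_um", "y_um"]].to_numpy()
    d = cdist(last, last)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())

open_arena = dict(arena=(0.0, 200.0, 0.0, 200.0), cluster_origin=(80.0, 85.0),
                  cluster_extent=(40.0, 30.0))

cluster, isolated, keep, cil = [], [], [], []
for seed in (1, 2, 3):
    cluster.append(net_dx(abm.run_simulation(abm.SimConfig(seed=seed))[0]))
    isolated.append(net_dx(abm.run_simulation(abm.SimConfig(
        seed=seed, n_cells=1, cluster_origin=(150.0, 18.0),
        cluster_extent=(0.001, 0.001)))[0]))
    keep.append(mean_nn(abm.run_simulation(abm.SimConfig(seed=seed, **open_arena))[0]))
    cil.append(mean_nn(abm.run_simulation(abm.SimConfig(
        seed=seed, contact_mode="remove_point", **open_arena))[0]))

print(f"confined cluster, net displacement along strip: {np.round(cluster,1)} um")
print(f"isolated cell, net displacement:                {np.round(isolated,1)} um")
print(f"final nearest-neighbor distance, junction mode: {np.round(keep,1)} um")
print(f"final nearest-neighbor distance, CIL mode:      {np.round(cil,1)} um")
print(
    "\nNo parameter encodes a direction: the cluster's bias along the free\n"
    "axis emerges from contact-dependent loss of matrix grip alone, and\n"
    "deleting protrusions on contact (CIL mode) turns cohesion into\n"
    "dispersal."
)
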