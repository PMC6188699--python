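"""MD-trajectory observables on a toy trajectory with known ground truth.

Builds a small synthetic trajectory (Gaussian jitter around fixed sites,
one correlated atom pair, a scripted ion-binding episode covering 37% of
frames) and runs the full observable stack: ion-site occupancy, RMSD,
radius of gyration, per-residue RMSF, conformational clustering and the
mutual-information generalized correlation matrix.
"""

import numpy as np

from ionprobe import (
    AtomSelection,
    cluster_frames,
    generalized_correlation,
    min_distance_series,
    occupancy_percent,
    radius_of_gyration_series,
    rmsd_series,
    rmsf_per_residue,
)
from ionprobe.synthetic import IonEpisode, ToyTrajectorySpec, simulate_toy_trajectory

spec = ToyTrajectorySpec(
    n_atoms=6,
    n_frames=1000,
    fluctuation_sd=0.02,           # nm per coordinate
    correlated_pairs=[(1, 4, 0.6)],
    ion_episodes=[IonEpisode(100, 470, bound_distance=0.3, unbound_distance=0.6)],
    seed=7,
)
top, traj, truth = simulate_toy_trajectory(spec)
heavy = AtomSelection(top.heavy_atoms(), "heavy")

ion_site = min_distance_series(
    traj,
    AtomSelection([truth["ion_atom"]], "ion"),
    AtomSelection([truth["site_atom"]], "site"),
)
occ = occupancy_percent(ion_site, cutoff=0.4)
print(f"ion-site occupancy (< 0.4 nm): {occ:.2f} %   (prescribed: {truth['occupancy_percent']:.2f} %)")

rmsd = rmsd_series(traj, traj.coordinates[0], heavy)
rg = radius_of_gyration_series(traj, top.masses)
print(f"RMSD to frame 0 (mean)       : {rmsd.mean():.4f} nm")
print(f"radius of gyration (mean)    : {rg.mean():.3f} nm")

rmsf = rmsf_per_residue(traj, top)
print(f"RMSF range over residues     : {min(rmsf.values()):.4f} - {max(rmsf.values()):.4f} nm"
      f"   (sigma*sqrt(3) = {0.02 * np.sqrt(3):.4f})")

protein = AtomSelection(np.arange(6), "protein")
cm = generalized_correlation(traj, protein)
print(f"rMI of the planted rho=0.6 pair: {cm.values[1, 4]:.2f}")

cl = cluster_frames(traj, protein, cutoff=0.15)
print(f"clusters: {cl.n_clusters}, sizes {list(cl.sizes)}, representative frame {cl.representative_frames[0]}")
print()
print("Occupancy and rMI match their construction; a single-basin jittering")
print("structure collapses into one cluster at the 0.15 nm cutoff.")
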