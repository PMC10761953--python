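"""Stability metrics on a synthetic trajectory.

Samples 200 frames from the thermal ensemble of a helix ANM and runs the
trajectory-analysis layer: RMSD series with histogram, per-residue RMSF,
radius of gyration, SASA of the first frame, and k-means clustering with
representative frames.
"""

import numpy as np

import prspath as pp

helix = pp.make_helix(20)
network = pp.build_anm_hessian(helix, cutoff_rc=13.0)
ensemble = pp.sample_anm_ensemble(network, n_frames=200, kT=0.5, seed=8, topology=helix)

rmsd = pp.rmsd_series(ensemble)
print(f"RMSD vs frame 0: mean {rmsd.values.mean():.2f} A, max {rmsd.values.max():.2f} A")
edges, freq = pp.histogram(rmsd.values, n_bins=10)
print("RMSD histogram occupancy (10 bins):", np.round(freq, 2).tolist())

fluct = pp.rmsf(ensemble)
print(f"RMSF: ends {fluct[0]:.2f}/{fluct[-1]:.2f} A vs core {fluct[10]:.2f} A")
# helix termini fluctuate more than the core — fewer springs restrain them

rg = pp.radius_of_gyration(ensemble.frames[0])
total_sasa, _ = pp.sasa(helix)
print(f"Rg of first frame: {rg:.2f} A; SASA of the ideal helix: {total_sasa:.0f} A^2")

clusters = pp.cluster_frames(ensemble, k=5, seed=0)
print(f"k-means (k=5) representative frames: {clusters.representatives}")
# the representatives are the frames closest to each cluster centroid —
# the compact stand-ins one would carry into docking or tunnel analysis
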