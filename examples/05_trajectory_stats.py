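"""Ensemble statistics: RMSF, DCCM, orientation clustering, D-A distances.

Builds a toy coordinate ensemble (20-residue CA trace + 6-atom sugar) with
two substrate poses and correlated backbone motion, then runs the full
trajectory-statistics stack on it.
"""

import numpy as np

from thermocat import (HBondSpec, average_structure, cluster_orientations, dccm,
                       donor_acceptor_distances, rmsf)
from thermocat.experiments import _cluster_reference
from thermocat.synthetic import CovarianceBlock, gen_ensemble

ref = _cluster_reference()
sub_idx = np.arange(20, 26)
alt_pose = ref.coordinates[0, sub_idx] + np.array([10.0, 0.0, 0.0])

# ensemble 1: thermal jitter + an 85/15 two-pose substrate mixture
ens, _ = gen_ensemble(ref, n_frames=500, isotropic_sigma=0.3,
                      orientation_mixture=(0.85, sub_idx, alt_pose), seed=6)

# substrate orientation clustering (average linkage, epsilon 1.5 A)
res = cluster_orientations(ens, substrate_selection="chain S",
                           fit_selection="name CA", epsilon=1.5)
print(f"{res.n_clusters} orientation clusters; dominant population "
      f"{100 * res.populations[0]:.1f}% (medoid frame {res.medoid_frames[0]})")

# RMSF after iterative alignment to the average structure
_, aligned = average_structure(ens, fit_indices=np.arange(20))
ids, vals = rmsf(aligned, selection="name CA")
print(f"per-residue RMSF: mean {vals.mean():.2f} A, max {vals.max():.2f} A")

# ensemble 2: correlated backbone motion (two anticorrelated halves)
ens2, _ = gen_ensemble(
    ref, n_frames=2000, isotropic_sigma=0.05,
    blocks=[CovarianceBlock(np.arange(0, 10), 0.4, 0.75, +1),
            CovarianceBlock(np.arange(10, 20), 0.4, 0.75, -1)], seed=8)
m = dccm(ens2, selection="name CA")
print(f"mean DCC within block 1: {m.matrix[:10, :10][np.triu_indices(10, 1)].mean():+.2f}; "
      f"between blocks: {m.matrix[:10, 10:].mean():+.2f}")

# donor-acceptor distance distribution (sugar C1 to first backbone atom)
d, (edges, counts) = donor_acceptor_distances(ens, ens.atom_index("C1"), 0)
print(f"D-A distance: {d.mean():.1f} +/- {d.std():.1f} A over {d.size} frames")

# The dominant cluster (~85%) mirrors the one-main-orientation case; the
# anticorrelated DCC blocks show how the factor model encodes long-range
# coupled motion that the DCCM recovers.
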