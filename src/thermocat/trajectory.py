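"""Statistics on coordinate ensembles: superposition, RMSF, DCCM, clustering,
donor-acceptor distances and hydrogen-bond occupancy.

All operations take a :class:`~thermocat.io.CoordinateEnsemble` (frames x
atoms x 3, Angstrom). Rigid-body motion is removed by Kabsch (SVD)
superposition before any fluctuation statistic; the dynamical
cross-correlation matrix uses the isotropic dot-product definition

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),

with dr the deviation from the time-mean position after alignment.
Substrate-orientation clustering is hierarchical agglomerative with average
linkage on the pairwise RMSD of substrate atoms computed in the shared
active-site alignment frame (no per-pair refitting), cut at a minimum
inter-cluster distance epsilon.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import ttest_ind

from .io import CoordinateEnsemble, SelectionError, ValidationError


@dataclass(frozen=True)
class Superposition:
    """A proper rigid-body transform y ~ x @ rotation.T + translation."""

    rotation: np.ndarray     # 3x3, det = +1
    translation: np.ndarray  # Angstrom
    rmsd: float              # over the fit selection, Angstrom

    def apply(self, coords):
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class DCCMatrix:
    """Residue-residue dynamical cross-correlation matrix."""

    matrix: np.ndarray
    residue_ids: np.ndarray
    chain_ids: np.ndarray
    zero_variance: np.ndarray  # bool flags for atoms with no motion


@dataclass(frozen=True)
class ClusterResult:
    """Frame clustering by substrate-orientation RMSD.

    Labels are contiguous from 0 in order of decreasing population; medoid
    representatives minimise the summed within-cluster RMSD.
    """

    labels: np.ndarray
    populations: np.ndarray        # fractions, sum to 1, decreasing
    medoid_frames: np.ndarray
    epsilon: float
    merge_heights: np.ndarray      # linkage distances, for diagnostics

    @property
    def n_clusters(self) -> int:
        return self.populations.size


@dataclass(frozen=True)
class HBondSpec:
    """Geometric hydrogen-bond criterion.

    Satisfied when donor-heavy-atom to acceptor distance <= distance_cutoff
    AND the D-H...A angle at the hydrogen >= angle_cutoff. Defaults follow
    common trajectory-analysis practice (3.0 Angstrom, 135 degrees).
    """

    donor: int        # heavy-atom index
    hydrogen: int | None
    acceptor: int
    distance_cutoff: float = 3.0   # Angstrom
    angle_cutoff: float = 135.0    # degrees

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValidationError("distance cutoff must be positive")
        if not (0 < self.angle_cutoff <= 180):
            raise ValidationError("angle cutoff must be in (0, 180] degrees")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile, reference, fit_indices=None):
    """Optimal least-squares proper rotation/translation (Kabsch via SVD).

    *mobile* and *reference* are (n_atoms, 3) arrays; the transform is
    determined on ``fit_indices`` (default: all atoms) and returned together
    with the whole transformed mobile structure. The reflection case is
    corrected so the rotation determinant is +1.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(mob.shape[0])
    fit_indices = np.asarray(fit_indices)
    if fit_indices.dtype == bool:
        fit_indices = np.flatnonzero(fit_indices)
    if fit_indices.size < 3:
        raise ValidationError("superposition needs at least 3 fit atoms")
    x = mob[fit_indices]
    y = ref[fit_indices]
    if x.shape != y.shape:
        raise ValidationError("fit selections must have equal length")

    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    H = xc.T @ yc
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1e-300):
        raise ValidationError("degenerate (collinear) fit geometry")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = y.mean(axis=0) - x.mean(axis=0) @ R.T
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved[fit_indices] - y) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd), moved


def coordinate_rmsd(a, b) -> float:
    """Plain coordinate RMSD between two equally-shaped coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def average_structure(ensemble: CoordinateEnsemble, fit_indices=None,
                      n_iter: int = 2, tol: float = 1e-6):
    """Iteratively align all frames to the running mean structure.

    Returns ``(mean_coords, aligned CoordinateEnsemble)``. Convergence is
    declared when the mean structure shifts by less than *tol* Angstrom
    (RMSD) or after *n_iter* refinement rounds.
    """
    if ensemble.n_frames < 2:
        raise ValidationError("average structure needs at least 2 frames")
    coords = ensemble.coordinates.copy()
    mean = coords[0].copy()
    for _ in range(max(n_iter, 1)):
        for f in range(coords.shape[0]):
            _, coords[f] = kabsch_superpose(coords[f], mean, fit_indices)
        new_mean = coords.mean(axis=0)
        shift = coordinate_rmsd(new_mean, mean)
        mean = new_mean
        if shift < tol:
            break
    aligned = CoordinateEnsemble(
        coordinates=coords, atom_names=ensemble.atom_names,
        residue_ids=ensemble.residue_ids, residue_names=ensemble.residue_names,
        chain_ids=ensemble.chain_ids, frame_times=ensemble.frame_times,
    )
    return mean, aligned


# ---------------------------------------------------------------------------
# Fluctuations
# ---------------------------------------------------------------------------

def rmsf(ensemble: CoordinateEnsemble, selection=None, group_by: str = "residue",
         average_monomers: bool = False):
    """Per-atom or per-residue RMSF of an already-aligned ensemble (Angstrom).

    RMSF_i = sqrt(<|r_i - <r_i>|^2>). With ``group_by='residue'`` atom values
    are averaged within each residue; ``average_monomers`` additionally maps
    the chains onto a common residue numbering (by rank within each chain)
    and averages positionally, yielding a single-monomer profile.

    Returns ``(ids, values)`` where ids are residue identifiers (or atom
    indices for ``group_by='atom'``).
    """
    ens = ensemble if selection is None else ensemble.select(selection)
    xyz = ens.coordinates
    dev = xyz - xyz.mean(axis=0, keepdims=True)
    per_atom = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))

    if group_by == "atom":
        return np.arange(per_atom.size), per_atom
    if group_by != "residue":
        raise ValueError("group_by must be 'atom' or 'residue'")

    if not average_monomers:
        keys = np.array([f"{c}:{r}" for c, r in zip(ens.chain_ids, ens.residue_ids)])
        uniq, inv = np.unique(keys, return_inverse=True)
        # preserve ensemble order of first occurrence
        first = np.array([np.flatnonzero(inv == i)[0] for i in range(uniq.size)])
        order = np.argsort(first)
        vals = np.array([per_atom[inv == i].mean() for i in order])
        return uniq[order], vals

    chains = np.unique(ens.chain_ids)
    profiles = []
    for ch in chains:
        m = ens.chain_ids == ch
        rid = ens.residue_ids[m]
        uniq = np.unique(rid)
        profiles.append(np.array([per_atom[m][rid == r].mean() for r in uniq]))
    lengths = {p.size for p in profiles}
    if len(lengths) != 1:
        raise ValidationError("monomer averaging requires chains of equal residue count")
    return np.arange(1, profiles[0].size + 1), np.mean(profiles, axis=0)


def rmsf_difference_test(profiles_a, profiles_b, adjust: bool = True):
    """Per-residue two-tailed Welch t-test between two sets of RMSF replicates.

    *profiles_a*/*profiles_b* are (n_replicates, n_residues) arrays with >= 2
    replicates each (independent simulations). Residues where both groups
    have zero variance get p = 1 and a flag. Returns a dict with ``p``,
    ``t``, ``zero_variance`` and, when *adjust*, Benjamini-Hochberg ``p_adj``.
    """
    a = np.asarray(profiles_a, dtype=float)
    b = np.asarray(profiles_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValidationError("replicate profiles must be 2-D with matching residue count")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("need at least 2 replicates per group")
    # variance of identical replicates can be ~1e-33 from rounding, not 0
    def _novar(x):
        return x.var(axis=0) <= 1e-24 * (np.mean(x, axis=0) ** 2 + 1.0)
    zero_var = _novar(a) & _novar(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            t, p = ttest_ind(a, b, axis=0, equal_var=False)
    p = np.where(zero_var, 1.0, p)
    t = np.where(zero_var, 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    out = {"t": t, "p": p, "zero_variance": zero_var}
    if adjust:
        from statsmodels.stats.multitest import multipletests
        out["p_adj"] = multipletests(p, method="fdr_bh")[1]
    return out


def dccm(ensemble: CoordinateEnsemble, selection="name CA") -> DCCMatrix:
    """Dynamical cross-correlation matrix over one atom per residue.

    The ensemble must already be aligned (e.g. via :func:`average_structure`).
    Atoms with zero positional variance get zero off-diagonal correlation and
    a flag rather than a division blow-up.
    """
    ens = ensemble if selection is None else ensemble.select(selection)
    xyz = ens.coordinates
    dev = xyz - xyz.mean(axis=0, keepdims=True)          # (F, N, 3)
    # <dr_i . dr_j> via a single tensordot over frames and xyz
    inner = np.tensordot(dev, dev, axes=([0, 2], [0, 2])) / dev.shape[0]
    var = np.diag(inner).copy()
    zero = var <= 0
    denom = np.sqrt(np.outer(np.where(zero, 1.0, var), np.where(zero, 1.0, var)))
    C = inner / denom
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(0.5 * (C + C.T), -1.0, 1.0)
    return DCCMatrix(matrix=C, residue_ids=ens.residue_ids.copy(),
                     chain_ids=ens.chain_ids.copy(), zero_variance=zero)


# ---------------------------------------------------------------------------
# Orientation clustering
# ---------------------------------------------------------------------------

def cluster_orientations(ensemble: CoordinateEnsemble, substrate_selection,
                         fit_selection=None, epsilon: float = 1.5,
                         align: bool = True) -> ClusterResult:
    """Cluster frames by substrate-orientation RMSD (average linkage).

    Frames are first aligned on *fit_selection* (e.g. active-site C-alpha
    atoms) to the iterative average structure; the pairwise RMSD of the
    non-hydrogen substrate atoms is then computed in that shared frame with
    no per-pair refitting. Agglomeration proceeds until the minimum distance
    between clusters exceeds *epsilon* (Angstrom). Clusters are relabelled by
    decreasing population.
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    if ensemble.n_frames == 1:
        return ClusterResult(labels=np.zeros(1, dtype=int), populations=np.ones(1),
                             medoid_frames=np.zeros(1, dtype=int), epsilon=epsilon,
                             merge_heights=np.empty(0))
    work = ensemble
    if align and fit_selection is not None:
        fit_mask = _mask_for(ensemble, fit_selection)
        _, work = average_structure(ensemble, fit_indices=np.flatnonzero(fit_mask))
    sub = work.select(substrate_selection)
    xyz = sub.coordinates                                     # (F, N, 3)
    F = xyz.shape[0]
    flat = xyz.reshape(F, -1)
    sq = np.sum((flat[:, None, :] - flat[None, :, :]) ** 2, axis=2) / xyz.shape[1]
    dist = np.sqrt(np.clip(sq, 0, None))
    cond = squareform(dist, checks=False)
    Z = linkage(cond, method="average")
    raw = fcluster(Z, t=epsilon, criterion="distance")        # merges up to epsilon
    labels, populations, medoids = _relabel_by_population(raw, dist)
    return ClusterResult(labels=labels, populations=populations,
                         medoid_frames=medoids, epsilon=epsilon,
                         merge_heights=Z[:, 2].copy())


def _mask_for(ens, selection):
    from .io import _selection_mask
    mask = _selection_mask(ens, selection)
    if not mask.any():
        raise SelectionError(f"fit selection {selection!r} matched no atoms")
    return mask


def _relabel_by_population(raw_labels, dist):
    uniq, counts = np.unique(raw_labels, return_counts=True)
    # decreasing population; ties resolved by first-frame order for determinism
    first_frame = np.array([np.flatnonzero(raw_labels == u)[0] for u in uniq])
    order = np.lexsort((first_frame, -counts))
    labels = np.empty(raw_labels.size, dtype=int)
    medoids = np.empty(order.size, dtype=int)
    populations = np.empty(order.size)
    for new, idx in enumerate(order):
        members = np.flatnonzero(raw_labels == uniq[idx])
        labels[members] = new
        populations[new] = members.size / raw_labels.size
        within = dist[np.ix_(members, members)].sum(axis=1)
        medoids[new] = members[np.argmin(within)]
    return labels, populations, medoids


# ---------------------------------------------------------------------------
# Distances and hydrogen bonds
# ---------------------------------------------------------------------------

def donor_acceptor_distances(ensemble: CoordinateEnsemble, donor: int, acceptor: int,
                             bin_width: float = 0.1):
    """Per-frame donor-acceptor distance (Angstrom) plus a histogram.

    For hydride transfer this is typically substrate C1 to nicotinamide C4.
    Returns ``(distances, (bin_edges, counts))``; counts sum to the frame
    count.
    """
    n = ensemble.n_atoms
    for idx, what in ((donor, "donor"), (acceptor, "acceptor")):
        if not (0 <= idx < n):
            raise SelectionError(f"{what} atom index {idx} not present (n_atoms={n})")
    d = np.linalg.norm(ensemble.coordinates[:, donor, :] -
                       ensemble.coordinates[:, acceptor, :], axis=1)
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    return d, (edges, counts)


def hbond_occupancy(ensemble: CoordinateEnsemble, spec: HBondSpec):
    """Fraction of frames satisfying the hydrogen-bond criterion.

    Returns ``(occupancy, per_frame_flags)``. The angle criterion needs the
    donor hydrogen; a missing hydrogen is an error since the criterion is
    always active (HBondSpec requires a positive angle cutoff).
    """
    xyz = ensemble.coordinates
    n = ensemble.n_atoms
    for idx, what in ((spec.donor, "donor"), (spec.acceptor, "acceptor")):
        if not (0 <= idx < n):
            raise SelectionError(f"{what} atom index {idx} not present (n_atoms={n})")
    d_da = np.linalg.norm(xyz[:, spec.donor] - xyz[:, spec.acceptor], axis=1)
    ok = d_da <= spec.distance_cutoff
    if spec.hydrogen is None:
        raise SelectionError("H-bond angle criterion requires the donor hydrogen atom")
    if not (0 <= spec.hydrogen < n):
        raise SelectionError(f"hydrogen atom index {spec.hydrogen} not present")
    hd = xyz[:, spec.donor] - xyz[:, spec.hydrogen]
    ha = xyz[:, spec.acceptor] - xyz[:, spec.hydrogen]
    cosang = np.sum(hd * ha, axis=1) / (
        np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok &= angle >= spec.angle_cutoff
    return float(ok.mean()), ok
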