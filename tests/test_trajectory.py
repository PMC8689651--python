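"""Superposition, RMSF, DCCM, orientation clustering, distances, H-bonds."""

import numpy as np
import pytest

from thermocat.io import CoordinateEnsemble, SelectionError, ValidationError
from thermocat.synthetic import CovarianceBlock, gen_ensemble, _rotation_matrix
from thermocat.trajectory import (
    HBondSpec, average_structure, cluster_orientations, coordinate_rmsd, dccm,
    donor_acceptor_distances, hbond_occupancy, kabsch_superpose, rmsf,
    rmsf_difference_test,
)


def _random_coords(n, seed=0, spread=5.0):
    return np.random.default_rng(seed).normal(0, spread, (n, 3))


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def test_superpose_identity():
    x = _random_coords(10)
    sup, moved = kabsch_superpose(x, x)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(sup.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(moved, x)


def test_superpose_recovers_known_rotation():
    x = _random_coords(12, seed=3)
    R = _rotation_matrix(np.array([0.0, 0.0, 1.0]), np.radians(37.0))
    y = x @ R.T + np.array([1.0, -2.0, 3.0])
    sup, moved = kabsch_superpose(x, y)
    assert sup.rmsd < 1e-10
    assert np.allclose(moved, y, atol=1e-9)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-10)


def test_superpose_rmsd_matches_hand_value():
    """4-atom toy, one atom displaced: RMSD equals the brute-force value."""
    ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    mob = ref.copy()
    mob[3] += [0.0, 0.0, 0.4]
    sup, moved = kabsch_superpose(mob, ref)
    # brute force over a dense grid of rotations about the centroid would be
    # expensive; instead verify against the closed-form optimum recomputed
    # independently from the covariance SVD
    xc = mob - mob.mean(axis=0)
    yc = ref - ref.mean(axis=0)
    U, S, Vt = np.linalg.svd(xc.T @ yc)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    msd = (np.sum(xc**2) + np.sum(yc**2) - 2 * (S[0] + S[1] + d * S[2])) / 4
    assert sup.rmsd == pytest.approx(np.sqrt(max(msd, 0)), abs=1e-12)


def test_superpose_rigid_pretransform_invariance():
    x = _random_coords(15, seed=5)
    y = _random_coords(15, seed=6)
    base = kabsch_superpose(x, y)[0].rmsd
    R = _rotation_matrix(np.array([1.0, 1.0, 0.0]) / np.sqrt(2), 1.1)
    moved = x @ R.T + np.array([4.0, 5.0, -6.0])
    again = kabsch_superpose(moved, y)[0].rmsd
    assert again == pytest.approx(base, abs=1e-9)


def test_superpose_degenerate_geometry():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValidationError):
        kabsch_superpose(line, line)
    with pytest.raises(ValidationError):
        kabsch_superpose(_random_coords(5), _random_coords(5), fit_indices=[0, 1])


# ---------------------------------------------------------------------------
# Average structure
# ---------------------------------------------------------------------------

def _ensemble_from_frames(frames):
    n = frames.shape[1]
    return CoordinateEnsemble(
        coordinates=frames, atom_names=np.array(["CA"] * n),
        residue_ids=np.arange(1, n + 1), residue_names=np.array(["GLY"] * n),
        chain_ids=np.array(["A"] * n))


def test_average_of_identical_frames():
    x = _random_coords(8)
    ens = _ensemble_from_frames(np.repeat(x[None], 4, axis=0))
    mean, aligned = average_structure(ens)
    assert np.allclose(mean, x, atol=1e-10)


def test_average_of_symmetric_pair():
    """Frames at x +/- delta average back to x when delta has no rigid part."""
    x = _random_coords(8, seed=2)
    delta = np.random.default_rng(3).normal(0, 0.05, x.shape)
    # project delta off the rigid-body modes (translations + infinitesimal
    # rotations about the centroid) so superposition is identity to 1st order
    xc = x - x.mean(axis=0)
    modes = []
    for ax in np.eye(3):
        modes.append(np.tile(ax, (8, 1)))            # translation
        modes.append(np.cross(np.tile(ax, (8, 1)), xc))  # rotation
    M = np.stack([m.ravel() / np.linalg.norm(m) for m in modes])
    d = delta.ravel()
    d = d - M.T @ np.linalg.lstsq(M.T, d, rcond=None)[0]
    delta = d.reshape(x.shape)
    ens = _ensemble_from_frames(np.stack([x + delta, x - delta]))
    mean, _ = average_structure(ens, n_iter=5)
    assert coordinate_rmsd(mean, x) < 5e-3


def test_average_converges_monotonically():
    rng = np.random.default_rng(9)
    frames = _random_coords(10, seed=4)[None] + rng.normal(0, 0.3, (6, 10, 3))
    ens = _ensemble_from_frames(frames)
    shifts = []
    coords = ens.coordinates.copy()
    mean = coords[0].copy()
    for _ in range(4):
        for f in range(coords.shape[0]):
            _, coords[f] = kabsch_superpose(coords[f], mean)
        new_mean = coords.mean(axis=0)
        shifts.append(coordinate_rmsd(new_mean, mean))
        mean = new_mean
    assert all(b <= a + 1e-12 for a, b in zip(shifts, shifts[1:]))


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def test_rmsf_static_ensemble_zero():
    x = _random_coords(6)
    ens = _ensemble_from_frames(np.repeat(x[None], 5, axis=0))
    _, vals = rmsf(ens)
    assert np.allclose(vals, 0.0)


def test_rmsf_two_frame_closed_form():
    """One atom at +/- 1 A about its mean has RMSF exactly 1.0 A."""
    x = _random_coords(4)
    a = x.copy(); b = x.copy()
    a[2] += [1.0, 0, 0]; b[2] -= [1.0, 0, 0]
    ens = _ensemble_from_frames(np.stack([a, b]))
    ids, vals = rmsf(ens, group_by="atom")
    assert vals[2] == pytest.approx(1.0)
    assert vals[0] == pytest.approx(0.0)


def test_rmsf_matches_naive_double_loop():
    rng = np.random.default_rng(11)
    frames = rng.normal(0, 1, (10, 5, 3))
    ens = _ensemble_from_frames(frames)
    _, fast = rmsf(ens, group_by="atom")
    naive = np.empty(5)
    for i in range(5):
        mean_i = frames[:, i, :].mean(axis=0)
        naive[i] = np.sqrt(np.mean([np.sum((frames[f, i] - mean_i) ** 2)
                                    for f in range(10)]))
    assert np.allclose(fast, naive, atol=1e-12)


def test_rmsf_rigid_body_motion_removed(toy_reference):
    """Pure rigid-body motion leaves RMSF < 1e-8 A after alignment."""
    ens, _ = gen_ensemble(toy_reference, 30, rigid_body=(8.0, 2.0), seed=21)
    _, aligned = average_structure(ens, n_iter=10)
    _, vals = rmsf(aligned, group_by="atom")
    assert vals.max() < 1e-8


def test_rmsf_monomer_averaging(tetramer_reference):
    ens, _ = gen_ensemble(tetramer_reference, 40, isotropic_sigma=0.3, seed=5)
    _, aligned = average_structure(ens)
    ids, vals = rmsf(aligned, average_monomers=True)
    assert vals.size == 10
    assert np.all(vals > 0)


def test_rmsf_monomer_averaging_unequal_chains_error(tetramer_reference):
    trimmed = tetramer_reference.select("resid 1-9 and chain A,B,C")
    # add back full chain D -> unequal residue counts
    import numpy as np
    full_d = tetramer_reference.select("chain D")
    merged = CoordinateEnsemble(
        coordinates=np.concatenate([trimmed.coordinates, full_d.coordinates], axis=1),
        atom_names=np.concatenate([trimmed.atom_names, full_d.atom_names]),
        residue_ids=np.concatenate([trimmed.residue_ids, full_d.residue_ids]),
        residue_names=np.concatenate([trimmed.residue_names, full_d.residue_names]),
        chain_ids=np.concatenate([trimmed.chain_ids, full_d.chain_ids]))
    ens, _ = gen_ensemble(merged, 5, isotropic_sigma=0.1, seed=1)
    with pytest.raises(ValidationError):
        rmsf(ens, average_monomers=True)


# ---------------------------------------------------------------------------
# Welch t-test on RMSF replicates
# ---------------------------------------------------------------------------

def test_welch_identical_groups():
    prof = np.tile(np.linspace(0.5, 1.5, 8), (3, 1))
    res = rmsf_difference_test(prof, prof.copy())
    assert np.all(res["p"] == 1.0)
    assert np.all(res["zero_variance"])


def test_welch_detects_shifted_residue():
    rng = np.random.default_rng(2)
    a = 1.0 + rng.normal(0, 0.05, (5, 10))
    b = a + rng.normal(0, 0.05, (5, 10)) * 0.0
    b = 1.0 + rng.normal(0, 0.05, (5, 10))
    b[:, 4] += 0.5   # 10 SD shift at residue 4
    res = rmsf_difference_test(a, b)
    assert res["p"][4] < 1e-3
    assert res["p_adj"][4] < 1e-2


def test_welch_statistic_matches_hand_formula():
    a = np.array([[1.0, 2.0], [1.2, 2.2], [0.9, 1.9]])
    b = np.array([[1.5, 2.0], [1.6, 2.1], [1.4, 2.2]])
    res = rmsf_difference_test(a, b, adjust=False)
    for j in range(2):
        x, y = a[:, j], b[:, j]
        t_hand = (x.mean() - y.mean()) / np.sqrt(x.var(ddof=1) / 3 + y.var(ddof=1) / 3)
        assert res["t"][j] == pytest.approx(t_hand, rel=1e-12)


# ---------------------------------------------------------------------------
# DCCM
# ---------------------------------------------------------------------------

def test_dccm_duplicate_and_negated_trajectories():
    rng = np.random.default_rng(4)
    base = rng.normal(0, 1, (50, 1, 3))
    frames = np.concatenate([base, base, -base], axis=1) + rng.normal(0, 0, (50, 3, 3))
    ens = _ensemble_from_frames(frames)
    m = dccm(ens, selection=None)
    assert m.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert m.matrix[0, 2] == pytest.approx(-1.0, abs=1e-12)
    assert np.allclose(np.diag(m.matrix), 1.0)
    assert np.allclose(m.matrix, m.matrix.T)
    assert np.all(np.abs(m.matrix) <= 1.0)


def test_dccm_matches_naive_loop():
    rng = np.random.default_rng(8)
    frames = rng.normal(0, 1, (20, 6, 3))
    ens = _ensemble_from_frames(frames)
    m = dccm(ens, selection=None).matrix
    dev = frames - frames.mean(axis=0)
    naive = np.empty((6, 6))
    for i in range(6):
        for j in range(6):
            num = np.mean([dev[f, i] @ dev[f, j] for f in range(20)])
            di = np.mean([dev[f, i] @ dev[f, i] for f in range(20)])
            dj = np.mean([dev[f, j] @ dev[f, j] for f in range(20)])
            naive[i, j] = num / np.sqrt(di * dj)
    assert np.allclose(m, naive, atol=1e-12)


def test_dccm_independent_atoms_near_zero():
    rng = np.random.default_rng(12)
    frames = rng.normal(0, 1, (2000, 12, 3))
    ens = _ensemble_from_frames(frames)
    m = dccm(ens, selection=None).matrix
    off = np.abs(m[np.triu_indices(12, 1)])
    assert np.mean(off < 0.1) >= 0.99


def test_dccm_zero_variance_atom_flagged():
    rng = np.random.default_rng(3)
    frames = rng.normal(0, 1, (30, 3, 3))
    frames[:, 1, :] = 7.0   # frozen atom
    ens = _ensemble_from_frames(frames)
    m = dccm(ens, selection=None)
    assert m.zero_variance[1]
    assert m.matrix[1, 1] == 1.0
    assert np.all(m.matrix[1, [0, 2]] == 0.0)


def test_dccm_recovers_block_sign_structure(toy_reference):
    """Factor-model ensemble: within-block corr > 0.5, anti-block < -0.3.

    The generator adds no rigid-body motion, so the ensemble is already in a
    common frame and no superposition (which would soak up part of the
    collective block motion) is applied.
    """
    blocks = [CovarianceBlock(np.arange(0, 10), 0.5, 0.75, +1),
              CovarianceBlock(np.arange(10, 20), 0.5, 0.75, -1)]
    ens, _ = gen_ensemble(toy_reference, 2000, blocks=blocks,
                          isotropic_sigma=0.05, seed=17)
    m = dccm(ens, selection="name CA").matrix
    within = m[:10, :10][np.triu_indices(10, 1)].mean()
    between = m[:10, 10:].mean()
    assert within > 0.5
    assert between < -0.3


# ---------------------------------------------------------------------------
# Orientation clustering
# ---------------------------------------------------------------------------

def test_cluster_two_separated_bundles(toy_reference):
    sub_idx = np.arange(20, 26)
    alt = toy_reference.coordinates[0, sub_idx] + np.array([10.0, 0.0, 0.0])
    ens, _ = gen_ensemble(toy_reference, 60, isotropic_sigma=0.2,
                          orientation_mixture=(0.5, sub_idx, alt), seed=31)
    res = cluster_orientations(ens, substrate_selection="chain S",
                               fit_selection="name CA", epsilon=1.5)
    assert res.n_clusters == 2
    assert res.populations.sum() == pytest.approx(1.0)
    assert np.all(np.diff(res.populations) <= 0)


def test_cluster_dominant_population(toy_reference):
    """85/15 two-pose mixture at 500 frames: dominant cluster > 80%."""
    sub_idx = np.arange(20, 26)
    alt = toy_reference.coordinates[0, sub_idx] + np.array([10.0, 0.0, 0.0])
    ens, _ = gen_ensemble(toy_reference, 500, isotropic_sigma=0.3,
                          orientation_mixture=(0.85, sub_idx, alt), seed=42)
    res = cluster_orientations(ens, substrate_selection="chain S",
                               fit_selection="name CA", epsilon=1.5)
    assert res.populations[0] > 0.80


def test_cluster_merge_heights_match_brute_force(toy_reference):
    """Average-linkage merge heights equal a naive implementation on 6 frames."""
    sub_idx = np.arange(20, 26)
    alt = toy_reference.coordinates[0, sub_idx] + np.array([6.0, 0.0, 0.0])
    ens, _ = gen_ensemble(toy_reference, 6, isotropic_sigma=0.4,
                          orientation_mixture=(0.5, sub_idx, alt), seed=13)
    res = cluster_orientations(ens, substrate_selection="chain S",
                               fit_selection=None, align=False, epsilon=1.5)
    # naive average linkage on the same distance matrix
    xyz = ens.select("chain S").coordinates
    F = xyz.shape[0]
    D = np.sqrt(((xyz[:, None] - xyz[None]) ** 2).sum(axis=(2, 3)) / xyz.shape[1])
    clusters = [[i] for i in range(F)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    assert np.allclose(np.sort(res.merge_heights), np.sort(heights), atol=1e-10)


def test_cluster_single_frame(toy_reference):
    ens, _ = gen_ensemble(toy_reference, 1, seed=0)
    res = cluster_orientations(ens, substrate_selection="chain S", epsilon=1.5)
    assert res.n_clusters == 1 and res.populations[0] == 1.0


def test_cluster_deterministic_and_permutation_consistent(toy_reference):
    sub_idx = np.arange(20, 26)
    alt = toy_reference.coordinates[0, sub_idx] + np.array([10.0, 0.0, 0.0])
    ens, _ = gen_ensemble(toy_reference, 40, isotropic_sigma=0.2,
                          orientation_mixture=(0.6, sub_idx, alt), seed=3)
    r1 = cluster_orientations(ens, "chain S", "name CA", 1.5)
    r2 = cluster_orientations(ens, "chain S", "name CA", 1.5)
    assert np.array_equal(r1.labels, r2.labels)
    perm = np.random.default_rng(0).permutation(40)
    permuted = CoordinateEnsemble(
        coordinates=ens.coordinates[perm], atom_names=ens.atom_names,
        residue_ids=ens.residue_ids, residue_names=ens.residue_names,
        chain_ids=ens.chain_ids)
    r3 = cluster_orientations(permuted, "chain S", "name CA", 1.5)
    # same partition: frames clustered together stay together
    for a in range(40):
        for b in range(a + 1, 40):
            same1 = r1.labels[a] == r1.labels[b]
            same3 = r3.labels[np.argsort(perm)[a]] == r3.labels[np.argsort(perm)[b]]
            assert same1 == same3


# ---------------------------------------------------------------------------
# Distances and H-bonds
# ---------------------------------------------------------------------------

def test_donor_acceptor_345_triangle():
    frames = np.zeros((3, 2, 3))
    frames[:, 1] = [3.0, 4.0, 0.0]
    ens = CoordinateEnsemble(frames, np.array(["C1", "C4"]), np.array([1, 2]),
                             np.array(["GLC", "NAP"]), np.array(["S", "N"]))
    d, (edges, counts) = donor_acceptor_distances(ens, 0, 1)
    assert np.allclose(d, 5.0)
    assert counts.sum() == 3
    assert counts.max() == 3        # degenerate single-bin histogram


def test_donor_acceptor_missing_atom():
    frames = np.zeros((2, 2, 3))
    ens = CoordinateEnsemble(frames, np.array(["C1", "C4"]), np.array([1, 2]),
                             np.array(["GLC", "NAP"]), np.array(["S", "N"]))
    with pytest.raises(SelectionError, match="acceptor"):
        donor_acceptor_distances(ens, 0, 5)


def _hbond_ensemble(n_good, n_bad):
    """Donor-H-acceptor geometry: good frames linear 2.8 A, bad frames 5 A."""
    frames = []
    for _ in range(n_good):
        frames.append([[0.0, 0, 0], [1.0, 0, 0], [2.8, 0, 0]])   # angle 180
    for _ in range(n_bad):
        frames.append([[0.0, 0, 0], [1.0, 0, 0], [5.0, 0, 0]])
    return CoordinateEnsemble(
        np.array(frames), np.array(["OD", "HD", "OA"]), np.array([1, 1, 2]),
        np.array(["ASP", "ASP", "SER"]), np.array(["A", "A", "A"]))


def test_hbond_occupancy_extremes_and_half():
    spec = HBondSpec(donor=0, hydrogen=1, acceptor=2)
    assert hbond_occupancy(_hbond_ensemble(4, 0), spec)[0] == 1.0
    assert hbond_occupancy(_hbond_ensemble(0, 4), spec)[0] == 0.0
    occ, flags = hbond_occupancy(_hbond_ensemble(3, 3), spec)
    assert occ == 0.5
    assert flags.sum() == 3


def test_hbond_angle_criterion():
    # bent geometry: H at right angle -> D-H...A angle 90 deg < 135 cutoff
    frames = np.array([[[0.0, 0, 0], [1.0, 0, 0], [1.0, 1.5, 0.0]]])
    ens = CoordinateEnsemble(frames, np.array(["OD", "HD", "OA"]), np.array([1, 1, 2]),
                             np.array(["ASP", "ASP", "SER"]), np.array(["A", "A", "A"]))
    occ, _ = hbond_occupancy(ens, HBondSpec(0, 1, 2))
    assert occ == 0.0   # distance 1.8 A passes but angle fails


def test_hbond_spec_validation():
    with pytest.raises(ValidationError):
        HBondSpec(0, 1, 2, distance_cutoff=-1.0)
    with pytest.raises(ValidationError):
        HBondSpec(0, 1, 2, angle_cutoff=270.0)
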