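"""Superposition, Gromos clustering and panel selection against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from allofinger.clustering import (
    DOMAIN_FRAMEWORKS,
    ClusterResult,
    binding_site_residues,
    gromos_cluster,
    make_framework,
    pairwise_rmsd_matrix,
    select_panel,
    superpose,
)
from allofinger.synthetic import default_trajectory_spec, generate_trajectory
from allofinger.trajectory import Metatrajectory

# ------------------------------------------------------------------ oracles


def gromos_brute(rmsd, cutoff):
    """Literal re-implementation of the neighbour-count rule with loops."""
    n = len(rmsd)
    unassigned = list(range(n))
    assignment = np.full(n, -1)
    reps, pops = [], []
    cid = 0
    while unassigned:
        best, best_count = None, -1
        for i in unassigned:  # ascending order -> lowest index wins ties
            count = sum(1 for j in unassigned if rmsd[i][j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = [j for j in unassigned if rmsd[best][j] <= cutoff]
        for j in members:
            assignment[j] = cid
        reps.append(best)
        pops.append(len(members))
        unassigned = [j for j in unassigned if j not in members]
        cid += 1
    return assignment, np.array(reps), np.array(pops)


def grid_search_rmsd(ref, mob, levels=12, pts=9):
    """Coarse-to-fine grid search over Euler angles (translation = centroid
    alignment, optimal for every rotation); independent of the Kabsch path."""
    P = mob - mob.mean(axis=0)
    Q = ref - ref.mean(axis=0)
    center = np.zeros(3)
    width = np.pi
    best = np.inf
    for _ in range(levels):
        grids = [np.linspace(c - width, c + width, pts) for c in center]
        for a in grids[0]:
            for b in grids[1]:
                for g in grids[2]:
                    R = Rotation.from_euler("zyx", [a, b, g]).as_matrix()
                    r = np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))
                    if r < best:
                        best, center = r, np.array([a, b, g])
        width /= 3.0
    return best


# -------------------------------------------------------------- superpose


def test_superpose_identity_gives_zero_rmsd(rng):
    X = rng.normal(size=(10, 3))
    fitted, rmsd = superpose(X, X.copy())
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(fitted, X, atol=1e-12)


def test_superpose_invariant_under_rigid_motion(rng):
    X = rng.normal(size=(12, 3))
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    moved = X @ R.T + np.array([1.0, 2.0, 3.0])
    fitted, rmsd = superpose(X, moved)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(fitted, X, atol=1e-9)


def test_superpose_matches_grid_search_oracle():
    ref = np.array(
        [[0.0, 0.0, 0.0], [0.5, 0.0, 0.0], [0.0, 0.5, 0.0], [0.0, 0.0, 0.5]]
    )
    mob = ref.copy()
    mob[3] += [0.0, 0.0, 0.2]  # one atom displaced 0.2 nm
    _, rmsd = superpose(ref, mob)
    assert rmsd == pytest.approx(grid_search_rmsd(ref, mob), abs=1e-4)


def test_superpose_is_symmetric(rng):
    A = rng.normal(size=(8, 3))
    B = rng.normal(size=(8, 3))
    _, r_ab = superpose(A, B)
    _, r_ba = superpose(B, A)
    assert r_ab == pytest.approx(r_ba, abs=1e-10)


def test_superpose_rejects_degenerate_subsets(rng):
    X = rng.normal(size=(5, 3))
    with pytest.raises(ValueError, match="at least 3"):
        superpose(X, X, subset=[0, 1])
    line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="collinear"):
        superpose(line, line)


def test_rmsd_matrix_equals_per_pair_superpose(rng):
    frames = rng.normal(size=(5, 7, 3))
    idx = np.arange(7)
    mat = pairwise_rmsd_matrix(frames, idx)
    assert mat.shape == (5, 5)
    np.testing.assert_allclose(np.diag(mat), 0.0, atol=1e-9)
    for i in range(5):
        for j in range(5):
            _, r = superpose(frames[i], frames[j], idx)
            assert mat[i, j] == pytest.approx(r, abs=1e-9)


def test_rmsd_matrix_zero_for_identical_frames(rng):
    frame = rng.normal(size=(6, 3))
    frames = np.repeat(frame[None], 4, axis=0)
    np.testing.assert_allclose(pairwise_rmsd_matrix(frames, np.arange(6)), 0.0, atol=1e-9)


# ----------------------------------------------------------------- gromos


def _random_rmsd(rng, n, scale=1.0):
    m = rng.random((n, n)) * scale
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


def test_gromos_all_far_gives_singletons(rng):
    m = _random_rmsd(rng, 6) + 1.0
    np.fill_diagonal(m, 0.0)
    res = gromos_cluster(m, cutoff=0.5)
    assert res.n_clusters == 6
    np.testing.assert_array_equal(res.populations, np.ones(6))
    np.testing.assert_array_equal(np.sort(res.representatives), np.arange(6))


def test_gromos_all_close_gives_one_cluster(rng):
    m = _random_rmsd(rng, 6, scale=0.1)
    res = gromos_cluster(m, cutoff=0.5)
    assert res.n_clusters == 1
    assert res.representatives[0] == 0  # complete graph: tie -> lowest index


def test_gromos_matches_bruteforce_on_random_instances(rng):
    for _ in range(60):
        n = int(rng.integers(2, 15))
        m = _random_rmsd(rng, n)
        cutoff = float(rng.uniform(0.1, 0.9))
        res = gromos_cluster(m, cutoff)
        assign, reps, pops = gromos_brute(m, cutoff)
        np.testing.assert_array_equal(res.assignment, assign)
        np.testing.assert_array_equal(res.representatives, reps)
        np.testing.assert_array_equal(res.populations, pops)


def test_gromos_rejects_bad_matrices(rng):
    m = _random_rmsd(rng, 4)
    with pytest.raises(ValueError, match="positive"):
        gromos_cluster(m, 0.0)
    bad = m.copy()
    bad[0, 1] += 1.0
    with pytest.raises(ValueError, match="symmetric"):
        gromos_cluster(bad, 0.5)
    bad2 = m.copy()
    np.fill_diagonal(bad2, 0.3)
    with pytest.raises(ValueError, match="diagonal"):
        gromos_cluster(bad2, 0.5)


# ------------------------------------------------------------------- panel


def _fake_result(pops, n_frames):
    """ClusterResult with given populations over contiguous frame blocks."""
    assignment = np.repeat(np.arange(len(pops)), pops)
    reps = np.concatenate([[0], np.cumsum(pops)[:-1]])
    return ClusterResult(assignment, reps, np.array(pops))


def test_panel_size_arithmetic():
    domain = {name: _fake_result([5, 3, 2], 10) for name in DOMAIN_FRAMEWORKS}
    site = _fake_result([6, 4], 10)
    assert select_panel(domain, site, n_top=3, n_site=2).size == 14
    assert select_panel(domain, site, n_top=1, n_site=0).size == 4


def test_panel_errors_name_the_offending_framework():
    domain = {name: _fake_result([5, 3, 2], 10) for name in DOMAIN_FRAMEWORKS}
    domain["Clust-MC"] = _fake_result([10], 10)
    site = _fake_result([6, 4], 10)
    with pytest.raises(ValueError, match="Clust-MC"):
        select_panel(domain, site)


def test_panel_orders_by_population_and_records_fractions():
    domain = {name: _fake_result([4, 3, 2, 1], 10) for name in DOMAIN_FRAMEWORKS}
    site = _fake_result([7, 3], 10)
    panel = select_panel(domain, site)
    entries = panel.entries
    assert entries["framework"].tolist() == [
        f for f in DOMAIN_FRAMEWORKS for _ in range(3)
    ] + ["Site", "Site"]
    first = entries[entries["framework"] == "Clust-N"]
    assert first["population_fraction"].tolist() == [0.4, 0.3, 0.2]
    assert entries["structure_id"].is_unique


def test_panel_representatives_cover_all_basins():
    """On a 3-basin synthetic trajectory every framework's top clusters map
    back to all three planted basins."""
    spec = default_trajectory_spec(
        seed=17, n_residues=18, n_basins=3, n_frames=150,
        basin_weights=np.array([0.45, 0.35, 0.20]),
    )
    traj, truth = generate_trajectory(spec)
    site_res = binding_site_residues(traj)
    domain = {}
    for name in DOMAIN_FRAMEWORKS:
        fw = make_framework(name, traj.atom_meta)
        domain[name] = gromos_cluster(pairwise_rmsd_matrix(traj, fw), 0.225)
    site_fw = make_framework("Site", traj.atom_meta, site_residues=site_res)
    site = gromos_cluster(pairwise_rmsd_matrix(traj, site_fw), 0.225)
    panel = select_panel(domain, site)
    for name in DOMAIN_FRAMEWORKS:
        frames = panel.entries.loc[
            panel.entries["framework"] == name, "frame_index"
        ].to_numpy()
        assert set(truth[frames]) == {0, 1, 2}


# ------------------------------------------------------------- binding site


def _toy_site_trajectory():
    """One ligand atom at the origin; five 1-atom residues at controlled
    distances per frame (4 frames)."""
    # per-frame x-distance of residues A..E from the ligand
    dists = np.array(
        [
            [0.5, 0.5, 0.5, 0.5],   # A: always well within 1 nm
            [0.5, 0.5, 0.5, 5.0],   # B: within in exactly 3/4 frames (75%)
            [0.5, 5.0, 5.0, 0.5],   # C: within in 2/4 frames only
            [1.0, 1.0, 1.0, 1.0],   # D: exactly at the 1 nm cutoff
            [5.0, 5.0, 5.0, 5.0],   # E: never within
        ]
    )
    n_res, n_frames = dists.shape
    rows = [
        {
            "resid": r + 1,
            "resname": "ALA",
            "name": "CA",
            "heavy": True,
            "backbone": True,
            "domain": "M",
        }
        for r in range(n_res)
    ]
    rows.append(
        {
            "resid": 99,
            "resname": "LIG",
            "name": "L1",
            "heavy": True,
            "backbone": False,
            "domain": "ligand",
        }
    )
    coords = np.zeros((n_frames, n_res + 1, 3))
    for f in range(n_frames):
        for r in range(n_res):
            coords[f, r, 0] = dists[r, f]
    return Metatrajectory(coords, pd.DataFrame(rows))


def test_binding_site_membership_matches_hand_computation():
    traj = _toy_site_trajectory()
    residues = binding_site_residues(traj, dist_cutoff=1.0, frac=0.75)
    # A always in; B at the inclusive 75% boundary; D at the inclusive 1 nm
    # boundary; C (50%) and E (never) out.
    assert residues.tolist() == [1, 2, 4]


def test_binding_site_requires_ligand():
    traj = _toy_site_trajectory()
    meta = traj.atom_meta.copy()
    meta["domain"] = "M"
    with pytest.raises(ValueError, match="ligand"):
        binding_site_residues(Metatrajectory(traj.coords, meta))
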