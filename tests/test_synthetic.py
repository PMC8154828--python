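"""Generators: composition counts, determinism, and planted-signal recovery."""

import numpy as np
import pytest
from scipy import stats

from allofinger.chem import tanimoto
from allofinger.clustering import gromos_cluster, pairwise_rmsd_matrix
from allofinger.synthetic import (
    ACTIVATOR,
    INHIBITOR,
    LibrarySpec,
    PanelGenSpec,
    TrajectoryGenSpec,
    default_trajectory_spec,
    generate_docking_panel,
    generate_ligand_library,
    generate_pose_sets,
    generate_trajectory,
)

# ------------------------------------------------------------------ library


def test_default_library_composition(library):
    counts = library.labels["class"].value_counts()
    assert len(library.labels) == 133
    assert counts[INHIBITOR] == 49
    assert counts[ACTIVATOR] == 84
    assert library.labels["group"].nunique() == 8
    assert library.labels["ligand_id"].is_unique
    # each group maps to exactly one class
    assert (library.labels.groupby("group")["class"].nunique() == 1).all()


def test_library_deterministic_for_fixed_seed():
    a = generate_ligand_library(LibrarySpec(seed=3))
    b = generate_ligand_library(LibrarySpec(seed=3))
    assert a.labels.equals(b.labels)
    np.testing.assert_array_equal(a.fingerprints, b.fingerprints)
    c = generate_ligand_library(LibrarySpec(seed=4))
    assert not np.array_equal(a.fingerprints, c.fingerprints)


def test_zero_flip_rate_gives_identical_fingerprints_within_group():
    lib = generate_ligand_library(LibrarySpec(bit_flip_rate=0.0, seed=1))
    for _, grp in lib.labels.groupby("group"):
        fps = lib.fingerprints[grp.index.to_numpy()]
        assert (fps == fps[0]).all()


def test_half_flip_rate_erases_group_structure(rng):
    """At flip rate 0.5 every fingerprint is uniform random, so within-group
    and between-group Tanimoto similarities coincide (Monte-Carlo check)."""
    lib = generate_ligand_library(LibrarySpec(bit_flip_rate=0.5, fp_bits=1024, seed=2))
    groups = lib.labels["group"].to_numpy()
    n = len(groups)
    within, between = [], []
    while len(within) < 100 or len(between) < 100:
        i, j = rng.integers(n, size=2)
        if i == j:
            continue
        sim = tanimoto(lib.fingerprints[i], lib.fingerprints[j])
        (within if groups[i] == groups[j] else between).append(sim)
    assert abs(np.mean(within[:100]) - np.mean(between[:100])) < 0.05


def test_inconsistent_group_totals_rejected():
    spec = LibrarySpec(group_sizes=(40, 17, 10, 15, 16, 16, 18, 2))
    with pytest.raises(ValueError, match="group sizes"):
        spec.validate()
    with pytest.raises(ValueError, match="CB"):
        LibrarySpec(group_class=("activator", "badclass") + ("activator",) * 6).validate()


# --------------------------------------------------------------- trajectory


def _toy_spec(**kw):
    base = default_trajectory_spec(seed=0, n_residues=6, n_basins=2, n_frames=10)
    defaults = dict(
        basin_centers=base.basin_centers,
        basin_weights=base.basin_weights,
        atom_meta=base.atom_meta,
        n_frames=10,
        noise_sd=0.0,
        seed=0,
    )
    defaults.update(kw)
    return TrajectoryGenSpec(**defaults)


def test_zero_noise_frames_equal_basin_centers():
    spec = _toy_spec(basin_weights=np.array([0.5, 0.5]))
    traj, assign = generate_trajectory(spec)
    for i in range(traj.n_frames):
        np.testing.assert_array_equal(traj.coords[i], spec.basin_centers[assign[i]])


def test_degenerate_weights_assign_all_frames_to_one_basin():
    spec = _toy_spec(basin_weights=np.array([1.0, 0.0]))
    _, assign = generate_trajectory(spec)
    assert (assign == 0).all()


def test_invalid_weights_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        generate_trajectory(_toy_spec(basin_weights=np.array([0.7, 0.7])))


def test_near_degenerate_basins_logged(caplog):
    spec = _toy_spec(noise_sd=1.0)  # separation 0.3 nm << 3 nm
    with caplog.at_level("WARNING", logger="allofinger.synthetic"):
        generate_trajectory(spec)
    assert any("recovery not guaranteed" in r.message for r in caplog.records)


def test_well_separated_basins_recovered_by_gromos():
    """Three basins separated by >= 10x noise: downstream clustering at a
    cutoff between the noise and separation scales recovers them with
    >= 95% frame agreement against the generator's truth labels."""
    spec = default_trajectory_spec(
        seed=9, n_residues=18, n_basins=3, n_frames=300, noise_sd=0.02,
        basin_displacement=0.3, basin_weights=np.array([0.45, 0.35, 0.20]),
    )
    traj, truth = generate_trajectory(spec)
    rmsd = pairwise_rmsd_matrix(traj.coords, np.arange(traj.n_atoms))
    result = gromos_cluster(rmsd, cutoff=0.15)
    assert result.n_clusters == 3
    # agreement up to relabeling: map each cluster to its majority basin
    agree = 0
    for c in range(result.n_clusters):
        members = truth[result.assignment == c]
        agree += np.bincount(members).max()
    assert agree / traj.n_frames >= 0.95


# ------------------------------------------------------------ docking panel


def test_null_panel_scores_are_class_exchangeable(library):
    """With class_shift = 0 the per-structure best scores of the two classes
    come from the same distribution (two-sample test, alpha = 0.01)."""
    spec = PanelGenSpec(class_shift=0.0, seed=21)
    pose_sets, _ = generate_pose_sets(spec, library.labels)
    best = {ps.ligand_id: ps.scores[0] for ps in pose_sets if ps.structure_id == "S01"}
    cls = library.labels.set_index("ligand_id")["class"]
    act = [v for k, v in best.items() if cls[k] == ACTIVATOR]
    inh = [v for k, v in best.items() if cls[k] == INHIBITOR]
    assert stats.mannwhitneyu(act, inh).pvalue > 0.01


def test_zero_variance_shift_gives_exact_best_scores(library):
    spec = PanelGenSpec(class_shift=2.0, base_score=-6.0, score_sd=0.0, seed=0)
    pose_sets, truth = generate_pose_sets(spec, library.labels)
    cls = library.labels.set_index("ligand_id")["class"]
    preferred = set(truth["preferred_sets"][ACTIVATOR])
    for ps in pose_sets:
        if cls[ps.ligand_id] == ACTIVATOR:
            expected = -8.0 if ps.structure_id in preferred else -6.0
            assert ps.scores[0] == pytest.approx(expected)


def test_pose_table_matches_pose_sets(library):
    """The long-format table and the in-memory pose sets are the same draw."""
    spec = PanelGenSpec(seed=33)
    table, _ = generate_docking_panel(spec, library.labels)
    pose_sets, _ = generate_pose_sets(spec, library.labels)
    first = pose_sets[0]
    sub = table[
        (table["ligand_id"] == first.ligand_id)
        & (table["structure_id"] == first.structure_id)
        & (table["rank"] == 1)
    ]
    np.testing.assert_allclose(sub["score"].iloc[0], first.scores[0])
    np.testing.assert_allclose(sub[["x", "y", "z"]].to_numpy(), first.coords[0])


def test_empty_preferred_set_with_shift_rejected(library):
    spec = PanelGenSpec(class_shift=1.0, preferred_sets={ACTIVATOR: (0, 1)})
    with pytest.raises(ValueError, match="inhibitor"):
        generate_pose_sets(spec, library.labels)


def test_preferred_set_out_of_range_rejected():
    with pytest.raises(ValueError, match="subset of panel indices"):
        PanelGenSpec(n_structures=4, preferred_sets={ACTIVATOR: (5,), INHIBITOR: (1,)}).validate()
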