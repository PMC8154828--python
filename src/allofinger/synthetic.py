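"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators stand in for the experimental stages that are out of scope
here (MD simulation, ensemble docking, fingerprint computation from real
molecules):

* a ligand library with scaffold-group structure — by default 133 ligands
  (84 activators, 49 inhibitors) in eight scaffold groups, each group with a
  template bit vector whose bits are flipped independently per ligand;
* a metatrajectory sampled from planted conformational basins (mixture of
  Gaussians around per-basin reference geometries), with ground-truth basin
  labels kept in a sidecar;
* class-conditional docking-score panels encoding a conformational-selection
  signal: each functional class docks better (by ``class_shift``, in score
  units) on its preferred subset of panel structures.

Docking scores follow the negative-is-better convention (kcal/mol-like).
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import Metatrajectory

logger = logging.getLogger(__name__)

ACTIVATOR = "activator"
INHIBITOR = "inhibitor"

#: default scaffold groups: (name, class, size). Group->class follows the
#: study design (three inhibitor chemotypes, five activator ones, one
#: singleton); the per-group sizes are configurable conventions.
DEFAULT_GROUPS: tuple[tuple[str, str, int], ...] = (
    ("CC", ACTIVATOR, 40),
    ("CB", INHIBITOR, 17),
    ("GT", ACTIVATOR, 10),
    ("DP", ACTIVATOR, 15),
    ("BP1", INHIBITOR, 16),
    ("BP2", INHIBITOR, 16),
    ("Z", ACTIVATOR, 18),
    ("Unk", ACTIVATOR, 1),
)


# ------------------------------------------------------------------ library


@dataclass
class LibrarySpec:
    """Composition of the synthetic ligand library.

    ``bit_flip_rate`` is the per-bit probability of flipping a ligand's
    fingerprint away from its scaffold-group template; ``template_density``
    the probability a template bit is set.
    """

    n_activators: int = 84
    n_inhibitors: int = 49
    group_names: tuple[str, ...] = tuple(g for g, _, _ in DEFAULT_GROUPS)
    group_class: tuple[str, ...] = tuple(c for _, c, _ in DEFAULT_GROUPS)
    group_sizes: tuple[int, ...] = tuple(s for _, _, s in DEFAULT_GROUPS)
    fp_bits: int = 1024
    bit_flip_rate: float = 0.03
    template_density: float = 0.1
    shuffle: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (len(self.group_names) == len(self.group_class) == len(self.group_sizes)):
            raise ValueError("group_names/group_class/group_sizes lengths differ")
        for g, c in zip(self.group_names, self.group_class):
            if c not in (ACTIVATOR, INHIBITOR):
                raise ValueError(f"group {g!r} has invalid class {c!r}")
        n_act = sum(s for s, c in zip(self.group_sizes, self.group_class) if c == ACTIVATOR)
        n_inh = sum(s for s, c in zip(self.group_sizes, self.group_class) if c == INHIBITOR)
        if n_act != self.n_activators or n_inh != self.n_inhibitors:
            raise ValueError(
                f"group sizes imply {n_act} activators / {n_inh} inhibitors, "
                f"spec says {self.n_activators} / {self.n_inhibitors}"
            )
        if not 0.0 <= self.bit_flip_rate <= 1.0:
            raise ValueError("bit_flip_rate must be in [0, 1]")
        if self.fp_bits < 1:
            raise ValueError("fp_bits must be positive")


@dataclass
class LigandLibrary:
    """Label table plus aligned fingerprint matrix.

    ``labels`` columns: ligand_id, class, group; ``fingerprints`` is a
    (n_ligands, fp_bits) uint8 array row-aligned with ``labels``.
    """

    labels: pd.DataFrame
    fingerprints: np.ndarray
    scheme: str = "synthetic"

    def write_labels(self, path: str | Path) -> None:
        self.labels.to_csv(path, index=False)

    def write_fingerprints(self, path: str | Path) -> None:
        bitstrings = ["".join(map(str, row)) for row in self.fingerprints]
        pd.DataFrame(
            {
                "ligand_id": self.labels["ligand_id"],
                "scheme": self.scheme,
                "bitstring": bitstrings,
            }
        ).to_csv(path, index=False)

    @classmethod
    def read(cls, labels_path: str | Path, fp_path: str | Path) -> "LigandLibrary":
        labels = pd.read_csv(labels_path)
        fps = pd.read_csv(fp_path, dtype={"bitstring": str})
        fps = fps.set_index("ligand_id").loc[labels["ligand_id"]]
        mat = np.array(
            [[int(b) for b in s] for s in fps["bitstring"]], dtype=np.uint8
        )
        return cls(labels, mat, scheme=str(fps["scheme"].iloc[0]))


def generate_ligand_library(spec: LibrarySpec | None = None) -> LigandLibrary:
    """Draw the synthetic ligand library.

    Each scaffold group gets a random template bit vector; every member's
    fingerprint flips each template bit independently with probability
    ``bit_flip_rate``. Record order is shuffled (seed-deterministically)
    unless ``spec.shuffle`` is false, so that contiguous cross-validation
    folds mix classes the way an unordered screening library would.
    """
    spec = spec or LibrarySpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    fps = []
    for gname, gclass, gsize in zip(spec.group_names, spec.group_class, spec.group_sizes):
        template = rng.random(spec.fp_bits) < spec.template_density
        for i in range(gsize):
            flips = rng.random(spec.fp_bits) < spec.bit_flip_rate
            fps.append(np.where(flips, ~template, template))
            rows.append(
                {"ligand_id": f"{gname}-{i + 1:02d}", "class": gclass, "group": gname}
            )
    labels = pd.DataFrame(rows)
    mat = np.asarray(fps, dtype=np.uint8)
    if spec.shuffle:
        order = rng.permutation(len(labels))
        labels = labels.iloc[order].reset_index(drop=True)
        mat = mat[order]
    return LigandLibrary(labels, mat)


# --------------------------------------------------------------- trajectory


@dataclass
class TrajectoryGenSpec:
    """Mixture-of-basins model for a synthetic metatrajectory.

    Frame i samples basin k ~ ``basin_weights`` and adds i.i.d. Gaussian
    noise (sd ``noise_sd`` nm per coordinate) to ``basin_centers[k]``.
    """

    basin_centers: np.ndarray  # (n_basins, n_atoms, 3), nm
    basin_weights: np.ndarray
    atom_meta: pd.DataFrame
    n_frames: int = 240
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        self.basin_centers = np.asarray(self.basin_centers, float)
        self.basin_weights = np.asarray(self.basin_weights, float)
        if self.basin_centers.ndim != 3 or self.basin_centers.shape[2] != 3:
            raise ValueError("basin_centers must have shape (n_basins, n_atoms, 3)")
        if len(self.basin_weights) != self.basin_centers.shape[0]:
            raise ValueError("one weight per basin required")
        if abs(self.basin_weights.sum() - 1.0) > 1e-9:
            raise ValueError("basin_weights must sum to 1")
        if (self.basin_weights < 0).any():
            raise ValueError("basin_weights must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def generate_trajectory(
    spec: TrajectoryGenSpec,
) -> tuple[Metatrajectory, np.ndarray]:
    """Sample a metatrajectory; returns (trajectory, true basin per frame)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers = spec.basin_centers
    k = centers.shape[0]
    if k > 1 and spec.noise_sd > 0:
        # plain coordinate RMSD between centers, no fitting: a pessimistic
        # separation check sufficient to flag unrecoverable constructions
        for a in range(k):
            for b in range(a + 1, k):
                sep = np.sqrt(np.mean(np.sum((centers[a] - centers[b]) ** 2, axis=1)))
                if sep < 3 * spec.noise_sd:
                    logger.warning(
                        "basins %d and %d are separated by %.3g nm < 3 x noise_sd; "
                        "recovery not guaranteed",
                        a,
                        b,
                        sep,
                    )
    assignment = rng.choice(k, size=spec.n_frames, p=spec.basin_weights)
    coords = centers[assignment] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_frames,) + centers.shape[1:]
    )
    traj = Metatrajectory(coords, spec.atom_meta.copy(), np.zeros(spec.n_frames, int))
    return traj, assignment


_BACKBONE = (
    ("N", np.array([-0.10, 0.08, 0.00])),
    ("CA", np.array([0.00, 0.00, 0.00])),
    ("C", np.array([0.12, 0.06, 0.02])),
    ("O", np.array([0.14, 0.17, -0.04])),
    ("CB", np.array([0.02, -0.10, 0.12])),
)


def default_trajectory_spec(
    seed: int = 0,
    n_residues: int = 48,
    n_basins: int = 4,
    n_frames: int = 240,
    noise_sd: float = 0.02,
    basin_displacement: float = 0.3,
    n_ligand_atoms: int = 10,
    basin_weights: np.ndarray | None = None,
) -> TrajectoryGenSpec:
    """A ready-made chaperone-like trajectory spec.

    Residues are laid out along a random self-avoiding-ish chain and split
    into three equal sequence blocks labelled N, M and C. A small-molecule
    ligand sits at the M/C boundary so the allosteric-site criterion has
    something to find. Basin 0 is the base geometry; each further basin
    displaces every atom by an independent random vector of length
    ``basin_displacement`` nm, which separates basins under every framework.
    """
    rng = np.random.default_rng(seed)
    # residue trace: cumulative random unit steps of 0.38 nm (CA-CA distance)
    steps = rng.normal(size=(n_residues, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    ca = np.cumsum(0.38 * steps, axis=0)

    third = n_residues // 3
    domains = ["N"] * third + ["M"] * third + ["C"] * (n_residues - 2 * third)
    rows = []
    base = []
    for r in range(n_residues):
        for name, offset in _BACKBONE:
            rows.append(
                {
                    "resid": r + 1,
                    "resname": "ALA",
                    "name": name,
                    "heavy": True,
                    "backbone": name != "CB",
                    "domain": domains[r],
                }
            )
            base.append(ca[r] + offset)
    # ligand centred between the last M and first C residues
    boundary = slice(2 * third - 3, 2 * third + 3)
    lig_center = ca[boundary].mean(axis=0)
    for j in range(n_ligand_atoms):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        rows.append(
            {
                "resid": n_residues + 1,
                "resname": "LIG",
                "name": f"L{j + 1}",
                "heavy": True,
                "backbone": False,
                "domain": "ligand",
            }
        )
        base.append(lig_center + 0.2 * rng.random() * direction)

    base = np.asarray(base)
    n_atoms = base.shape[0]
    centers = np.empty((n_basins, n_atoms, 3))
    centers[0] = base
    for b in range(1, n_basins):
        disp = rng.normal(size=(n_atoms, 3))
        disp /= np.linalg.norm(disp, axis=1, keepdims=True)
        centers[b] = base + basin_displacement * disp

    if basin_weights is None:
        w = np.array([0.40, 0.27, 0.18, 0.15][:n_basins], dtype=float)
        if len(w) < n_basins:
            w = np.concatenate([w, np.full(n_basins - len(w), w[-1])])
        basin_weights = w / w.sum()
    meta = pd.DataFrame(rows)
    return TrajectoryGenSpec(
        basin_centers=centers,
        basin_weights=np.asarray(basin_weights, float),
        atom_meta=meta,
        n_frames=n_frames,
        noise_sd=noise_sd,
        seed=seed,
    )


# ------------------------------------------------------------ docking panel


@dataclass
class PanelGenSpec:
    """Class-conditional docking-score model over a structure panel.

    Each (ligand, structure) pair yields ``n_poses`` scores drawn
    ``Normal(mu, score_sd)`` with ``mu = base_score - class_shift`` when the
    structure index is in the ligand class's preferred set, else
    ``base_score`` (more negative = better). Pose coordinates are a shared
    base ligand geometry plus Gaussian jitter, already expressed in the
    common receptor frame.
    """

    n_structures: int = 14
    base_score: float = -6.0
    class_shift: float = 1.0
    preferred_sets: dict = field(
        default_factory=lambda: {
            ACTIVATOR: tuple(range(0, 6)),
            INHIBITOR: tuple(range(6, 12)),
        }
    )
    score_sd: float = 0.5
    pose_jitter_sd: float = 0.05
    n_poses: int = 10
    n_ligand_atoms: int = 8
    seed: int = 0
    structure_id_override: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.structure_id_override is not None and len(
            self.structure_id_override
        ) != self.n_structures:
            raise ValueError("structure_id_override length != n_structures")
        if self.n_poses < 1:
            raise ValueError("n_poses must be >= 1")
        if self.score_sd < 0 or self.pose_jitter_sd < 0:
            raise ValueError("score_sd and pose_jitter_sd must be >= 0")
        for cls, idxs in self.preferred_sets.items():
            if any(i < 0 or i >= self.n_structures for i in idxs):
                raise ValueError(
                    f"preferred set for {cls!r} not a subset of panel indices"
                )

    @property
    def structure_ids(self) -> list[str]:
        if self.structure_id_override is not None:
            return list(self.structure_id_override)
        return [f"S{i + 1:02d}" for i in range(self.n_structures)]


def _draw_panel_arrays(
    spec: PanelGenSpec, labels: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, dict]:
    spec.validate()
    if labels is None or len(labels) == 0:
        raise ValueError("labels table is empty")
    classes = labels["class"].unique()
    if spec.class_shift > 0:
        for cls in classes:
            if len(spec.preferred_sets.get(cls, ())) == 0:
                raise ValueError(
                    f"class {cls!r} has an empty preferred set but class_shift > 0"
                )

    rng = np.random.default_rng(spec.seed)
    n_lig, n_str, n_pose, n_atom = (
        len(labels),
        spec.n_structures,
        spec.n_poses,
        spec.n_ligand_atoms,
    )
    base_geometry = rng.normal(0.0, 0.15, size=(n_atom, 3))

    # per-(ligand, structure) means: preferred structures dock better
    mu = np.full((n_lig, n_str), spec.base_score)
    for cls in classes:
        lig_mask = (labels["class"] == cls).to_numpy()
        for s in spec.preferred_sets.get(cls, ()):
            mu[lig_mask, s] -= spec.class_shift

    scores = rng.normal(mu[:, :, None], spec.score_sd, size=(n_lig, n_str, n_pose))
    scores.sort(axis=2)  # ascending: best (most negative) first
    coords = base_geometry + rng.normal(
        0.0, spec.pose_jitter_sd, size=(n_lig, n_str, n_pose, n_atom, 3)
    )
    sids = spec.structure_ids
    truth = {
        "preferred_sets": {
            cls: [sids[i] for i in idxs] for cls, idxs in spec.preferred_sets.items()
        },
        "base_score": spec.base_score,
        "class_shift": spec.class_shift,
    }
    return scores, coords, truth


def generate_pose_sets(spec: PanelGenSpec, labels: pd.DataFrame):
    """Draw the docking panel directly as in-memory pose sets.

    Same statistical model as :func:`generate_docking_panel` (and identical
    draws for the same seed); returns ``(list[DockingPoseSet], truth)``
    without materialising the long-format table.
    """
    from .features import DockingPoseSet

    scores, coords, truth = _draw_panel_arrays(spec, labels)
    sids = spec.structure_ids
    pose_sets = [
        DockingPoseSet(str(lig), sid, scores[i, j], coords[i, j])
        for i, lig in enumerate(labels["ligand_id"])
        for j, sid in enumerate(sids)
    ]
    return pose_sets, truth


def generate_docking_panel(
    spec: PanelGenSpec, labels: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Draw a full ligand x structure pose table.

    ``labels`` must carry ``ligand_id`` and ``class`` columns. Returns the
    pose table in the canonical CSV schema
    (ligand_id, structure_id, rank, score, atom_index, x, y, z)
    plus a ground-truth sidecar dict with the preferred sets.
    """
    scores, coords, truth = _draw_panel_arrays(spec, labels)
    n_lig, n_str, n_pose, n_atom = coords.shape[:4]
    sids = spec.structure_ids
    table = pd.DataFrame(
        {
            "ligand_id": np.repeat(labels["ligand_id"].to_numpy(), n_str * n_pose * n_atom),
            "structure_id": np.tile(np.repeat(sids, n_pose * n_atom), n_lig),
            "rank": np.tile(np.repeat(np.arange(1, n_pose + 1), n_atom), n_lig * n_str),
            "score": np.repeat(scores.ravel(), n_atom),
            "atom_index": np.tile(np.arange(n_atom), n_lig * n_str * n_pose),
            "x": coords[..., 0].ravel(),
            "y": coords[..., 1].ravel(),
            "z": coords[..., 2].ravel(),
        }
    )
    return table, truth


def write_truth_sidecar(truth: dict, path: str | Path) -> None:
    """Persist ground-truth generation metadata next to (not inside) inputs."""
    rows = [
        {"class": cls, "structure_id": sid}
        for cls, sids in truth["preferred_sets"].items()
        for sid in sids
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
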