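"""Dynamic-fingerprint feature construction from ensemble-docking poses.

For every ligand and every panel structure three metrics are computed:

* ``best_score`` — the docking score of the rank-1 pose;
* ``score_rms``  — root-mean-square of the scores of the 10 best poses
  (the raw-score RMS; an sd-about-mean variant is available);
* ``pose_spread`` — mean coordinate RMSD of poses 2..10 to the best pose,
  with no refitting since all poses live in the common receptor frame
  (an all-pairs variant is available).

A 14-structure panel therefore yields a 42-column feature matrix. Scores
are negative-is-better throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import StructurePanel

logger = logging.getLogger(__name__)

POSE_CSV_COLUMNS = [
    "ligand_id",
    "structure_id",
    "rank",
    "score",
    "atom_index",
    "x",
    "y",
    "z",
]

METRICS = ("best_score", "score_rms", "pose_spread")


@dataclass
class DockingPoseSet:
    """Ranked poses of one ligand docked into one panel structure.

    ``scores`` are ascending (rank 1 = best = most negative); ``coords`` has
    shape (n_poses, n_atoms, 3) in nm, all poses sharing atom ordering.
    """

    ligand_id: str
    structure_id: str
    scores: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.coords = np.asarray(self.coords, float)
        if self.scores.ndim != 1 or len(self.scores) == 0:
            raise ValueError("scores must be a non-empty 1-D array")
        if np.any(np.diff(self.scores) < -1e-9):
            raise ValueError(
                f"scores not non-decreasing with rank for "
                f"({self.ligand_id}, {self.structure_id})"
            )
        if self.coords.shape[0] != len(self.scores) or self.coords.ndim != 3:
            raise ValueError("coords must have shape (n_poses, n_atoms, 3)")

    @property
    def n_poses(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------- metrics


def best_score(poses: DockingPoseSet) -> float:
    """Docking score of the best (rank-1) pose."""
    return float(poses.scores[0])


def score_rms(poses: DockingPoseSet, n: int = 10, mode: str = "rms") -> float:
    """RMS of the scores of the ``n`` best poses.

    ``mode='rms'`` is the root-mean-square of the raw scores;
    ``mode='sd'`` the standard deviation about their mean (population sd).
    Short pose sets use all available poses (shortfall logged).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    use = poses.scores[: min(n, poses.n_poses)]
    if len(use) < n:
        logger.debug(
            "(%s, %s): only %d poses for score_rms(n=%d)",
            poses.ligand_id,
            poses.structure_id,
            len(use),
            n,
        )
    if mode == "rms":
        return float(np.sqrt(np.mean(use**2)))
    if mode == "sd":
        return float(np.std(use))
    raise ValueError(f"unknown score_rms mode {mode!r}")


def pose_spread(poses: DockingPoseSet, n: int = 10, mode: str = "to_best") -> float:
    """Coordinate RMSD spread of the ``n`` best poses (nm), no refitting.

    ``mode='to_best'``: mean RMSD of poses 2..n to the rank-1 pose.
    ``mode='all_pairs'``: mean over all unordered pose pairs.
    A single pose gives 0 by convention.
    """
    k = min(n, poses.n_poses)
    if k < 2:
        return 0.0
    X = poses.coords[:k]

    def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))

    if mode == "to_best":
        return float(np.mean([_rmsd(X[i], X[0]) for i in range(1, k)]))
    if mode == "all_pairs":
        vals = [_rmsd(X[i], X[j]) for i in range(k) for j in range(i + 1, k)]
        return float(np.mean(vals))
    raise ValueError(f"unknown pose_spread mode {mode!r}")


# ------------------------------------------------------------------- I/O


def pose_sets_from_frame(df: pd.DataFrame) -> list[DockingPoseSet]:
    """Group a long-format pose table into validated pose sets.

    Validates the schema, rank contiguity from 1 and score monotonicity;
    order of first appearance of each ligand is preserved.
    """
    missing = [c for c in POSE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pose table missing columns: {missing}")
    if df[["x", "y", "z"]].isna().any().any():
        raise ValueError("pose table has missing coordinates")
    out: list[DockingPoseSet] = []
    for (lig, sid), grp in df.groupby(["ligand_id", "structure_id"], sort=False):
        pose_ranks = np.sort(grp["rank"].unique())
        expected = np.arange(1, len(pose_ranks) + 1)
        if not np.array_equal(pose_ranks, expected):
            raise ValueError(
                f"({lig}, {sid}): pose ranks {pose_ranks.tolist()} are not "
                f"contiguous from 1"
            )
        grp = grp.sort_values(["rank", "atom_index"])
        n_pose = len(pose_ranks)
        atoms_per = grp.groupby("rank").size().unique()
        if len(atoms_per) != 1:
            raise ValueError(f"({lig}, {sid}): poses have differing atom counts")
        n_atom = int(atoms_per[0])
        scores = grp.groupby("rank")["score"].first().to_numpy()
        coords = grp[["x", "y", "z"]].to_numpy().reshape(n_pose, n_atom, 3)
        out.append(DockingPoseSet(str(lig), str(sid), scores, coords))
    return out


def read_pose_table(path: str | Path, dialect: str = "csv") -> list[DockingPoseSet]:
    """Read docking poses from CSV (canonical schema) or SDF."""
    if dialect == "csv":
        return pose_sets_from_frame(pd.read_csv(path))
    if dialect == "sdf":
        return _read_pose_sdf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_pose_csv(pose_sets: Iterable[DockingPoseSet], path: str | Path) -> None:
    rows = []
    for ps in pose_sets:
        n_atom = ps.coords.shape[1]
        for r in range(ps.n_poses):
            for a in range(n_atom):
                rows.append(
                    (
                        ps.ligand_id,
                        ps.structure_id,
                        r + 1,
                        ps.scores[r],
                        a,
                        *ps.coords[r, a],
                    )
                )
    pd.DataFrame(rows, columns=POSE_CSV_COLUMNS).to_csv(path, index=False)


def write_pose_sdf(pose_sets: Iterable[DockingPoseSet], path: str | Path) -> None:
    """Write one SDF record per pose with LIGAND_ID/STRUCTURE_ID/RANK/SCORE.

    Coordinates are converted nm -> angstrom per SDF convention; atoms are
    written as carbons since synthetic poses carry no element information.
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    with Chem.SDWriter(str(path)) as writer:
        for ps in pose_sets:
            n_atom = ps.coords.shape[1]
            for r in range(ps.n_poses):
                mol = Chem.RWMol()
                for _ in range(n_atom):
                    mol.AddAtom(Chem.Atom(6))
                conf = Chem.Conformer(n_atom)
                for a in range(n_atom):
                    x, y, z = (ps.coords[r, a] * 10.0).tolist()
                    conf.SetAtomPosition(a, Point3D(x, y, z))
                m = mol.GetMol()
                m.AddConformer(conf)
                m.SetProp("LIGAND_ID", ps.ligand_id)
                m.SetProp("STRUCTURE_ID", ps.structure_id)
                m.SetProp("RANK", str(r + 1))
                m.SetProp("SCORE", repr(float(ps.scores[r])))
                writer.write(m)


def _read_pose_sdf(path: str | Path) -> list[DockingPoseSet]:
    from rdkit import Chem

    rows = []
    for mol in Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False):
        if mol is None:
            raise ValueError("unreadable SDF record")
        conf = mol.GetConformer()
        coords = conf.GetPositions() / 10.0
        rows.append(
            {
                "ligand_id": mol.GetProp("LIGAND_ID"),
                "structure_id": mol.GetProp("STRUCTURE_ID"),
                "rank": int(mol.GetProp("RANK")),
                "score": float(mol.GetProp("SCORE")),
                "coords": coords,
            }
        )
    out: list[DockingPoseSet] = []
    df = pd.DataFrame(rows)
    for (lig, sid), grp in df.groupby(["ligand_id", "structure_id"], sort=False):
        grp = grp.sort_values("rank")
        ranks = grp["rank"].to_numpy()
        if not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
            raise ValueError(f"({lig}, {sid}): non-contiguous SDF pose ranks")
        out.append(
            DockingPoseSet(
                str(lig),
                str(sid),
                grp["score"].to_numpy(),
                np.stack(grp["coords"].to_list()),
            )
        )
    return out


# ----------------------------------------------------------- feature matrix


@dataclass
class FeatureMatrix:
    """Ligands x (panel structures x 3 metrics) table plus optional labels."""

    X: pd.DataFrame
    labels: pd.Series | None = None
    imputed: list = field(default_factory=list)
    excluded: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def metric_columns(self, metric: str) -> list[str]:
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        return [c for c in self.X.columns if c.endswith("." + metric)]

    def to_csv(self, path: str | Path) -> None:
        out = self.X.copy()
        if self.labels is not None:
            out.insert(0, "class", self.labels)
        out.to_csv(path, index_label="ligand_id")


def build_feature_matrix(
    pose_sets: Sequence[DockingPoseSet],
    panel: StructurePanel | Sequence[str],
    labels: pd.DataFrame | None = None,
    impute_policy: str = "penalty",
    n_poses: int = 10,
    rms_mode: str = "rms",
    spread_mode: str = "to_best",
) -> FeatureMatrix:
    """Assemble the dynamic-fingerprint matrix in panel column order.

    Columns are ``<structure_id>.<metric>`` blocks in panel order. Missing
    (ligand, structure) cells are filled per ``impute_policy``:

    * ``'penalty'`` — best_score 0.0 (no favourable binding), score_rms 0.0,
      pose_spread = maximum observed spread (worst structural adaptation);
    * ``'error'`` — raise.

    Ligands with no pose set for any structure are excluded with a warning.
    ``labels`` (columns ligand_id, class), when given, fixes the row order
    and provides the class column; otherwise rows follow first appearance.
    """
    sids = panel.structure_ids if isinstance(panel, StructurePanel) else list(panel)
    by_key = {(ps.ligand_id, ps.structure_id): ps for ps in pose_sets}
    unknown = {s for (_, s) in by_key} - set(sids)
    if unknown:
        raise ValueError(f"pose sets reference structures not in panel: {sorted(unknown)}")

    if labels is not None:
        ligands = labels["ligand_id"].tolist()
    else:
        seen: dict[str, None] = {}
        for ps in pose_sets:
            seen.setdefault(ps.ligand_id, None)
        ligands = list(seen)

    excluded = [
        lig for lig in ligands if not any((lig, s) in by_key for s in sids)
    ]
    for lig in excluded:
        warnings.warn(f"ligand {lig!r} has no pose sets anywhere; excluded")
    ligands = [lig for lig in ligands if lig not in excluded]

    columns = [f"{sid}.{m}" for sid in sids for m in METRICS]
    data = np.full((len(ligands), len(columns)), np.nan)
    imputed: list[tuple[str, str]] = []
    for i, lig in enumerate(ligands):
        for j, sid in enumerate(sids):
            ps = by_key.get((lig, sid))
            if ps is None:
                imputed.append((lig, sid))
                continue
            data[i, 3 * j] = best_score(ps)
            data[i, 3 * j + 1] = score_rms(ps, n=n_poses, mode=rms_mode)
            data[i, 3 * j + 2] = pose_spread(ps, n=n_poses, mode=spread_mode)

    if imputed:
        if impute_policy == "error":
            raise ValueError(f"missing pose sets for {imputed[:5]}...")
        if impute_policy != "penalty":
            raise ValueError(f"unknown impute policy {impute_policy!r}")
        spread_cols = np.arange(2, len(columns), 3)
        observed = data[:, spread_cols]
        max_spread = np.nanmax(observed) if np.isfinite(observed).any() else 0.0
        lig_pos = {lig: i for i, lig in enumerate(ligands)}
        sid_pos = {sid: j for j, sid in enumerate(sids)}
        for lig, sid in imputed:
            i, j = lig_pos[lig], sid_pos[sid]
            data[i, 3 * j : 3 * j + 2] = 0.0
            data[i, 3 * j + 2] = max_spread
            logger.info("imputed (%s, %s) with penalty policy", lig, sid)

    X = pd.DataFrame(data, index=pd.Index(ligands, name="ligand_id"), columns=columns)
    y = None
    if labels is not None:
        y = labels.set_index("ligand_id")["class"].loc[ligands]
    return FeatureMatrix(X, y, imputed, excluded)


def read_feature_csv(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col="ligand_id")
    labels = None
    if "class" in df.columns:
        labels = df.pop("class")
    return FeatureMatrix(df, labels)
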