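"""Conformational-panel construction from a metatrajectory.

The panel is built by geometric cluster analysis of the metatrajectory under
several atom "frameworks" (atom subsets used both for rigid superposition and
for the RMSD): the backbone of the N-terminal domain (Clust-N), of the middle
domain (Clust-M), of N+M (Clust-NM), of M+C (Clust-MC), and the heavy atoms
of the allosteric-site residues (Site). Clustering uses the Gromos (Daura)
neighbour-count algorithm; the panel collects the representatives of the
``n_top`` most populated clusters per domain framework plus the ``n_site``
main site-framework representatives.

All distances are in nm. RMSD is unweighted (no atomic masses).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .trajectory import Metatrajectory

logger = logging.getLogger(__name__)

DOMAIN_FRAMEWORKS = ("Clust-N", "Clust-M", "Clust-NM", "Clust-MC")
SITE_FRAMEWORK = "Site"

#: default Gromos cutoff in nm (midpoint of the conventional 0.2-0.25 nm band)
DEFAULT_CUTOFF = 0.225

_FRAMEWORK_DOMAINS = {
    "Clust-N": ("N",),
    "Clust-M": ("M",),
    "Clust-NM": ("N", "M"),
    "Clust-MC": ("M", "C"),
}


@dataclass(frozen=True)
class AtomFramework:
    """Named atom subset used for superposition and RMSD."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=int))
        if self.indices.size == 0:
            raise ValueError(f"framework {self.name!r} selects no atoms")


def make_framework(
    name: str,
    atom_meta: pd.DataFrame,
    site_residues: Sequence[int] | None = None,
    selector: Callable[[pd.DataFrame], np.ndarray] | None = None,
) -> AtomFramework:
    """Build one of the standard frameworks, or a custom one via ``selector``.

    Domain frameworks select backbone atoms of the named domain(s); the Site
    framework selects the heavy protein atoms of ``site_residues`` (as
    returned by :func:`binding_site_residues`).
    """
    if selector is not None:
        mask = np.asarray(selector(atom_meta), dtype=bool)
    elif name in _FRAMEWORK_DOMAINS:
        doms = _FRAMEWORK_DOMAINS[name]
        mask = (atom_meta["backbone"] & atom_meta["domain"].isin(doms)).to_numpy()
    elif name == SITE_FRAMEWORK:
        if site_residues is None:
            raise ValueError("Site framework requires site_residues")
        mask = (
            atom_meta["heavy"]
            & (atom_meta["domain"] != "ligand")
            & atom_meta["resid"].isin(site_residues)
        ).to_numpy()
    else:
        raise ValueError(f"unknown framework {name!r}")
    return AtomFramework(name, np.flatnonzero(mask))


# --------------------------------------------------------------- superposition


def superpose(
    reference: np.ndarray, mobile: np.ndarray, subset: Sequence[int] | None = None
) -> tuple[np.ndarray, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    The optimal rotation (proper, no reflection) and translation are computed
    on the ``subset`` atoms (Kabsch); the full mobile coordinate set is
    transformed and the RMSD over the subset after fitting is returned.

    Returns ``(fitted_mobile, rmsd_nm)``.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape:
        raise ValueError("reference and mobile shapes differ")
    sub = np.arange(ref.shape[0]) if subset is None else np.asarray(subset, int)
    if sub.size < 3:
        raise ValueError("superposition needs at least 3 subset atoms")
    P = mob[sub]
    Q = ref[sub]
    p0, q0 = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - p0, Q - q0
    if min(np.linalg.matrix_rank(Pc, tol=1e-9), np.linalg.matrix_rank(Qc, tol=1e-9)) < 2:
        raise ValueError("subset atoms are collinear; fit underdetermined")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    fitted = (mob - p0) @ R.T + q0
    rmsd = float(np.sqrt(np.mean(np.sum((fitted[sub] - ref[sub]) ** 2, axis=1))))
    return fitted, rmsd


def pairwise_rmsd_matrix(
    traj: Metatrajectory | np.ndarray, framework: AtomFramework | Sequence[int]
) -> np.ndarray:
    """All-vs-all superposed RMSD on the framework atoms (nm).

    Uses the closed-form Kabsch objective (batched 3x3 SVDs), so only the
    RMSD — not the fitted coordinates — is materialised per pair.
    """
    coords = traj.coords if isinstance(traj, Metatrajectory) else np.asarray(traj)
    idx = framework.indices if isinstance(framework, AtomFramework) else np.asarray(framework, int)
    if idx.size < 3:
        raise ValueError("framework must select at least 3 atoms")
    X = coords[:, idx, :]
    X = X - X.mean(axis=1, keepdims=True)
    n, a, _ = X.shape
    G = np.einsum("iak,iak->i", X, X)
    out = np.zeros((n, n))
    # chunk rows to bound the (chunk, n, 3, 3) covariance tensor
    chunk = max(1, int(2e7 // (9 * n)) or 1)
    for s in range(0, n, chunk):
        e = min(n, s + chunk)
        H = np.einsum("iak,jal->ijkl", X[s:e], X)
        sv = np.linalg.svd(H, compute_uv=False)
        det = np.linalg.det(H)
        best = sv[..., 0] + sv[..., 1] + np.sign(det) * sv[..., 2]
        msd = (G[s:e, None] + G[None, :] - 2.0 * best) / a
        out[s:e] = np.sqrt(np.clip(msd, 0.0, None))
    np.fill_diagonal(out, 0.0)
    return 0.5 * (out + out.T)  # enforce exact symmetry against FP jitter


# ------------------------------------------------------------------ clustering


@dataclass
class ClusterResult:
    """Partition of frames produced by Gromos clustering.

    ``assignment`` maps every frame to a cluster id (formation order);
    ``representatives[c]`` is the central frame of cluster ``c``;
    ``populations[c]`` its frame count.
    """

    assignment: np.ndarray
    representatives: np.ndarray
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, int)
        self.representatives = np.asarray(self.representatives, int)
        self.populations = np.asarray(self.populations, int)
        if (self.assignment < 0).any():
            raise ValueError("every frame must be assigned (no -1 labels)")
        if self.populations.sum() != self.assignment.size:
            raise ValueError("populations do not sum to n_frames")
        for c, rep in enumerate(self.representatives):
            if self.assignment[rep] != c:
                raise ValueError("representative not a member of its cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def to_frame(self) -> pd.DataFrame:
        reps = set(self.representatives.tolist())
        return pd.DataFrame(
            {
                "frame": np.arange(self.assignment.size),
                "cluster": self.assignment,
                "is_representative": [
                    f in reps for f in range(self.assignment.size)
                ],
            }
        )


def gromos_cluster(rmsd: np.ndarray, cutoff: float) -> ClusterResult:
    """Gromos (Daura) neighbour-count clustering of an RMSD matrix.

    Repeatedly take, among still-unassigned frames, the frame with the most
    unassigned neighbours within ``cutoff`` (ties broken toward the lowest
    frame index); that frame becomes the cluster representative and, with its
    neighbours, forms the cluster, which is then removed. Clusters come out
    in formation order, i.e. by descending population up to late ties.
    """
    rmsd = np.asarray(rmsd, dtype=float)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if rmsd.ndim != 2 or rmsd.shape[0] != rmsd.shape[1]:
        raise ValueError("RMSD matrix must be square")
    if not np.allclose(rmsd, rmsd.T, atol=1e-9):
        raise ValueError("RMSD matrix must be symmetric")
    if np.abs(np.diag(rmsd)).max(initial=0.0) > 1e-9:
        raise ValueError("RMSD matrix must have a zero diagonal")

    n = rmsd.shape[0]
    adj = rmsd <= cutoff
    np.fill_diagonal(adj, True)
    assignment = np.full(n, -1, dtype=int)
    reps: list[int] = []
    pops: list[int] = []
    unassigned = np.ones(n, dtype=bool)
    cid = 0
    while unassigned.any():
        idx = np.flatnonzero(unassigned)
        counts = adj[np.ix_(idx, idx)].sum(axis=1)
        center = int(idx[int(np.argmax(counts))])  # argmax -> lowest index on tie
        members = idx[adj[center, idx]]
        assignment[members] = cid
        unassigned[members] = False
        reps.append(center)
        pops.append(len(members))
        cid += 1
    return ClusterResult(assignment, np.array(reps), np.array(pops))


# ----------------------------------------------------------------- panel


@dataclass
class StructurePanel:
    """Ordered list of representative structures with provenance.

    ``entries`` columns: structure_id, framework, cluster_rank (1-based),
    population_fraction, frame_index.
    """

    entries: pd.DataFrame

    @property
    def size(self) -> int:
        return len(self.entries)

    @property
    def structure_ids(self) -> list[str]:
        return self.entries["structure_id"].tolist()

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def select_panel(
    domain_results: Mapping[str, ClusterResult],
    site_result: ClusterResult,
    n_top: int = 3,
    n_site: int = 2,
    min_top_fraction: float = 0.45,
) -> StructurePanel:
    """Assemble the docking panel from per-framework clusterings.

    Takes the representatives of the ``n_top`` most populated clusters per
    domain framework (in the order the mapping lists them) plus the first
    ``n_site`` site-framework representatives. Population ties keep formation
    order. Logs a warning when the top-``n_top`` clusters of a framework hold
    less than ``min_top_fraction`` of the frames.
    """
    rows = []

    def _top(result: ClusterResult, name: str, k: int) -> None:
        if result.n_clusters < k:
            raise ValueError(
                f"framework {name!r} produced only {result.n_clusters} clusters; "
                f"{k} required"
            )
        order = np.lexsort((np.arange(result.n_clusters), -result.populations))
        total = result.populations.sum()
        frac_top = result.populations[order[:k]].sum() / total
        if frac_top < min_top_fraction:
            logger.warning(
                "framework %s: top-%d clusters cover only %.1f%% of frames",
                name,
                k,
                100 * frac_top,
            )
        for rank, c in enumerate(order[:k], start=1):
            rows.append(
                {
                    "structure_id": f"{name}.c{rank}",
                    "framework": name,
                    "cluster_rank": rank,
                    "population_fraction": result.populations[c] / total,
                    "frame_index": int(result.representatives[c]),
                }
            )

    for name, result in domain_results.items():
        _top(result, name, n_top)
    _top(site_result, SITE_FRAMEWORK, n_site)
    entries = pd.DataFrame(rows)
    if entries["structure_id"].duplicated().any():
        raise ValueError("duplicate structure ids in panel")
    return StructurePanel(entries)


# ------------------------------------------------------------- binding site


def binding_site_residues(
    traj: Metatrajectory, dist_cutoff: float = 1.0, frac: float = 0.75
) -> np.ndarray:
    """Residues in ligand contact persistently enough to define the site.

    A residue is included iff, in at least ``frac`` (inclusive) of all
    frames, the minimum heavy-atom distance between the residue and any
    ligand heavy atom is at most ``dist_cutoff`` (inclusive), in nm.
    """
    meta = traj.atom_meta
    lig_mask = ((meta["domain"] == "ligand") & meta["heavy"]).to_numpy()
    if not lig_mask.any():
        raise ValueError("trajectory contains no ligand heavy atoms")
    prot_mask = ((meta["domain"] != "ligand") & meta["heavy"]).to_numpy()
    prot_idx = np.flatnonzero(prot_mask)
    lig_idx = np.flatnonzero(lig_mask)
    resids = meta["resid"].to_numpy()[prot_idx]
    unique_res = np.unique(resids)
    pos = np.searchsorted(unique_res, resids)

    hits = np.zeros(len(unique_res), dtype=int)
    for frame in traj.coords:
        d_atom = cdist(frame[prot_idx], frame[lig_idx]).min(axis=1)
        d_res = np.full(len(unique_res), np.inf)
        np.minimum.at(d_res, pos, d_atom)
        hits += d_res <= dist_cutoff
    frac_in = hits / traj.n_frames
    return unique_res[frac_in >= frac - 1e-12]
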