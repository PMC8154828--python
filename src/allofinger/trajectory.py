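"""Metatrajectory container and plain-text trajectory I/O.

A metatrajectory is the concatenation of one or more MD replicas into a
single ordered frame sequence, sharing one atom-metadata table. Coordinates
are stored in nanometres throughout; PDB files (which are in angstroms) are
converted on read/write.

Domain labels (N-terminal, middle, C-terminal domain, or bound ligand) are
round-tripped through the PDB chain identifier, since the PDB format has no
native slot for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ATOM_META_COLUMNS = ["resid", "resname", "name", "heavy", "backbone", "domain"]
DOMAINS = ("N", "M", "C", "ligand")

# domain <-> PDB chain id mapping used by to_pdb / from_pdb
_DOMAIN_CHAIN = {"N": "A", "M": "B", "C": "C", "ligand": "L"}
_CHAIN_DOMAIN = {v: k for k, v in _DOMAIN_CHAIN.items()}

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


@dataclass
class Metatrajectory:
    """Ordered frames of atom coordinates plus per-atom metadata.

    Parameters
    ----------
    coords:
        Array of shape ``(n_frames, n_atoms, 3)``, in nm.
    atom_meta:
        DataFrame with columns ``resid, resname, name, heavy, backbone,
        domain`` shared by all frames.
    provenance:
        Optional per-frame source replica id (kept through concatenation).
    """

    coords: np.ndarray
    atom_meta: pd.DataFrame
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        missing = [c for c in ATOM_META_COLUMNS if c not in self.atom_meta.columns]
        if missing:
            raise ValueError(f"atom_meta missing columns: {missing}")
        if len(self.atom_meta) != self.coords.shape[1]:
            raise ValueError("atom_meta length does not match n_atoms")
        bad = set(self.atom_meta["domain"]) - set(DOMAINS)
        if bad:
            raise ValueError(f"unknown domain labels: {sorted(bad)}")
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance)
            if len(self.provenance) != self.n_frames:
                raise ValueError("provenance length does not match n_frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @staticmethod
    def concatenate(parts: list["Metatrajectory"]) -> "Metatrajectory":
        """Concatenate replicas in the order given (no reweighting)."""
        if not parts:
            raise ValueError("no trajectories to concatenate")
        meta = parts[0].atom_meta
        for p in parts[1:]:
            if not p.atom_meta[ATOM_META_COLUMNS].equals(meta[ATOM_META_COLUMNS]):
                raise ValueError("replicas do not share atom metadata")
        coords = np.concatenate([p.coords for p in parts], axis=0)
        prov = np.concatenate(
            [
                p.provenance
                if p.provenance is not None
                else np.full(p.n_frames, i)
                for i, p in enumerate(parts)
            ]
        )
        return Metatrajectory(coords, meta.copy(), prov)

    # ------------------------------------------------------------------ PDB

    def to_pdb(self, path: str | Path) -> None:
        """Write a multi-model PDB (one MODEL per frame, coordinates in A)."""
        import MDAnalysis as mda

        meta = self.atom_meta
        res_key = meta[["resid", "resname", "domain"]].drop_duplicates()
        res_index = {
            tuple(row): i for i, row in enumerate(res_key.itertuples(index=False))
        }
        atom_resindex = np.array(
            [
                res_index[(r.resid, r.resname, r.domain)]
                for r in meta.itertuples(index=False)
            ]
        )
        u = mda.Universe.empty(
            self.n_atoms,
            n_residues=len(res_key),
            atom_resindex=atom_resindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", meta["name"].tolist())
        u.add_TopologyAttr("resnames", res_key["resname"].tolist())
        u.add_TopologyAttr("resids", res_key["resid"].tolist())
        u.add_TopologyAttr(
            "chainIDs", [_DOMAIN_CHAIN[d] for d in meta["domain"]]
        )
        u.load_new(self.coords * 10.0, order="fac")
        with mda.Writer(str(path), multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)

    @classmethod
    def from_pdb(cls, path: str | Path) -> "Metatrajectory":
        """Read a multi-model PDB written by :meth:`to_pdb` (or compatible)."""
        import MDAnalysis as mda

        u = mda.Universe(str(path))
        names = [a.name for a in u.atoms]
        chain = [getattr(a, "chainID", "A") for a in u.atoms]
        domains = [_CHAIN_DOMAIN.get(c, "N") for c in chain]
        meta = pd.DataFrame(
            {
                "resid": [a.resid for a in u.atoms],
                "resname": [a.resname for a in u.atoms],
                "name": names,
                "heavy": [not n.startswith("H") for n in names],
                "backbone": [
                    n in _BACKBONE_NAMES and d != "ligand"
                    for n, d in zip(names, domains)
                ],
                "domain": domains,
            }
        )
        coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory]) / 10.0
        return cls(coords, meta)

    # ------------------------------------------------------------------ CSV

    def to_csv(self, coord_path: str | Path, meta_path: str | Path) -> None:
        """Write long-format coordinates (frame,atom,x,y,z in nm) + metadata."""
        n_f, n_a = self.n_frames, self.n_atoms
        df = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n_f), n_a),
                "atom": np.tile(np.arange(n_a), n_f),
                "x": self.coords[:, :, 0].ravel(),
                "y": self.coords[:, :, 1].ravel(),
                "z": self.coords[:, :, 2].ravel(),
            }
        )
        df.to_csv(coord_path, index=False)
        self.atom_meta.to_csv(meta_path, index=False)

    @classmethod
    def from_csv(
        cls, coord_path: str | Path, meta_path: str | Path
    ) -> "Metatrajectory":
        df = pd.read_csv(coord_path)
        meta = pd.read_csv(meta_path)
        n_f = int(df["frame"].max()) + 1
        n_a = int(df["atom"].max()) + 1
        coords = np.full((n_f, n_a, 3), np.nan)
        coords[df["frame"], df["atom"], :] = df[["x", "y", "z"]].to_numpy()
        if np.isnan(coords).any():
            raise ValueError("trajectory CSV has missing (frame, atom) entries")
        return cls(coords, meta)
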