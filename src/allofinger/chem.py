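"""Chemical-similarity baseline: can fingerprints alone separate the classes?

The dynamics-free control for the dynamic-fingerprint classifier: ligands
are represented by binary substructure fingerprints (ECFP-like, MACCS-like,
or the synthetic generator's group-template vectors), compared by Tanimoto
similarity, segmented by k-means for k = 2..6, and scored per scaffold group
by the fraction of members "correctly separated" — i.e. sitting in the
cluster that holds the majority of their class.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .screen import PurityResult, kmeans_segment, purity

logger = logging.getLogger(__name__)


def tanimoto(a: Sequence[int], b: Sequence[int]) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two bit vectors.

    Two all-zero vectors are defined as identical (similarity 1, logged).
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint lengths differ: {a.shape} vs {b.shape}")
    union = np.sum(a | b)
    if union == 0:
        logger.info("both fingerprints empty; Tanimoto defined as 1.0")
        return 1.0
    return float(np.sum(a & b) / union)


def fingerprints_from_smiles(
    smiles: Sequence[str], scheme: str = "ECFP", n_bits: int = 1024, radius: int = 2
) -> np.ndarray:
    """Adapter: real molecules -> bit-vector matrix via RDKit.

    ``scheme`` is ``'ECFP'`` (Morgan, circular) or ``'MACCS'`` (166
    structural keys; ``n_bits`` ignored). The rest of the pipeline treats
    the result as opaque bits, exactly like synthetic fingerprints.
    """
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys
    from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator

    mols = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {s!r}")
        mols.append(mol)
    if scheme == "ECFP":
        gen = GetMorganGenerator(radius=radius, fpSize=n_bits)
        return np.array([np.array(gen.GetFingerprint(m)) for m in mols], dtype=np.uint8)
    if scheme == "MACCS":
        return np.array(
            [np.array(MACCSkeys.GenMACCSKeys(m)) for m in mols], dtype=np.uint8
        )
    raise ValueError(f"unknown fingerprint scheme {scheme!r}")


def cluster_fingerprints(
    fingerprints: np.ndarray,
    labels: Sequence[str],
    k_range: Iterable[int] = range(2, 7),
    seed: int = 0,
) -> dict[int, tuple[np.ndarray, PurityResult]]:
    """k-means segmentation of bit vectors with class contingency per k.

    Euclidean distance on 0/1 vectors (monotone in Hamming distance) for
    parity with the feature-space clustering. Returns, per k, the
    assignment and a :class:`PurityResult` whose contingency table is in
    cluster x class layout.
    """
    fps = np.asarray(fingerprints, float)
    out = {}
    for k in k_range:
        assign = kmeans_segment(fps, k, seed=seed)
        out[k] = (assign, purity(assign, labels, algorithm=f"kmeans-fp-k{k}"))
    return out


def contingency_table(results: dict[int, tuple[np.ndarray, PurityResult]]) -> pd.DataFrame:
    """Stack per-k contingencies into one tidy table (k, cluster, class counts)."""
    rows = []
    for k, (_, res) in sorted(results.items()):
        for cluster, counts in res.contingency.iterrows():
            rows.append({"k": k, "cluster": int(cluster), **counts.to_dict()})
    return pd.DataFrame(rows)


def group_fraction_correct(
    values: Sequence,
    labels: Sequence[str],
    groups: Sequence[str],
    mode: str = "cluster",
    method: str | None = None,
) -> pd.DataFrame:
    """Per-scaffold-group fraction of correctly separated/predicted ligands.

    ``mode='cluster'``: ``values`` is a 2-cluster assignment; a ligand is
    correct iff its cluster is the one holding the majority of its class
    (a class split evenly between the clusters counts both as correct,
    logged). ``mode='classifier'``: ``values`` are predicted labels; correct
    iff prediction equals the true label.

    Returns a table (group, method, n, n_correct, fraction_correct).
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if not (len(values) == len(labels) == len(groups)):
        raise ValueError("values, labels and groups must have equal lengths")

    if mode == "cluster":
        clusters = np.unique(values)
        if len(clusters) != 2:
            raise ValueError("cluster mode requires a 2-cluster assignment")
        correct = np.zeros(len(labels), bool)
        for cls in np.unique(labels):
            in_cls = labels == cls
            counts = {c: int(np.sum(in_cls & (values == c))) for c in clusters}
            top = max(counts.values())
            majority = {c for c, v in counts.items() if v == top}
            if len(majority) > 1:
                logger.info("class %r split evenly; both clusters count as correct", cls)
            correct |= in_cls & np.isin(values, list(majority))
        method = method or "fingerprint-cluster"
    elif mode == "classifier":
        correct = values == labels
        method = method or "classifier"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for g in pd.unique(groups):
        mask = groups == g
        rows.append(
            {
                "group": g,
                "method": method,
                "n": int(mask.sum()),
                "n_correct": int(correct[mask].sum()),
                "fraction_correct": float(correct[mask].mean()),
            }
        )
    return pd.DataFrame(rows)
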