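"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from allofinger.features import build_feature_matrix
from allofinger.synthetic import (
    LibrarySpec,
    PanelGenSpec,
    generate_ligand_library,
    generate_pose_sets,
)


@pytest.fixture(scope="session")
def library():
    """Default 133-ligand library, fixed seed."""
    return generate_ligand_library(LibrarySpec(seed=7))


def make_features(labels, class_shift=1.0, seed=0, **kw):
    spec = PanelGenSpec(class_shift=class_shift, seed=seed, **kw)
    pose_sets, _ = generate_pose_sets(spec, labels)
    return build_feature_matrix(pose_sets, spec.structure_ids, labels=labels)


@pytest.fixture(scope="session")
def signal_features(library):
    """Feature matrix with the strong conformational-selection signal."""
    return make_features(library.labels, class_shift=1.0, seed=11)


@pytest.fixture(scope="session")
def null_features(library):
    """Feature matrix with no class signal (class_shift = 0)."""
    return make_features(library.labels, class_shift=0.0, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
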