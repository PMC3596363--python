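"""Shared fixtures: built models and canonical poses reused across modules."""

import pytest

from cannmotif.builder import make_model, motif_residues_for
from cannmotif.synthetic import generate_canonical_pose, generate_pose_ensemble


@pytest.fixture(scope="session")
def motif():
    return motif_residues_for("CPS224Ac")


@pytest.fixture(scope="session")
def native_structure():
    return make_model("CPS224Ac", "native")


@pytest.fixture(scope="session")
def extended_structure():
    return make_model("CPS224Ac", "extended")


@pytest.fixture(scope="session")
def canonical_pose(native_structure, motif):
    """(structure, placed anion, achieved geometry) for the default targets."""
    return generate_canonical_pose(
        native_structure, motif, "sulfate", seed=1
    )


@pytest.fixture(scope="session")
def small_ensemble(canonical_pose, motif):
    structure, anion, _ = canonical_pose
    return generate_pose_ensemble(
        structure, anion, n=60, noise_translation=0.02, noise_rotation=1.0, seed=7
    )
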