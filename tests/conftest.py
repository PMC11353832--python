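"""Shared fixtures: synthetic bones and hands generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from handlink import synthetic as syn
from handlink.axes import joint_axis_from_mesh


@pytest.fixture(scope="session")
def pp_bone():
    """Deformity-free proximal phalanx at the default 0.4 mm grid."""
    return syn.generate_bone(syn.DEFAULT_BONE_PARAMS["pp"], 0.4, name="pp")


@pytest.fixture(scope="session")
def mc_fit():
    """Metacarpal with its fitted joint axis/frame: the proximal-joint
    reference for deformity measurements."""
    mesh, truth = syn.generate_bone(syn.DEFAULT_BONE_PARAMS["mc"], 0.4, name="mc")
    axis, frame, circles = joint_axis_from_mesh(mesh, truth.landmarks())
    return mesh, truth, axis, frame


@pytest.fixture(scope="session")
def mal12(pp_bone):
    """Proximal phalanx with a 12 degree pure transverse malunion."""
    _, truth = pp_bone
    spec = syn.DeformitySpec("pp", 0.5, 12.0)
    return syn.impose_malunion(truth, spec, 0.4) + (spec,)


@pytest.fixture(scope="session")
def hand_clean():
    """Deformity-free 4-digit hand with its ground truth."""
    return syn.generate_hand()


@pytest.fixture(scope="session")
def hand_deformed20():
    """4-digit hand with a 20 degree rotational malunion of the index
    proximal phalanx."""
    return syn.generate_hand(
        deformities=[syn.DeformitySpec("index_pp", 0.5, 20.0)]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240821)
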