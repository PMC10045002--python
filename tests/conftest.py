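"""Shared fixtures: one standard phantom and its derived products."""

from __future__ import annotations

import numpy as np
import pytest

import sympose as sp


@pytest.fixture(scope="session")
def phantom() -> sp.Phantom:
    """Perfectly mirror-symmetric phantom on the default 64^3 / 0.5 mm grid."""
    return sp.make_phantom(sp.PhantomSpec())


@pytest.fixture(scope="session")
def phantom_mesh(phantom) -> sp.TriangleMesh:
    return sp.extract_mesh(phantom.volume)


@pytest.fixture(scope="session")
def phantom_frame(phantom, phantom_mesh) -> sp.PlaneFrame:
    return sp.local_frame(phantom_mesh, phantom.true_plane)


@pytest.fixture(scope="session")
def phantom_contour(phantom_mesh, phantom_frame) -> sp.Contour2D:
    yz = sp.project_to_plane(phantom_mesh, phantom_frame)
    return sp.trace_contour(yz, 0.5)


def rot2d(theta_deg: float) -> np.ndarray:
    t = np.radians(theta_deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
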