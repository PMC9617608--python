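"""Shared fixtures: analytic tube/torus/Y volumes and a cached phantom."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from spinemesh.segmentation import BinarizedVolume
from spinemesh.synthetic import (
    SpinePhantomSpec,
    generate_spine_geometry,
    grow_network,
)


def tube_mask(shape, p0, p1, radius):
    """Solid tube between two points (voxel coordinates)."""
    idx = np.stack(np.indices(shape), -1).astype(float)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    L = np.linalg.norm(d)
    u = d / L
    t = np.clip((idx - p0) @ u, 0, L)
    closest = p0 + t[..., None] * u
    return np.linalg.norm(idx - closest, axis=-1) <= radius


@pytest.fixture(scope="session")
def straight_tube():
    m = tube_mask((21, 21, 60), (10, 10, 2), (10, 10, 57), 4.0)
    return BinarizedVolume(m, voxel_pitch=2.0)


@pytest.fixture(scope="session")
def torus():
    shape = (17, 48, 48)
    zz, yy, xx = np.indices(shape)
    rad = np.sqrt((yy - 24.0) ** 2 + (xx - 24.0) ** 2)
    m = ((rad - 15.0) ** 2 + (zz - 8.0) ** 2) <= 16.0
    return BinarizedVolume(m, voxel_pitch=2.0)


@pytest.fixture(scope="session")
def y_junction():
    shape = (25, 50, 50)
    m = (
        tube_mask(shape, (12, 45, 25), (12, 25, 25), 3.5)
        | tube_mask(shape, (12, 25, 25), (12, 8, 10), 3.5)
        | tube_mask(shape, (12, 25, 25), (12, 8, 40), 3.5)
    )
    return BinarizedVolume(m, voxel_pitch=2.0)


@pytest.fixture(scope="session")
def small_phantom():
    """Small spine phantom with its ground-truth network (no cross-links:
    the truth graph is a forest, convenient for topology checks)."""
    spec = SpinePhantomSpec(
        head_radius=60.0,
        neck_length=70.0,
        neck_radius=30.0,
        crosslink_rate=0.0,
    )
    mask = generate_spine_geometry(spec, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = grow_network(mask, spec, seed=12)
    return spec, mask, net


@pytest.fixture(scope="session")
def crosslinked_phantom():
    spec = SpinePhantomSpec(
        head_radius=60.0,
        neck_length=70.0,
        neck_radius=30.0,
        crosslink_rate=0.4,
        min_branch_spacing=12.0,
        target_node_density=9e4,
    )
    mask = generate_spine_geometry(spec, seed=21)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = grow_network(mask, spec, seed=22)
    return spec, mask, net
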