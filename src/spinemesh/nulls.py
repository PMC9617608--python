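"""Analytic and Monte-Carlo reference models.

These null models give the reference values against which the measured
network statistics are judged: the sin(alpha) orientation law for randomly
oriented filaments, the sorted-angle statistics of random 3-way branching,
the rigid-rod orientation constraint near a flat membrane, the Euler
buckling force, the isosceles-triangle reading of tortuosity, and the
random placement reference for branch-end clustering.

Uniform directions are sampled as normalized 3D Gaussian draws, which is
exactly uniform on the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class PhysicalConstants:
    kappa: float = 0.040  # flexural rigidity of F-actin, pN um^2
    filament_diameter: float = 8.0  # nm
    rod_length: float = 15.4  # nm, mean inter-node spacing

    def __post_init__(self) -> None:
        if min(self.kappa, self.filament_diameter, self.rod_length) <= 0:
            raise ValueError("physical constants must be positive")


def random_orientation_reference() -> float:
    """Mean angle (degrees) between a random direction and a fixed axis,
    folded to [0, 90]: the density is sin(alpha), so the mean is exactly
    one radian (57.2958 degrees)."""
    return float(np.degrees(1.0))


def random_orientation_density(alpha_deg: np.ndarray) -> np.ndarray:
    """sin(alpha) density on [0, 90] degrees, normalized to unit integral."""
    a = np.radians(np.asarray(alpha_deg, dtype=float))
    return np.sin(a) * np.pi / 180.0


def uniform_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def random_branching_angle_reference(
    n: int = 100_000, seed: int = 0
) -> dict[str, np.ndarray]:
    """Sorted pairwise angles of triples of independent uniform unit
    vectors: Monte-Carlo means and SDs for the smallest, intermediate and
    largest angle (degrees)."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    u = uniform_unit_vectors(3 * n, rng).reshape(n, 3, 3)
    dots = np.clip(
        np.stack(
            [
                np.sum(u[:, 0] * u[:, 1], axis=1),
                np.sum(u[:, 0] * u[:, 2], axis=1),
                np.sum(u[:, 1] * u[:, 2], axis=1),
            ],
            axis=1,
        ),
        -1.0,
        1.0,
    )
    angles = np.degrees(np.arccos(dots))
    angles.sort(axis=1)
    return {
        "means": angles.mean(axis=0),
        "sds": angles.std(axis=0, ddof=1),
        "angles": angles,
    }


def rigid_rod_orientation_model(
    rod_length: float,
    distance_to_wall: float,
    n: int = 100_000,
    seed: int = 0,
) -> float:
    """Mean folded angle (degrees) between a rigid rod and the wall
    normal, for rods of the given length whose centre sits at the given
    distance from a flat wall; orientations are uniform among those not
    crossing the wall.

    A rod crosses the wall iff (L/2)|cos alpha| exceeds the distance, so
    the allowed region is cos alpha <= c with c = min(1, 2 d / L).  For a
    uniform direction cos alpha is uniform on [0, 1], hence cos alpha is
    sampled uniformly on [0, c].
    """
    if rod_length <= 0 or distance_to_wall < 0 or n < 1:
        raise ValueError("invalid inputs")
    c = min(1.0, 2.0 * distance_to_wall / rod_length)
    if c == 0.0:
        return 90.0
    rng = np.random.default_rng(seed)
    z = rng.uniform(0.0, c, size=n)
    return float(np.degrees(np.arccos(z)).mean())


def rigid_rod_orientation_analytic(
    rod_length: float, distance_to_wall: float
) -> float:
    """Closed form of the rigid-rod mean angle: with alpha0 =
    arccos(min(1, 2d/L)), the sin-weighted mean over [alpha0, 90] is
    (1 - sin(alpha0) + alpha0 cos(alpha0)) / cos(alpha0)."""
    c = min(1.0, 2.0 * distance_to_wall / rod_length)
    if c == 0.0:
        return 90.0
    a0 = np.arccos(c)
    return float(np.degrees((1.0 - np.sin(a0) + a0 * np.cos(a0)) / c))


def buckling_force(kappa: float, length: float) -> float:
    """Euler buckling force F = pi^2 kappa / L^2 (kappa in pN um^2, L in
    um, result in pN)."""
    if kappa < 0 or length <= 0:
        raise ValueError("kappa must be >= 0 and length > 0")
    return float(np.pi**2 * kappa / length**2)


def tortuosity_base_angle(t: float) -> float:
    """Base angle (degrees) of the isosceles triangle whose base is the
    Euclidean span and whose equal sides sum to the arc length:
    arccos(1/t)."""
    if t < 1.0:
        raise ValueError("tortuosity must be >= 1")
    return float(np.degrees(np.arccos(1.0 / t)))


def random_branch_end_reference(
    shell_voxels: np.ndarray,
    n_points: int,
    n_reps: int = 100,
    seed: int = 0,
    voxel_pitch: float = 2.0,
    origin=(0.0, 0.0, 0.0),
) -> dict[str, float | np.ndarray]:
    """Nearest-neighbour distance distribution for points placed
    uniformly at random (jittered within voxels) in a membrane-shell
    voxel set."""
    shell_voxels = np.atleast_2d(np.asarray(shell_voxels))
    if len(shell_voxels) == 0:
        raise ValueError("shell is empty")
    if n_points < 2:
        raise ValueError("need at least two points")
    rng = np.random.default_rng(seed)
    origin = np.asarray(origin, dtype=float)
    pooled = []
    distinct = len(shell_voxels) >= n_points
    for _ in range(n_reps):
        # branch ends are distinct objects: sample voxels without
        # replacement whenever the shell allows it
        if distinct:
            pick = rng.choice(len(shell_voxels), size=n_points, replace=False)
        else:
            pick = rng.integers(0, len(shell_voxels), size=n_points)
        jitter = rng.uniform(0.0, 1.0, size=(n_points, 3))
        pts = origin + (shell_voxels[pick] + jitter) * voxel_pitch
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        pooled.append(d[:, 1])
    pooled = np.concatenate(pooled)
    return {
        "distances": pooled,
        "mean": float(pooled.mean()),
        "sd": float(pooled.std(ddof=1)),
    }
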