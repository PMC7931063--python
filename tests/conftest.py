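import numpy as np
import pytest

from trip3p import (RetinalImage, TriangleShape, project_vertices,
                    sample_shape, side_lengths)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def planar_vertices(shape: TriangleShape):
    """Vertices of the shape in its own plane (z = 0), |AB| = 1, A at origin."""
    a, b, c = side_lengths(shape)
    wA = np.deg2rad(shape.omega_A)
    return np.array([
        [0.0, 0.0, 0.0],
        [c, 0.0, 0.0],
        [b * np.cos(wA), b * np.sin(wA), 0.0],
    ])


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random rotation from the QR decomposition of a Gaussian."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_placed_triangle(rng):
    """A random shape placed rigidly in front of the eye.

    Returns (shape, image, true_distances, vertex_positions); retries until
    the projection is non-degenerate.
    """
    while True:
        shape = sample_shape(rng)
        pts = planar_vertices(shape) @ random_rotation(rng).T
        pts = pts + np.array([0.0, 0.0, rng.uniform(8.0, 25.0)])
        if np.min(pts[:, 2]) <= 0.1:
            continue
        try:
            image = project_vertices(*pts)
        except Exception:
            continue
        return shape, image, np.linalg.norm(pts, axis=1), pts


def frontoparallel_equilateral(distance: float = 10.0):
    """Equilateral triangle in a z = distance plane, centroid on the z-axis."""
    r = 1.0 / np.sqrt(3.0)  # circumradius for side 1
    angles = np.deg2rad([90.0, 210.0, 330.0])
    pts = np.stack([r * np.cos(angles), r * np.sin(angles),
                    np.full(3, distance)], axis=1)
    shape = TriangleShape(60.0, 60.0)
    return shape, project_vertices(*pts), pts
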