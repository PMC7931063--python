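"""Core geometric types and projection operations.

A triangle ``ABC`` viewed from an eye ``E`` at the origin is described by

* its *shape*: the interior vertex angles ``(omega_A, omega_B, omega_C)``,
  two of which are free since they sum to 180 degrees, and
* its *retinal image*: the three visual angles ``(theta_BC, theta_CA,
  theta_AB)`` subtended at ``E`` by each pair of vertices.

All interfaces use degrees; radians appear only inside trigonometric
kernels.  Side lengths are expressed in units of ``|AB| = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, ValidationError

__all__ = [
    "TriangleShape",
    "RetinalImage",
    "SightRays",
    "Interpretation",
    "SolutionSet",
    "side_lengths",
    "rays_from_image",
    "project_vertices",
    "shape_from_orientation",
    "residuals",
    "STUDY_OMEGA_LO",
    "STUDY_OMEGA_HI",
]

#: Vertex-angle bounds used by the Monte-Carlo study (degrees).
STUDY_OMEGA_LO = 10.0
STUDY_OMEGA_HI = 170.0

_ANGLE_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TriangleShape:
    """Interior vertex angles of a triangle, in degrees.

    ``omega_C`` is derived as ``180 - omega_A - omega_B``.
    """

    omega_A: float
    omega_B: float

    def __post_init__(self):
        for name, val in (("omega_A", self.omega_A), ("omega_B", self.omega_B),
                          ("omega_C", self.omega_C)):
            if not np.isfinite(val) or not (0.0 < val < 180.0):
                raise ValidationError(
                    f"{name}={val!r} must lie strictly in (0, 180) degrees")

    @property
    def omega_C(self) -> float:
        return 180.0 - self.omega_A - self.omega_B

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.omega_A, self.omega_B, self.omega_C)

    def within_study_bounds(self, lo: float = STUDY_OMEGA_LO,
                            hi: float = STUDY_OMEGA_HI) -> bool:
        """True when every vertex angle lies strictly inside ``(lo, hi)``."""
        return all(lo < w < hi for w in self.angles)


@dataclass(frozen=True)
class RetinalImage:
    """Visual angles (degrees) subtended at the eye by each vertex pair.

    The three angles must form a valid apex: each in (0, 180), their sum
    below 360, and every pairwise triangle inequality strict.
    """

    theta_BC: float
    theta_CA: float
    theta_AB: float

    def __post_init__(self):
        t = self.thetas
        for name, val in zip(("theta_BC", "theta_CA", "theta_AB"), t):
            if not np.isfinite(val) or not (0.0 < val < 180.0):
                raise ValidationError(
                    f"{name}={val!r} must lie strictly in (0, 180) degrees")
        if not sum(t) < 360.0:
            raise ValidationError(
                f"visual angles must sum to < 360 degrees, got {sum(t)!r}")
        for i in range(3):
            if not t[i] < t[(i + 1) % 3] + t[(i + 2) % 3]:
                raise ValidationError(
                    f"visual angles {t} violate the apex triangle inequality")

    @property
    def thetas(self) -> tuple[float, float, float]:
        return (self.theta_BC, self.theta_CA, self.theta_AB)

    @property
    def max_angle(self) -> float:
        return max(self.thetas)


@dataclass(frozen=True)
class SightRays:
    """Unit vectors from the eye ``E`` (origin) toward the three vertices."""

    V_A: np.ndarray
    V_B: np.ndarray
    V_C: np.ndarray

    def __post_init__(self):
        for name in ("V_A", "V_B", "V_C"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValidationError(f"{name} must be a 3-vector")
            if abs(np.linalg.norm(v) - 1.0) > 1e-12:
                raise ValidationError(f"{name} must have unit length")
            object.__setattr__(self, name, v)

    def pairwise_angles(self) -> tuple[float, float, float]:
        """(theta_BC, theta_CA, theta_AB) reproduced from the rays, degrees."""
        ang = lambda u, v: float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))
        return (ang(self.V_B, self.V_C), ang(self.V_C, self.V_A),
                ang(self.V_A, self.V_B))


@dataclass(frozen=True)
class Interpretation:
    """One recovered 3D placement of the triangle.

    ``l_A, l_B, l_C`` are the distances of the vertices from the eye along
    their sight rays, in units of ``|AB| = scale``.
    """

    l_A: float
    l_B: float
    l_C: float
    A_pos: np.ndarray
    B_pos: np.ndarray
    C_pos: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        if min(self.l_A, self.l_B, self.l_C) <= 0:
            raise ValidationError("vertex distances must be strictly positive")
        if self.scale <= 0:
            raise ValidationError("scale must be strictly positive")
        for name in ("A_pos", "B_pos", "C_pos"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))

    @property
    def distances(self) -> tuple[float, float, float]:
        return (self.l_A, self.l_B, self.l_C)

    def rescaled(self, factor: float) -> "Interpretation":
        """Similar interpretation with the triangle size multiplied by *factor*."""
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        return Interpretation(
            l_A=self.l_A * factor, l_B=self.l_B * factor, l_C=self.l_C * factor,
            A_pos=self.A_pos * factor, B_pos=self.B_pos * factor,
            C_pos=self.C_pos * factor, scale=self.scale * factor)


@dataclass(frozen=True)
class SolutionSet:
    """All distinct 3D interpretations of a (shape, image) pair.

    Solutions are sorted by ``l_A`` ascending (ties by ``l_B``) so that a
    given instance always enumerates in the same order.
    """

    shape: TriangleShape
    image: RetinalImage
    solutions: tuple[Interpretation, ...] = field(default=())

    def __post_init__(self):
        if not 0 <= len(self.solutions) <= 4:
            raise ValidationError("a P3P instance has at most 4 solutions")
        object.__setattr__(
            self, "solutions",
            tuple(sorted(self.solutions, key=lambda s: (s.l_A, s.l_B))))

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self):
        return iter(self.solutions)

    def __getitem__(self, i):
        return self.solutions[i]


def side_lengths(shape: TriangleShape) -> tuple[float, float, float]:
    """Side lengths ``(|BC|, |CA|, |AB|)`` with ``|AB|`` normalized to 1.

    By the law of sines, ``|BC| = sin(omega_A) / sin(omega_C)`` and
    ``|CA| = sin(omega_B) / sin(omega_C)``.
    """
    wA, wB, wC = np.deg2rad(shape.angles)
    return (float(np.sin(wA) / np.sin(wC)), float(np.sin(wB) / np.sin(wC)), 1.0)


def rays_from_image(image: RetinalImage) -> SightRays:
    """Embed the three sight rays in a fixed canonical frame.

    Convention: ``V_A`` along +z, ``V_B`` in the x-z half-plane (x > 0),
    ``V_C`` with positive y-component.  Solution counts do not depend on
    the mirror choice for ``V_C``.
    """
    tBC, tCA, tAB = np.deg2rad(image.thetas)
    V_A = np.array([0.0, 0.0, 1.0])
    V_B = np.array([np.sin(tAB), 0.0, np.cos(tAB)])
    z = np.cos(tCA)
    x = (np.cos(tBC) - np.cos(tCA) * np.cos(tAB)) / np.sin(tAB)
    y2 = 1.0 - x * x - z * z
    if y2 <= 0:
        raise DegenerateGeometryError(
            f"no real sight-ray configuration for image {image.thetas}")
    V_C = np.array([x, np.sqrt(y2), z])
    return SightRays(V_A=V_A, V_B=V_B, V_C=V_C)


def project_vertices(A_pos, B_pos, C_pos) -> RetinalImage:
    """Visual angles of three vertex positions seen from the origin."""
    pts = [np.asarray(p, dtype=float) for p in (A_pos, B_pos, C_pos)]
    norms = [np.linalg.norm(p) for p in pts]
    if min(norms) < 1e-12:
        raise DegenerateGeometryError("a vertex coincides with the eye")
    units = [p / n for p, n in zip(pts, norms)]

    def ang(u, v):
        c = np.clip(u @ v, -1.0, 1.0)
        a = float(np.degrees(np.arccos(c)))
        if a < 1e-12 or a > 180.0 - 1e-12:
            raise DegenerateGeometryError(
                "two vertices are collinear with the eye")
        return a

    try:
        return RetinalImage(theta_BC=ang(units[1], units[2]),
                            theta_CA=ang(units[2], units[0]),
                            theta_AB=ang(units[0], units[1]))
    except ValidationError as exc:  # pragma: no cover - defensive
        raise DegenerateGeometryError(str(exc)) from exc


def shape_from_orientation(image: RetinalImage, plane_normal,
                           plane_distance: float,
                           ) -> tuple[TriangleShape, float]:
    """Unique triangle cut from the sight rays by a plane of known pose.

    The plane is ``n . x = d`` with unit normal *n* and offset
    ``d = plane_distance > 0``.  Returns the shape of the intersection
    triangle and its size ``|AB|``.
    """
    if plane_distance <= 0:
        raise ValidationError("plane_distance must be positive")
    n = np.asarray(plane_normal, dtype=float)
    if n.shape != (3,) or abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValidationError("plane_normal must be a unit 3-vector")
    rays = rays_from_image(image)
    pts = []
    for V in (rays.V_A, rays.V_B, rays.V_C):
        dn = float(n @ V)
        if abs(dn) < 1e-12:
            raise DegenerateGeometryError(
                "plane normal is perpendicular to a line of projection")
        t = plane_distance / dn
        if t <= 0:
            raise DegenerateGeometryError(
                "plane intersects a sight ray behind the eye")
        pts.append(t * V)
    A, B, C = pts
    size = float(np.linalg.norm(B - A))
    ang = lambda u, v: float(np.degrees(np.arccos(np.clip(
        (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0))))
    omega_A = ang(B - A, C - A)
    omega_B = ang(A - B, C - B)
    return TriangleShape(omega_A=omega_A, omega_B=omega_B), size


def residuals(interp: Interpretation, shape: TriangleShape,
              image: RetinalImage) -> tuple[float, float, float]:
    """Absolute law-of-cosines residuals for the pairs (B,C), (C,A), (A,B).

    Residual ``|l_i^2 + l_j^2 - 2 l_i l_j cos(theta_ij) - (s d_ij)^2``| is
    zero for every pair exactly when *interp* solves the instance.
    """
    d = np.array(side_lengths(shape)) * interp.scale
    cth = np.cos(np.deg2rad(image.thetas))
    l = interp.distances
    pairs = ((1, 2), (2, 0), (0, 1))
    return tuple(
        float(abs(l[i] ** 2 + l[j] ** 2 - 2 * l[i] * l[j] * cth[k] - d[k] ** 2))
        for k, (i, j) in enumerate(pairs))
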