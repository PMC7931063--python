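"""Perspective-3-Point solver via the classical quartic reduction.

Given the triangle's side lengths ``a = |BC|, b = |CA|, c = |AB| = 1`` and
the cosines of the visual angles, the vertex distances ``(l_A, l_B, l_C)``
satisfy three law-of-cosines constraints.  Substituting the ratios
``u = l_B / l_A`` and ``v = l_C / l_A`` leaves two quadratics in ``u`` whose
coefficients are polynomials in ``v``; their resultant is a degree-4
polynomial in ``v``.  Each admissible real root back-substitutes to one
candidate distance triple, which is Newton-polished and verified against
the original constraints before being counted.  There are therefore 0 to 4
distinct interpretations per instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, ValidationError
from .geometry import (Interpretation, RetinalImage, SolutionSet,
                       TriangleShape, rays_from_image, side_lengths)

__all__ = [
    "SolverTolerances",
    "solve_p3p",
    "count_solutions",
    "count_solutions_batch",
    "is_depth_reversal_pair",
]

# law-of-cosines pairing: constraint k couples distances (i, j)
_PAIRS = ((1, 2), (2, 0), (0, 1))


@dataclass(frozen=True)
class SolverTolerances:
    """Numerical tolerances of the quartic P3P solver."""

    #: a quartic root is real when |Im| < imag_tol * max(1, |Re|)
    imag_tol: float = 1e-9
    #: distances at or below this are treated as behind the eye
    min_distance: float = 1e-9
    #: max law-of-cosines residual accepted after polishing
    residual_tol: float = 1e-8
    #: two triples are the same solution when their max component
    #: difference, relative to the triple's overall magnitude, is below
    #: this (scaled to the whole triple, not per component, so that the
    #: polish scatter around a near-double root cannot split one solution)
    dedup_rel: float = 1e-6
    #: Newton polishing iterations applied to each algebraic candidate
    #: (enough for slow linear convergence at near-double roots, so that
    #: duplicate candidates collapse within dedup_rel)
    newton_iters: int = 8


DEFAULT_TOLERANCES = SolverTolerances()


def _quartic_coefficients(a2, b2, c2, ca, cb, cg):
    """Ascending coefficients of the resultant quartic in ``v = l_C / l_A``.

    Works elementwise on arrays.  The two quadratics in ``u`` are
    ``b2*u^2 - 2*b2*cg*u + (b2 - c2 + 2*c2*cb*v - c2*v^2)`` (from the CA/AB
    equations) and ``(c2-a2)*u^2 + (2*a2*cg - 2*c2*ca*v)*u + (c2*v^2 - a2)``
    (from the BC/AB equations).
    """
    A = b2
    B = -2.0 * b2 * cg
    D = c2 - a2
    # G = A*F - D*C        (degree 2 in v)
    G0 = -A * a2 - D * (b2 - c2)
    G1 = -D * 2.0 * c2 * cb
    G2 = A * c2 + D * c2
    # H = A*E - B*D        (degree 1 in v)
    H0 = A * 2.0 * a2 * cg - B * D
    H1 = -A * 2.0 * c2 * ca
    # K = B*F - C*E        (degree 3 in v)
    K0 = -B * a2 - (b2 - c2) * 2.0 * a2 * cg
    K1 = -((b2 - c2) * (-2.0 * c2 * ca) + 2.0 * c2 * cb * 2.0 * a2 * cg)
    K2 = B * c2 - (2.0 * c2 * cb * (-2.0 * c2 * ca) - c2 * 2.0 * a2 * cg)
    K3 = -(2.0 * c2 * c2 * ca)
    # quartic = G^2 - H*K  (degree 4 in v)
    q0 = G0 * G0 - H0 * K0
    q1 = 2.0 * G0 * G1 - (H0 * K1 + H1 * K0)
    q2 = G1 * G1 + 2.0 * G0 * G2 - (H0 * K2 + H1 * K1)
    q3 = 2.0 * G1 * G2 - (H0 * K3 + H1 * K2)
    q4 = G2 * G2 - H1 * K3
    return (q0, q1, q2, q3, q4), (G0, G1, G2), (H0, H1)


def _newton_polish(l, d2, cth, iters):
    """Newton iterations on the three law-of-cosines equations; 3-vector l."""
    for _ in range(iters):
        F = np.empty(3)
        J = np.zeros((3, 3))
        for k, (i, j) in enumerate(_PAIRS):
            F[k] = l[i] ** 2 + l[j] ** 2 - 2 * l[i] * l[j] * cth[k] - d2[k]
            J[k, i] = 2 * l[i] - 2 * l[j] * cth[k]
            J[k, j] = 2 * l[j] - 2 * l[i] * cth[k]
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            break
        l = l - step
    return l


def _max_residual(l, d2, cth):
    return max(abs(l[i] ** 2 + l[j] ** 2 - 2 * l[i] * l[j] * cth[k] - d2[k])
               for k, (i, j) in enumerate(_PAIRS))


def _candidate_triples(shape: TriangleShape, image: RetinalImage,
                       tol: SolverTolerances) -> list[np.ndarray]:
    """Distinct positive, verified (l_A, l_B, l_C) triples, unsorted."""
    a, b, c = side_lengths(shape)
    a2, b2, c2 = a * a, b * b, c * c
    cth = np.cos(np.deg2rad(image.thetas))
    ca, cb, cg = cth
    (q0, q1, q2, q3, q4), G, H = _quartic_coefficients(a2, b2, c2, ca, cb, cg)
    coeffs = np.array([q4, q3, q2, q1, q0])  # descending for np.roots
    scale = np.max(np.abs(coeffs))
    if scale == 0 or not np.all(np.isfinite(coeffs)):
        raise NumericalError("degenerate quartic", inputs=(shape, image))
    coeffs = coeffs / scale
    # deflate a (near-)vanishing leading coefficient rather than dividing by it
    while len(coeffs) > 1 and abs(coeffs[0]) < 1e-13:
        coeffs = coeffs[1:]
    if len(coeffs) <= 1:
        return []
    roots = np.roots(coeffs)
    d2 = np.array([a2, b2, c2])
    triples: list[np.ndarray] = []
    for v in roots:
        if abs(v.imag) > tol.imag_tol * max(1.0, abs(v.real)):
            continue
        v = float(v.real)
        if v <= 0.0:
            continue
        for u in _u_candidates(v, a2, b2, c2, ca, cb, cg, G, H):
            if u <= 0.0:
                continue
            R = u * u + 1.0 - 2.0 * u * cg
            if R <= 0.0:
                continue
            lA = c / np.sqrt(R)
            l = _newton_polish(np.array([lA, u * lA, v * lA]), d2, cth,
                               tol.newton_iters)
            if not np.all(np.isfinite(l)) or np.min(l) <= tol.min_distance:
                continue
            if _max_residual(l, d2, cth) > tol.residual_tol:
                continue
            if any(np.max(np.abs(l - t)) / max(1.0, float(np.max(np.abs(t))))
                   < tol.dedup_rel for t in triples):
                continue
            triples.append(l)
    return triples


def _u_candidates(v, a2, b2, c2, ca, cb, cg, G, H):
    """Candidate ``u = l_B / l_A`` values for one quartic root ``v``.

    The linear elimination gives the shared root of the two u-quadratics,
    but degenerates (0/0) when a symmetric instance makes the quadratics
    proportional, in which case one ``v`` carries two distinct solutions.
    The quadratics' own roots are therefore always offered as candidates
    too; ghosts are discarded downstream by the residual check.
    """
    out = []
    Gv = G[0] + G[1] * v + G[2] * v * v
    Hv = H[0] + H[1] * v
    if abs(Hv) > 1e-300:
        out.append(-Gv / Hv)
    # quadratic from the CA/AB pair: b2*u^2 - 2*b2*cg*u + C(v)
    Cv = b2 - c2 + 2.0 * c2 * cb * v - c2 * v * v
    disc = b2 * b2 * cg * cg - b2 * Cv
    if disc >= 0.0:
        r = np.sqrt(disc)
        out.extend([(b2 * cg + r) / b2, (b2 * cg - r) / b2])
    # quadratic from the BC/AB pair: (c2-a2)*u^2 + E(v)*u + F(v)
    D = c2 - a2
    Ev = 2.0 * a2 * cg - 2.0 * c2 * ca * v
    Fv = c2 * v * v - a2
    if abs(D) > 1e-12 * max(a2, c2):
        disc = Ev * Ev - 4.0 * D * Fv
        if disc >= 0.0:
            r = np.sqrt(disc)
            out.extend([(-Ev + r) / (2.0 * D), (-Ev - r) / (2.0 * D)])
    elif abs(Ev) > 1e-300:
        out.append(-Fv / Ev)
    return out


def solve_p3p(shape: TriangleShape, image: RetinalImage,
              tolerances: SolverTolerances = DEFAULT_TOLERANCES) -> SolutionSet:
    """Enumerate every 3D interpretation of *shape* consistent with *image*.

    Returns a :class:`SolutionSet` holding 0 to 4 distinct
    :class:`Interpretation` objects (size ``|AB| = 1``), each verified to
    satisfy all three law-of-cosines constraints within
    ``tolerances.residual_tol``.
    """
    if not isinstance(shape, TriangleShape):
        raise ValidationError("shape must be a TriangleShape")
    if not isinstance(image, RetinalImage):
        raise ValidationError("image must be a RetinalImage")
    rays = rays_from_image(image)
    interps = []
    for l in _candidate_triples(shape, image, tolerances):
        interps.append(Interpretation(
            l_A=float(l[0]), l_B=float(l[1]), l_C=float(l[2]),
            A_pos=l[0] * rays.V_A, B_pos=l[1] * rays.V_B,
            C_pos=l[2] * rays.V_C, scale=1.0))
    return SolutionSet(shape=shape, image=image, solutions=tuple(interps))


def count_solutions(shape: TriangleShape, image: RetinalImage,
                    tolerances: SolverTolerances = DEFAULT_TOLERANCES) -> int:
    """Number of distinct 3D interpretations (0-4) without building vectors."""
    return len(_candidate_triples(shape, image, tolerances))


def count_solutions_batch(omega_A, omega_B, theta_BC, theta_CA, theta_AB,
                          tolerances: SolverTolerances = DEFAULT_TOLERANCES,
                          ) -> np.ndarray:
    """Vectorized solution counts for many (shape, image) instances.

    All five arguments are broadcastable arrays of angles in degrees; every
    instance must already satisfy the shape and image invariants.  Returns
    an integer array of counts in ``{0, ..., 4}``.  Agrees with
    :func:`count_solutions` instance by instance; instances whose quartic
    is ill-conditioned fall back to the scalar path.
    """
    wA, wB, tBC, tCA, tAB = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in
          (omega_A, omega_B, theta_BC, theta_CA, theta_AB)))
    shp = wA.shape
    wA, wB, tBC, tCA, tAB = (x.ravel() for x in (wA, wB, tBC, tCA, tAB))
    n = wA.size
    tol = tolerances

    wC = 180.0 - wA - wB
    sC = np.sin(np.deg2rad(wC))
    a = np.sin(np.deg2rad(wA)) / sC
    b = np.sin(np.deg2rad(wB)) / sC
    a2, b2, c2 = a * a, b * b, np.ones(n)
    ca, cb, cg = (np.cos(np.deg2rad(t)) for t in (tBC, tCA, tAB))
    (q0, q1, q2, q3, q4), (G0, G1, G2), (H0, H1) = _quartic_coefficients(
        a2, b2, c2, ca, cb, cg)

    coeffs = np.stack([q0, q1, q2, q3, q4], axis=1)
    scale = np.max(np.abs(coeffs), axis=1)
    bad = (scale == 0) | ~np.isfinite(scale)
    scale = np.where(bad, 1.0, scale)
    coeffs /= scale[:, None]
    fallback = bad | (np.abs(coeffs[:, 4]) < 1e-13)

    # batched companion matrices for the monic quartic
    lead = np.where(fallback, 1.0, coeffs[:, 4])
    monic = coeffs[:, :4] / lead[:, None]
    comp = np.zeros((n, 4, 4))
    comp[:, 1, 0] = comp[:, 2, 1] = comp[:, 3, 2] = 1.0
    comp[:, :, 3] = -monic
    roots = np.linalg.eigvals(comp)  # (n, 4) complex

    real = np.abs(roots.imag) <= tol.imag_tol * np.maximum(1.0, np.abs(roots.real))
    v = roots.real
    valid = real & (v > 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        Gv = G0[:, None] + G1[:, None] * v + G2[:, None] * v * v
        Hv = H0[:, None] + H1[:, None] * v
        u = -Gv / Hv
    # a (near-)degenerate elimination means one v may carry two solutions
    # (proportional u-quadratics at a symmetric instance): resolve those
    # instances through the scalar path
    h_scale = np.abs(H0[:, None]) + np.abs(H1[:, None] * v)
    fallback |= np.any(valid & (np.abs(Hv) <= 1e-6 * h_scale), axis=1)
    valid &= np.isfinite(u) & (u > 0.0) & (np.abs(Hv) > 1e-300)
    R = u * u + 1.0 - 2.0 * u * cg[:, None]
    valid &= R > 0.0

    lA = np.where(valid, 1.0 / np.sqrt(np.where(valid, R, 1.0)), np.nan)
    l = np.stack([lA, u * lA, v * lA], axis=-1)          # (n, 4, 3)
    l = np.where(valid[..., None], l, 1.0)               # safe dummy values

    d2 = np.stack([a2, b2, c2], axis=1)[:, None, :]      # (n, 1, 3)
    cth = np.stack([ca, cb, cg], axis=1)[:, None, :]
    for _ in range(tol.newton_iters):
        F = np.empty_like(l)
        J = np.zeros(l.shape[:-1] + (3, 3))
        for k, (i, j) in enumerate(_PAIRS):
            F[..., k] = (l[..., i] ** 2 + l[..., j] ** 2
                         - 2 * l[..., i] * l[..., j] * cth[..., k] - d2[..., k])
            J[..., k, i] = 2 * l[..., i] - 2 * l[..., j] * cth[..., k]
            J[..., k, j] = 2 * l[..., j] - 2 * l[..., i] * cth[..., k]
        dets = np.linalg.det(J)
        solvable = np.abs(dets) > 1e-300
        J[~solvable] = np.eye(3)
        F[~solvable] = 0.0
        l = l - np.linalg.solve(J, F[..., None])[..., 0]

    res = np.zeros(l.shape[:-1])
    for k, (i, j) in enumerate(_PAIRS):
        res = np.maximum(res, np.abs(
            l[..., i] ** 2 + l[..., j] ** 2
            - 2 * l[..., i] * l[..., j] * cth[..., k] - d2[..., k]))
    valid &= np.all(np.isfinite(l), axis=-1)
    valid &= np.min(l, axis=-1) > tol.min_distance
    valid &= res <= tol.residual_tol

    # dedup the <=4 candidates of each instance pairwise
    for i in range(4):
        for j in range(i + 1, 4):
            scale = np.maximum(1.0, np.max(np.abs(l[:, i, :]), axis=-1))
            close = np.max(np.abs(l[:, i, :] - l[:, j, :]), axis=-1) \
                < tol.dedup_rel * scale
            valid[:, j] &= ~(valid[:, i] & close)

    counts = np.sum(valid, axis=1).astype(np.int64)
    for idx in np.nonzero(fallback)[0]:
        counts[idx] = count_solutions(
            TriangleShape(float(wA[idx]), float(wB[idx])),
            RetinalImage(float(tBC[idx]), float(tCA[idx]), float(tAB[idx])),
            tol)
    return counts.reshape(shp)


def is_depth_reversal_pair(s1: Interpretation, s2: Interpretation,
                           tol: float = 0.15) -> tuple[bool, float]:
    """Test whether two interpretations are approximate depth reversals.

    Each triangle's depth profile is its vertex distances minus their mean.
    The pair is a reversal when the profiles approximately negate each
    other.  Returns ``(verdict, discrepancy)`` where the discrepancy is
    ``|d1 + d2| / (|d1| + |d2|)`` (0 for an exact reversal, 1 for
    identical non-frontoparallel profiles).  Two exactly frontoparallel
    triangles have zero profiles and count as an exact reversal.
    """
    d1 = np.array(s1.distances) - np.mean(s1.distances)
    d2 = np.array(s2.distances) - np.mean(s2.distances)
    denom = np.linalg.norm(d1) + np.linalg.norm(d2)
    if denom < 1e-12:
        return True, 0.0
    metric = float(np.linalg.norm(d1 + d2) / denom)
    return metric < tol, metric
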