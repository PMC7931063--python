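"""Brute-force solution counter, independent of the quartic solver.

The instance is reduced to a one-dimensional root count.  The planar
triangle ``EAB`` (visual angle ``theta_AB`` at ``E``, side ``|AB| = c``) is
swept by the angle ``phi`` at vertex ``A``; each ``phi`` fixes ``(l_A,
l_B)`` exactly.  The remaining two constraints are quadratics in ``l_C``
whose resultant ``W(phi)`` is smooth in ``phi`` — no square-root branch
choices — and vanishes exactly at the 3D interpretations.  Sign changes of
``W`` on a dense grid are bisected to the root and each refined root is
verified against all three constraints before being counted.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .geometry import RetinalImage, TriangleShape, side_lengths

__all__ = ["oracle_count"]


def oracle_count(shape: TriangleShape, image: RetinalImage,
                 scan_step: float = 1e-4) -> int:
    """Count 3D interpretations by dense 1D scanning plus bisection.

    *scan_step* is the grid spacing as a fraction of the scanned
    ``phi``-interval (default 1e-4, i.e. 10,000 grid points).  Independent
    of :func:`trip3p.solver.solve_p3p`; used to cross-check it.
    """
    if not isinstance(shape, TriangleShape):
        raise ValidationError("shape must be a TriangleShape")
    if not isinstance(image, RetinalImage):
        raise ValidationError("image must be a RetinalImage")
    if scan_step <= 0:
        raise ValidationError("scan_step must be positive")

    a, b, c = side_lengths(shape)
    ca, cb, cg = np.cos(np.deg2rad(image.thetas))
    gamma = np.deg2rad(image.theta_AB)
    sin_g = np.sin(gamma)

    def eval_W(phi):
        """Resultant of the two l_C quadratics, plus their shared root."""
        l_B = c * np.sin(phi) / sin_g
        l_A = c * np.sin(gamma + phi) / sin_g
        p1 = -2.0 * l_A * cb
        p0 = l_A * l_A - b * b
        q1 = -2.0 * l_B * ca
        q0 = l_B * l_B - a * a
        W = (q0 - p0) ** 2 + p1 * (q0 - p0) * (p1 - q1) + p0 * (p1 - q1) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            l_C = (q0 - p0) / (p1 - q1)
        return W, l_C, l_A, l_B

    n = int(np.ceil(1.0 / scan_step))
    span = np.pi - gamma
    phi = (np.arange(n + 1) + 0.5) * span / (n + 1)
    # roots can hide arbitrarily close to the endpoints (a vertex distance
    # approaching zero); log-spaced refinement reaches them
    edge = np.geomspace(1e-12 * span, phi[0], 60)
    phi = np.sort(np.concatenate([edge, phi, span - edge]))
    W, _, _, _ = eval_W(phi)
    sign = np.sign(W)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]

    count = 0
    for i in crossings:
        lo, hi = phi[i], phi[i + 1]
        W_lo = W[i]
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            W_mid = eval_W(mid)[0]
            if W_mid == 0.0:
                lo = hi = mid
                break
            if np.sign(W_mid) == np.sign(W_lo):
                lo = mid
            else:
                hi = mid
        mid = 0.5 * (lo + hi)
        _, l_C, l_A, l_B = eval_W(mid)
        if not np.isfinite(l_C) or min(l_A, l_B, l_C) <= 1e-9:
            continue
        residual = max(
            abs(l_B ** 2 + l_C ** 2 - 2 * l_B * l_C * ca - a * a),
            abs(l_C ** 2 + l_A ** 2 - 2 * l_C * l_A * cb - b * b),
            abs(l_A ** 2 + l_B ** 2 - 2 * l_A * l_B * cg - c * c))
        if residual < 1e-6 * max(1.0, l_A * l_A):
            count += 1
    return count
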