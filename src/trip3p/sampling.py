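"""Constrained-uniform samplers for triangle shapes and retinal images.

Shapes: ``(omega_A, omega_B)`` uniform over the region where all three
vertex angles lie strictly inside (10, 170) degrees, by rejection from the
(10, 170)^2 box.  Images: ``(theta_BC, theta_CA, theta_AB)`` uniform over a
box intersected with the apex constraints (sum < 360, pairwise triangle
inequalities), again by rejection, so the joint law is exactly the
constrained uniform.  Boundary hits are rejected (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .geometry import (RetinalImage, STUDY_OMEGA_HI, STUDY_OMEGA_LO,
                       TriangleShape)

__all__ = [
    "ImageRange",
    "sample_shape",
    "sample_shapes",
    "sample_image",
    "sample_images",
    "substream",
]

#: Experiment-1 lower bound on every visual angle (degrees).
FULL_RANGE_THETA_LO = 0.1

_MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class ImageRange:
    """Sampling interval for the three visual angles, in degrees."""

    theta_lo: float
    theta_hi: float
    mode: str = "full"

    def __post_init__(self):
        if not (0.0 < self.theta_lo < self.theta_hi <= 180.0):
            raise ValidationError(
                f"need 0 < theta_lo < theta_hi <= 180, got "
                f"({self.theta_lo!r}, {self.theta_hi!r})")
        if self.mode not in ("full", "half"):
            raise ValidationError(f"unknown mode {self.mode!r}")

    @classmethod
    def full(cls, theta_max: float) -> "ImageRange":
        """Experiment-1 range: every angle in (0.1 deg, theta_max)."""
        return cls(theta_lo=FULL_RANGE_THETA_LO, theta_hi=theta_max, mode="full")

    @classmethod
    def half(cls, theta_max: float) -> "ImageRange":
        """Experiment-2 range: every angle in (theta_max / 2, theta_max)."""
        return cls(theta_lo=theta_max / 2.0, theta_hi=theta_max, mode="half")

    @classmethod
    def for_mode(cls, mode: str, theta_max: float) -> "ImageRange":
        if mode == "full":
            return cls.full(theta_max)
        if mode == "half":
            return cls.half(theta_max)
        raise ValidationError(f"unknown mode {mode!r}")


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent child generator derived from a master seed and an index key.

    Streams with distinct keys are statistically independent, and adding
    new keys never perturbs existing ones.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def sample_shapes(rng: np.random.Generator, n: int,
                  lo: float = STUDY_OMEGA_LO,
                  hi: float = STUDY_OMEGA_HI) -> np.ndarray:
    """Draw *n* shapes; returns an ``(n, 2)`` array of (omega_A, omega_B)."""
    if n < 0:
        raise ValidationError("n must be non-negative")
    out = np.empty((n, 2))
    got = 0
    rounds = 0
    while got < n:
        rounds += 1
        if rounds > _MAX_REJECTION_ROUNDS:
            raise ConfigurationError(
                "shape sampler acceptance rate is numerically zero")
        m = max(256, 2 * (n - got))
        draw = rng.uniform(lo, hi, size=(m, 2))
        wC = 180.0 - draw.sum(axis=1)
        keep = draw[(wC > lo) & (wC < hi)]
        take = min(len(keep), n - got)
        out[got:got + take] = keep[:take]
        got += take
    return out


def sample_shape(rng: np.random.Generator) -> TriangleShape:
    """Draw one shape uniform over the study region."""
    wA, wB = sample_shapes(rng, 1)[0]
    return TriangleShape(omega_A=float(wA), omega_B=float(wB))


def _apex_ok(t: np.ndarray) -> np.ndarray:
    s = t.sum(axis=1)
    return ((s < 360.0)
            & (t[:, 0] + t[:, 1] > t[:, 2])
            & (t[:, 1] + t[:, 2] > t[:, 0])
            & (t[:, 2] + t[:, 0] > t[:, 1]))


def sample_images(rng: np.random.Generator, image_range: ImageRange,
                  n: int) -> np.ndarray:
    """Draw *n* images; returns ``(n, 3)`` of (theta_BC, theta_CA, theta_AB)."""
    if n < 0:
        raise ValidationError("n must be non-negative")
    lo, hi = image_range.theta_lo, image_range.theta_hi
    out = np.empty((n, 3))
    got = 0
    rounds = 0
    while got < n:
        rounds += 1
        if rounds > _MAX_REJECTION_ROUNDS:
            raise ConfigurationError(
                f"image sampler acceptance rate is numerically zero for "
                f"range ({lo}, {hi})")
        m = max(256, 4 * (n - got))
        draw = rng.uniform(lo, hi, size=(m, 3))
        keep = draw[_apex_ok(draw)]
        take = min(len(keep), n - got)
        out[got:got + take] = keep[:take]
        got += take
    return out


def sample_image(rng: np.random.Generator,
                 image_range: ImageRange) -> RetinalImage:
    """Draw one image uniform over the constrained box."""
    t = sample_images(rng, image_range, 1)[0]
    return RetinalImage(theta_BC=float(t[0]), theta_CA=float(t[1]),
                        theta_AB=float(t[2]))
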