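"""Shape-space solution-count maps for a fixed retinal image.

For a fixed image, the (omega_A, omega_B) plane is discretized and the
number of 3D interpretations is computed at every valid cell, reproducing
the published ambiguity maps: per-image heat maps, summary fractions, and
the binocular conjunction of a left/right image pair.

The bundled stimuli are the retinal images of the triangles used in two
classic psychophysics experiments (three monocular images from Beck &
Gibson's shape-constancy study; a binocular left/right pair from
Watanabe's visual-space study) plus the small/large probe images from the
Monte-Carlo follow-up analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .geometry import RetinalImage
from .solver import DEFAULT_TOLERANCES, SolverTolerances, count_solutions_batch

__all__ = [
    "STIMULI",
    "SolutionCountMap",
    "BinocularMap",
    "compute_shape_map",
    "map_statistics",
    "binocular_combine",
    "map_to_frame",
]

#: Marker stored in invalid (non-triangle) grid cells.
INVALID = -1

#: Named stimulus images (theta_BC, theta_CA, theta_AB) in degrees.
STIMULI = MappingProxyType({
    "beck_gibson_1": RetinalImage(5.538, 5.538, 6.573),
    "beck_gibson_2": RetinalImage(4.928, 4.928, 6.638),
    "beck_gibson_3": RetinalImage(4.222, 4.222, 6.689),
    "watanabe_left": RetinalImage(41.19, 27.68, 31.01),
    "watanabe_right": RetinalImage(41.18, 27.78, 30.91),
    "fig3_text_small": RetinalImage(9.0, 10.0, 11.0),
    "fig3_caption_small": RetinalImage(10.0, 15.0, 20.0),
    "fig3_large": RetinalImage(90.0, 100.0, 110.0),
})


@dataclass(frozen=True)
class SolutionCountMap:
    """Solution counts on an (omega_A, omega_B) grid for one image.

    ``counts[i, j]`` is the number of interpretations for the shape
    ``(omega_A_deg[i], omega_B_deg[j])``, or :data:`INVALID` where the cell
    is not a valid triangle shape within the map's angle bounds.
    """

    image: RetinalImage
    grid_step: float
    omega_lo: float
    omega_hi: float
    omega_A_deg: np.ndarray
    omega_B_deg: np.ndarray
    counts: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.counts != INVALID

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))


@dataclass(frozen=True)
class BinocularMap:
    """Cell-wise combination of a left-eye and a right-eye count map."""

    left: SolutionCountMap
    right: SolutionCountMap

    @property
    def valid(self) -> np.ndarray:
        return self.left.valid

    @property
    def projectable(self) -> np.ndarray:
        """Cells projectable to both eyes (count >= 1 in each map)."""
        return self.valid & (self.left.counts >= 1) & (self.right.counts >= 1)


def _grid_axis(lo: float, hi: float, step: float) -> np.ndarray:
    return np.arange(lo + step / 2.0, hi, step)


def compute_shape_map(image: RetinalImage, grid_step: float = 0.5,
                      omega_lo: float = 0.0, omega_hi: float = 180.0,
                      tolerances: SolverTolerances = DEFAULT_TOLERANCES,
                      ) -> SolutionCountMap:
    """Solution count for every valid shape on a regular angle grid.

    Cell centers sit at ``omega_lo + step/2 + k*step``; a cell is valid
    when all three vertex angles lie strictly inside
    ``(omega_lo, omega_hi)``.  The default bounds span the whole shape
    simplex; pass ``omega_lo=10, omega_hi=170`` for the restricted region
    used by the Monte-Carlo sampling.
    """
    if not isinstance(image, RetinalImage):
        raise ValidationError("image must be a RetinalImage")
    if grid_step <= 0:
        raise ValidationError("grid_step must be positive")
    if not (0.0 <= omega_lo < omega_hi <= 180.0):
        raise ValidationError("need 0 <= omega_lo < omega_hi <= 180")
    axis = _grid_axis(omega_lo, omega_hi, grid_step)
    if len(axis) == 0:
        raise ConfigurationError(
            f"grid_step={grid_step} leaves no cells in ({omega_lo}, {omega_hi})")
    wA, wB = np.meshgrid(axis, axis, indexing="ij")
    wC = 180.0 - wA - wB
    valid = ((wA > omega_lo) & (wA < omega_hi)
             & (wB > omega_lo) & (wB < omega_hi)
             & (wC > omega_lo) & (wC < omega_hi))
    if not np.any(valid):
        raise ConfigurationError("no valid shape cell on the requested grid")
    counts = np.full(wA.shape, INVALID, dtype=np.int64)
    t = image.thetas
    counts[valid] = count_solutions_batch(
        wA[valid], wB[valid], t[0], t[1], t[2], tolerances=tolerances)
    return SolutionCountMap(image=image, grid_step=float(grid_step),
                            omega_lo=float(omega_lo), omega_hi=float(omega_hi),
                            omega_A_deg=axis, omega_B_deg=axis, counts=counts)


def map_statistics(count_map: SolutionCountMap) -> dict:
    """Summary fractions over the valid cells of a count map."""
    vals = count_map.counts[count_map.valid]
    n = vals.size
    fractions = {k: float(np.sum(vals == k)) / n for k in range(5)}
    return {
        "n_valid_cells": int(n),
        "fraction_by_count": fractions,
        "fraction_projectable": float(np.sum(vals >= 1)) / n,
        "max_count": int(vals.max()),
    }


def binocular_combine(left: SolutionCountMap, right: SolutionCountMap,
                      ) -> tuple[BinocularMap, dict]:
    """Combine two eyes' maps; a shape is binocularly projectable when it
    projects to both retinal images.  Returns the combined map and its
    statistics (per-eye projectable fractions and their conjunction).
    """
    same_grid = (left.grid_step == right.grid_step
                 and left.omega_lo == right.omega_lo
                 and left.omega_hi == right.omega_hi
                 and left.counts.shape == right.counts.shape)
    if not same_grid:
        raise ValidationError("left and right maps must share one grid")
    combined = BinocularMap(left=left, right=right)
    n = left.n_valid
    stats = {
        "n_valid_cells": n,
        "fraction_projectable_left": map_statistics(left)["fraction_projectable"],
        "fraction_projectable_right": map_statistics(right)["fraction_projectable"],
        "fraction_projectable_binocular": float(np.sum(combined.projectable)) / n,
    }
    return combined, stats


def map_to_frame(count_map: SolutionCountMap,
                 right: SolutionCountMap | None = None) -> pd.DataFrame:
    """Long-format table of a map (optionally joined with a right-eye map)."""
    wA, wB = np.meshgrid(count_map.omega_A_deg, count_map.omega_B_deg,
                         indexing="ij")
    frame = pd.DataFrame({
        "omega_A_deg": wA.ravel(),
        "omega_B_deg": wB.ravel(),
        "omega_C_deg": 180.0 - wA.ravel() - wB.ravel(),
        "valid": count_map.valid.ravel(),
        "n_solutions": count_map.counts.ravel(),
    })
    if right is not None:
        combined, _ = binocular_combine(count_map, right)
        frame = frame.rename(columns={"n_solutions": "n_solutions_left"})
        frame["n_solutions_right"] = right.counts.ravel()
        frame["binocular"] = combined.projectable.ravel()
    return frame
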