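"""Monte-Carlo frequency study of P3P solution counts.

For each value of ``theta_max``, random (shape, image) pairs are drawn
from the constrained-uniform samplers and the number of 3D interpretations
is tallied into the categories 0-4.  Shape and image draws use
independent, seed-derived substreams per condition, so the grid of
``theta_max`` values can be extended without perturbing existing
conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sampling import ImageRange, sample_images, sample_shapes, substream
from .solver import DEFAULT_TOLERANCES, SolverTolerances, count_solutions_batch

__all__ = [
    "FrequencyRecord",
    "run_frequency_experiment",
    "records_to_frame",
    "frame_to_records",
]

logger = logging.getLogger(__name__)

#: theta_max grid used in the original sweep: 2, 4, ..., 120 degrees.
DEFAULT_THETA_MAX_GRID = tuple(range(2, 121, 2))

_BATCH = 20_000


@dataclass(frozen=True)
class FrequencyRecord:
    """Tally of solution counts 0-4 for one (theta_max, mode) condition."""

    theta_max: float
    mode: str
    trials: int
    counts: tuple[int, int, int, int, int]

    def __post_init__(self):
        if self.trials < 1:
            raise ValidationError("trials must be >= 1")
        if len(self.counts) != 5 or any(c < 0 for c in self.counts):
            raise ValidationError("counts must be five non-negative integers")
        if sum(self.counts) != self.trials:
            raise ValidationError(
                f"counts sum to {sum(self.counts)}, expected {self.trials}")

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(c / self.trials for c in self.counts)


def run_frequency_experiment(theta_max_values, trials_per_condition: int,
                             mode: str = "full", seed: int = 0,
                             tolerances: SolverTolerances = DEFAULT_TOLERANCES,
                             ) -> list[FrequencyRecord]:
    """Estimate the distribution of solution counts for each ``theta_max``.

    Parameters
    ----------
    theta_max_values
        Iterable of theta_max values in degrees, each in (0, 180].
    trials_per_condition
        Number of random (shape, image) pairs per condition.
    mode
        ``"full"`` samples visual angles on (0.1 deg, theta_max); ``"half"``
        samples on (theta_max / 2, theta_max).
    seed
        Master seed; each condition gets shape/image substreams derived
        from it by condition index, independent of the grid contents.
    """
    theta_max_values = list(theta_max_values)
    if trials_per_condition < 1:
        raise ValidationError("trials_per_condition must be >= 1")
    for tm in theta_max_values:
        if not (0.0 < tm <= 180.0):
            raise ValidationError(f"theta_max={tm!r} must be in (0, 180]")

    records = []
    for idx, theta_max in enumerate(theta_max_values):
        image_range = ImageRange.for_mode(mode, theta_max)
        shape_rng = substream(seed, idx, 0)
        image_rng = substream(seed, idx, 1)
        tally = np.zeros(5, dtype=np.int64)
        remaining = trials_per_condition
        while remaining > 0:
            m = min(_BATCH, remaining)
            shapes = sample_shapes(shape_rng, m)
            images = sample_images(image_rng, image_range, m)
            counts = count_solutions_batch(
                shapes[:, 0], shapes[:, 1],
                images[:, 0], images[:, 1], images[:, 2],
                tolerances=tolerances)
            tally += np.bincount(counts, minlength=5)[:5]
            remaining -= m
        records.append(FrequencyRecord(
            theta_max=float(theta_max), mode=mode,
            trials=trials_per_condition, counts=tuple(int(c) for c in tally)))
        logger.info("theta_max=%g mode=%s: frequencies %s", theta_max, mode,
                    [f"{f:.4f}" for f in records[-1].frequencies])
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Long-format table: one row per (theta_max, solution-count) category."""
    rows = []
    for rec in records:
        for k in range(5):
            rows.append({
                "theta_max_deg": rec.theta_max,
                "mode": rec.mode,
                "n_solutions": k,
                "count": rec.counts[k],
                "frequency": rec.counts[k] / rec.trials,
                "trials": rec.trials,
            })
    return pd.DataFrame(
        rows, columns=["theta_max_deg", "mode", "n_solutions", "count",
                       "frequency", "trials"])


def frame_to_records(frame: pd.DataFrame) -> list[FrequencyRecord]:
    """Inverse of :func:`records_to_frame` (lossless round trip)."""
    records = []
    if len(frame) == 0:
        return records
    for (theta_max, mode, trials), grp in frame.groupby(
            ["theta_max_deg", "mode", "trials"], sort=False):
        counts = [0] * 5
        for _, row in grp.iterrows():
            counts[int(row["n_solutions"])] = int(row["count"])
        records.append(FrequencyRecord(
            theta_max=float(theta_max), mode=str(mode), trials=int(trials),
            counts=tuple(counts)))
    return records
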