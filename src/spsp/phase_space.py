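"""Channel-space trajectory, its center, and radial distances.

A multichannel recording is viewed as a trajectory in M-dimensional space:
sample n is the point whose coordinates are the M channel values at n.  The
trajectory's mean point is the center of the smallest-inertia hypersphere,
and the per-sample Euclidean distance from that center is the scalar series
that downstream symbolization consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dataset_io import FLOAT_FMT, Recording
from .errors import DomainError


@dataclass
class TrajectoryMatrix:
    """M x N matrix whose column n is the trajectory point at sample n."""

    points: np.ndarray
    source: tuple[str, str]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise DomainError(
                f"trajectory must be 2-D, got shape {self.points.shape}"
            )

    @property
    def n_dims(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]


@dataclass
class CenterPoint:
    """Coordinate-wise mean of a trajectory (hypersphere center)."""

    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 1:
            raise DomainError("center must be a 1-D vector")


@dataclass
class DistanceSeries:
    """Per-sample Euclidean distance of trajectory points from a center."""

    values: np.ndarray
    center: Optional[CenterPoint] = None
    source: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DomainError("distance series must be 1-D")
        if np.any(self.values < 0):
            raise DomainError("distances must be nonnegative")

    def __len__(self) -> int:
        return self.values.shape[0]


def build_trajectory(recording: Recording) -> TrajectoryMatrix:
    """Interpret the recording matrix as N points in M-dimensional space.

    No resampling and no time-delay embedding: column n of the output is
    column n of the input.
    """
    return TrajectoryMatrix(
        points=recording.data.copy(),
        source=(recording.subject_id, recording.trial_id),
    )


def compute_center(trajectory: TrajectoryMatrix) -> CenterPoint:
    """Arithmetic mean of the trajectory points, coordinate by coordinate."""
    if trajectory.n_points < 1:
        raise DomainError("cannot compute the center of an empty trajectory")
    return CenterPoint(coordinates=trajectory.points.mean(axis=1))


def radial_distances(
    trajectory: TrajectoryMatrix, center: CenterPoint
) -> DistanceSeries:
    """Euclidean (L2) distance of every trajectory point from ``center``."""
    if center.coordinates.shape[0] != trajectory.n_dims:
        raise DomainError(
            f"center has {center.coordinates.shape[0]} coordinates but the "
            f"trajectory is {trajectory.n_dims}-dimensional"
        )
    deltas = trajectory.points - center.coordinates[:, None]
    values = np.sqrt(np.einsum("ij,ij->j", deltas, deltas))
    return DistanceSeries(values=values, center=center, source=trajectory.source)


def distance_series_for(recording: Recording) -> DistanceSeries:
    """Convenience pipeline: trajectory -> per-trial center -> distances."""
    trajectory = build_trajectory(recording)
    return radial_distances(trajectory, compute_center(trajectory))


def export_distances(series: DistanceSeries, path: str) -> None:
    """Write the distance values as a one-column CSV for inspection."""
    with open(path, "w") as fh:
        for v in series.values:
            fh.write(format(v, FLOAT_FMT) + "\n")
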