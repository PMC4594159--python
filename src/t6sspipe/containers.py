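"""Shared in-memory containers for the pipeline stages.

Coordinate convention (used everywhere in the package): ``x`` is the column
index, ``y`` the row index, both 0-based, with the centre of pixel (0, 0) at
the origin. Physical coordinates are ``px * pixel_size_um`` micrometres.
Axial (z) positions are ``k * z_spacing_um`` for plane ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateHistogramError(ValueError):
    """Raised when an intensity histogram has a single value and cannot be split."""


class FieldTooCrowdedError(RuntimeError):
    """Raised when cell placement fails after the configured number of retries."""


@dataclass
class ImageStack:
    """A single-channel 3D intensity volume.

    ``voxels`` has shape (m, n, z) = (rows, columns, planes); intensities are
    finite and non-negative. ``z = 1`` represents a single plane.
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_spacing_um: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[:, :, None]
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty (m, n, z) array")
        if not np.all(np.isfinite(self.voxels)) or self.voxels.min() < 0:
            raise ValueError("intensities must be finite and non-negative")
        if self.pixel_size_um <= 0 or self.z_spacing_um <= 0:
            raise ValueError("pixel_size_um and z_spacing_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_z(self) -> int:
        return self.voxels.shape[2]

    def max_projection(self) -> np.ndarray:
        """Maximum-intensity projection along z, shape (m, n)."""
        return self.voxels.max(axis=2)

    def plane(self, k: int) -> np.ndarray:
        return self.voxels[:, :, k]


@dataclass
class LabelMask:
    """Integer-labelled segmentation mask; 0 is background, k > 0 is cell k.

    ``labels`` may be a 2D plane or a 3D (m, n, z) volume.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim not in (2, 3):
            raise ValueError("labels must be 2D or 3D")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")

    @property
    def n_cells(self) -> int:
        vals = np.unique(self.labels)
        return int((vals > 0).sum())

    @property
    def label_values(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals > 0]

    def max_projection(self) -> "LabelMask":
        """2D mask: per (row, col), the largest label present in the column of z."""
        if self.labels.ndim == 2:
            return self
        return LabelMask(self.labels.max(axis=2))

    def plane_labels(self) -> np.ndarray:
        return self.labels if self.labels.ndim == 2 else self.labels.max(axis=2)


@dataclass
class Focus:
    """A detected fluorescent punctum with sub-pixel centroid."""

    x: float
    y: float
    channel: str = ""
    frame: int = 0
    integrated_intensity: float = 0.0
    peak_snr: float = 0.0
    z_plane: int | None = None
    degenerate: bool = False  # centroid fell back to the integer peak

    def position_px(self) -> tuple[float, float]:
        return (self.x, self.y)

    def position_um(self, pixel_size_um: float) -> tuple[float, float]:
        return (self.x * pixel_size_um, self.y * pixel_size_um)


@dataclass
class Track:
    """A focus trajectory: time-ordered (frame, x, y, intensity) samples."""

    track_id: int
    points: list[tuple[int, float, float, float]] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [p[0] for p in self.points]

    @property
    def first_frame(self) -> int:
        return self.points[0][0]

    @property
    def last_frame(self) -> int:
        return self.points[-1][0]

    def t_start(self, frame_interval_s: float) -> float:
        return self.first_frame * frame_interval_s

    def t_end(self, frame_interval_s: float) -> float:
        return self.last_frame * frame_interval_s

    def lifetime_s(self, frame_interval_s: float) -> float:
        """Observed lifetime; an n-frame track lives n * frame_interval."""
        return (self.last_frame - self.first_frame + 1) * frame_interval_s
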