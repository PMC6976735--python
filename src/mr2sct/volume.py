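"""In-memory containers for image volumes, multi-sequence MR stacks and dose grids.

Axis convention (pinned for the whole package): arrays are indexed
``(slice, row, column)`` = (z, y, x); indices are 0-based and a voxel's
center sits at ``index * spacing`` mm in the volume frame (plus ``origin``).
``spacing`` is mm per axis in the same (z, y, x) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError

_SPACING_ATOL = 1e-6


@dataclass
class ImageVolume:
    """A 3D scalar grid (HU or MR intensity) with its geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_geometry(self, other: "ImageVolume | MultiSequenceVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=_SPACING_ATOL)
            and np.allclose(self.origin, other.origin, atol=_SPACING_ATOL)
        )

    def check_geometry(self, other: "ImageVolume | MultiSequenceVolume") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"geometry mismatch: {self.shape}/{self.spacing} vs "
                f"{other.shape}/{other.spacing}"
            )

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=np.asarray(data))

    def copy(self) -> "ImageVolume":
        return replace(self, data=self.data.copy())


@dataclass
class MultiSequenceVolume:
    """Three co-registered MR channels (T1w, T2w, FLAIR) on one geometry.

    ``data`` has shape (3, slices, rows, cols); channel order is fixed.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    CHANNELS = ("t1", "t2", "flair")

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError(
                f"MultiSequenceVolume data must have shape (3, z, y, x), got {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> ImageVolume:
        idx = self.CHANNELS.index(name)
        return ImageVolume(self.data[idx], self.spacing, self.origin)

    def same_geometry(self, other) -> bool:
        return ImageVolume.same_geometry(self, other)  # type: ignore[arg-type]

    def check_geometry(self, other) -> None:
        ImageVolume.check_geometry(self, other)  # type: ignore[arg-type]

    def with_data(self, data: np.ndarray) -> "MultiSequenceVolume":
        return replace(self, data=np.asarray(data))


@dataclass
class BodyMask:
    """Boolean foreground grid on an ImageVolume geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("BodyMask data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_geometry(self, other) -> bool:
        return ImageVolume.same_geometry(self, other)  # type: ignore[arg-type]

    def check_geometry(self, other) -> None:
        ImageVolume.check_geometry(self, other)  # type: ignore[arg-type]


@dataclass
class DoseGrid:
    """A 3D dose array (Gy) on an ImageVolume geometry with its prescription dose.

    ``prescription`` (Gy) is the normalization dose used by gamma analysis and
    the V95% DVH metric.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    prescription: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("DoseGrid data must be 3D")
        if self.prescription <= 0:
            raise ValueError("prescription dose must be positive")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def max_dose(self) -> float:
        return float(self.data.max())

    def same_geometry(self, other) -> bool:
        return ImageVolume.same_geometry(self, other)  # type: ignore[arg-type]

    def check_geometry(self, other) -> None:
        ImageVolume.check_geometry(self, other)  # type: ignore[arg-type]
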