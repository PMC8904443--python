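"""Core data containers: voxel geometry and the complex image time-series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class VoxelGeometry:
    """In-plane and through-plane voxel dimensions, all in millimetres.

    ``slab_height`` (thickness + gap) is the per-slice height used by the
    method-of-slices volume computation.
    """

    pixel_spacing: float
    slice_thickness: float
    slice_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0 or self.slice_gap < 0:
            raise InvalidInputError(
                "geometry requires pixel_spacing > 0, slice_thickness > 0, slice_gap >= 0"
            )

    @property
    def slab_height(self) -> float:
        return self.slice_thickness + self.slice_gap


@dataclass
class ImageSeries:
    """Complex-valued short-axis image stack of shape (n_slices, n_frames, rows, cols).

    ``dt`` is the frame spacing in seconds.  ``magnitude_only`` marks series read
    from a magnitude-only file, whose imaginary part was assumed zero.
    """

    data: np.ndarray
    dt: float
    geometry: VoxelGeometry
    magnitude_only: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise InvalidInputError(
                f"series must be 4-D (n_slices, n_frames, rows, cols); got shape {self.data.shape}"
            )
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if self.dt <= 0:
            raise InvalidInputError("frame spacing dt must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def duration(self) -> float:
        """Length of the acquisition window in seconds."""
        return self.n_frames * self.dt

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz."""
        return 0.5 / self.dt

    def slice_frames(self, slice_index: int) -> np.ndarray:
        """Return the (n_frames, rows, cols) stack for one slice."""
        return self.data[slice_index]
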