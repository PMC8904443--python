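"""Analysis-region construction from end-diastole / end-systole segmentations.

Two region types are derived from the input masks:

* the per-chamber ROI — the annular band swept by the moving wall, obtained by
  subtracting the end-systole endocardial mask from the end-diastole mask;
* the ventricular anatomy (VA) — the union of the LV and RV end-diastolic
  masks, over which the voxelwise correlation map is defined.  ``M`` denotes
  its voxel count.

All masks use 0-based row/col voxel indices and must share the grid of the
image series they annotate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import VoxelGeometry
from .errors import EmptyROIError, EmptyVAMaskError, InvalidInputError

CHAMBERS = ("lv", "rv")
PHASES = ("ed", "es")


def _as_bool_mask(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise InvalidInputError(f"{name} mask values must be in {{0, 1}}")
    return arr.astype(bool)


@dataclass
class MaskSet:
    """Binary LV/RV endocardial masks at ED and ES, stacked per slice.

    Each array has shape (n_slices, rows, cols).  ``ed_frame``/``es_frame``
    record which frames of the companion series the segmentations refer to.
    """

    lv_ed: np.ndarray
    lv_es: np.ndarray
    rv_ed: np.ndarray
    rv_es: np.ndarray
    geometry: VoxelGeometry
    ed_frame: int = 0
    es_frame: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = set()
        for chamber in CHAMBERS:
            for phase in PHASES:
                name = f"{chamber}_{phase}"
                mask = _as_bool_mask(getattr(self, name), name)
                if mask.ndim != 3:
                    raise InvalidInputError(f"{name} must be 3-D (n_slices, rows, cols)")
                setattr(self, name, mask)
                shapes.add(mask.shape)
        if len(shapes) != 1:
            raise InvalidInputError(f"all masks must share one shape; got {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.lv_ed.shape

    @property
    def n_slices(self) -> int:
        return self.lv_ed.shape[0]

    def mask(self, chamber: str, phase: str) -> np.ndarray:
        if chamber not in CHAMBERS or phase not in PHASES:
            raise InvalidInputError(f"unknown chamber/phase: {chamber!r}/{phase!r}")
        return getattr(self, f"{chamber}_{phase}")


@dataclass
class ROIMask:
    """Per-chamber, per-slice region swept by the endocardial wall."""

    mask: np.ndarray
    chamber: str = ""
    slice_index: int = 0

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class VAMask:
    """Ventricular anatomy for one slice: union of LV and RV ED masks."""

    mask: np.ndarray
    slice_index: int = 0

    @property
    def m(self) -> int:
        """Total number of voxels within the ventricular anatomy."""
        return int(self.mask.sum())


def make_roi(
    ed_mask: np.ndarray,
    es_mask: np.ndarray,
    *,
    chamber: str = "",
    slice_index: int = 0,
) -> ROIMask:
    """Subtract the ES segmentation from the ED segmentation.

    The ROI voxel set is ``{v : ed(v)=1 and es(v)=0}``.  ES voxels lying
    outside ED (possible with noisy segmentations) are ignored with a warning.

    Raises
    ------
    EmptyROIError
        If the subtraction leaves no voxels — the caller should reject the slice.
    InvalidInputError
        If the two masks do not share a shape.
    """
    ed = _as_bool_mask(ed_mask, "ed")
    es = _as_bool_mask(es_mask, "es")
    if ed.shape != es.shape:
        raise InvalidInputError(f"mask shape mismatch: ed {ed.shape} vs es {es.shape}")
    outside = int((es & ~ed).sum())
    if outside:
        warnings.warn(
            f"{outside} ES voxel(s) lie outside the ED mask "
            f"(chamber={chamber or '?'}, slice={slice_index}); they do not affect the ROI",
            stacklevel=2,
        )
    roi = ed & ~es
    if not roi.any():
        raise EmptyROIError(
            f"ED minus ES left no voxels (chamber={chamber or '?'}, slice={slice_index})"
        )
    return ROIMask(mask=roi, chamber=chamber, slice_index=slice_index)


def make_va(lv_ed_mask: np.ndarray, rv_ed_mask: np.ndarray, *, slice_index: int = 0) -> VAMask:
    """Union of the LV and RV end-diastolic masks (voxelwise OR)."""
    lv = _as_bool_mask(lv_ed_mask, "lv_ed")
    rv = _as_bool_mask(rv_ed_mask, "rv_ed")
    if lv.shape != rv.shape:
        raise InvalidInputError(f"mask shape mismatch: lv {lv.shape} vs rv {rv.shape}")
    va = lv | rv
    if not va.any():
        raise EmptyVAMaskError(f"both ED masks are empty (slice={slice_index})")
    return VAMask(mask=va, slice_index=slice_index)
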