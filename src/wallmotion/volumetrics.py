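"""Volumetric indices (EDV, ESV, SV, EF) and image-quality metrics (SNR, CNR).

Volumes use the method of slices: each slice contributes its segmented area
times the slab height (slice thickness + inter-slice gap, matching a gapped
acquisition).  SNR/CNR follow the background-standard-deviation convention:

    SNR = mean(|blood|) / SD(|background|)
    CNR = (mean(|blood|) - mean(|myocardium|)) / SD(|background|)

For magnitude images whose background is pure complex Gaussian noise the
optional Rayleigh correction divides SD(|background|) by sqrt(2 - pi/2),
turning it into an estimate of the per-component noise standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anatomy import CHAMBERS, MaskSet
from .errors import InvalidInputError, InvalidParameterError

RAYLEIGH_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))


@dataclass
class VolumetricResult:
    """Per-chamber volumes (ml) and ejection fraction (%)."""

    chamber: str
    edv: float
    esv: float
    sv: float
    ef: float
    slice_areas_mm2: pd.DataFrame | None = None


@dataclass
class QualityResult:
    """SNR/CNR of one frame with the convention used to compute them."""

    snr: float
    cnr: float
    rayleigh_corrected: bool
    blood_voxels: int
    myocardium_voxels: int
    background_voxels: int
    myocardium_brighter: bool


def chamber_volume(
    masks: np.ndarray,
    pixel_spacing: float,
    slice_thickness: float,
    slice_gap: float = 0.0,
) -> float:
    """Method-of-slices volume in ml from a (n_slices, rows, cols) mask stack."""
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    if masks.ndim != 3 or masks.shape[0] < 1:
        raise InvalidInputError("mask stack must be (n_slices, rows, cols) with >= 1 slice")
    if pixel_spacing <= 0 or slice_thickness <= 0 or slice_gap < 0:
        raise InvalidParameterError("geometry must be positive (gap >= 0)")
    counts = masks.astype(bool).sum(axis=(1, 2))
    slab = slice_thickness + slice_gap
    return float(counts.sum() * pixel_spacing**2 * slab / 1000.0)


def ejection_fraction(edv: float, esv: float) -> tuple[float, float]:
    """Stroke volume (ml) and ejection fraction (%) from EDV/ESV."""
    if edv <= 0:
        raise InvalidParameterError("EDV must be positive")
    if esv < 0:
        raise InvalidParameterError("ESV must be >= 0")
    sv = edv - esv
    return sv, 100.0 * sv / edv


def compute_volumetrics(maskset: MaskSet) -> dict[str, VolumetricResult]:
    """EDV/ESV/SV/EF per chamber plus the slice-wise area table."""
    geom = maskset.geometry
    out: dict[str, VolumetricResult] = {}
    for chamber in CHAMBERS:
        ed = maskset.mask(chamber, "ed")
        es = maskset.mask(chamber, "es")
        edv = chamber_volume(ed, geom.pixel_spacing, geom.slice_thickness, geom.slice_gap)
        esv = chamber_volume(es, geom.pixel_spacing, geom.slice_thickness, geom.slice_gap)
        sv, ef = ejection_fraction(edv, esv)
        areas = pd.DataFrame(
            {
                "slice": np.arange(maskset.n_slices),
                "ed_area_mm2": ed.sum(axis=(1, 2)) * geom.pixel_spacing**2,
                "es_area_mm2": es.sum(axis=(1, 2)) * geom.pixel_spacing**2,
            }
        )
        out[chamber] = VolumetricResult(
            chamber=chamber, edv=edv, esv=esv, sv=sv, ef=ef, slice_areas_mm2=areas
        )
    return out


def snr_cnr(
    frame: np.ndarray,
    blood_roi: np.ndarray,
    myocardium_roi: np.ndarray,
    background_roi: np.ndarray,
    *,
    rayleigh_correction: bool = False,
) -> QualityResult:
    """Blood-pool SNR and blood–myocardium CNR of one (possibly complex) frame."""
    frame = np.abs(np.asarray(frame))
    rois = {}
    for name, roi in (
        ("blood", blood_roi),
        ("myocardium", myocardium_roi),
        ("background", background_roi),
    ):
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != frame.shape:
            raise InvalidInputError(f"{name} ROI shape {roi.shape} != frame {frame.shape}")
        if not roi.any():
            raise InvalidInputError(f"{name} ROI is empty")
        rois[name] = roi
    if (rois["blood"] & rois["myocardium"]).any() or (rois["blood"] & rois["background"]).any() or (
        rois["myocardium"] & rois["background"]
    ).any():
        raise InvalidInputError("blood, myocardium and background ROIs must be disjoint")

    noise_sd = float(frame[rois["background"]].std(ddof=1))
    if noise_sd == 0:
        raise InvalidInputError("background standard deviation is zero")
    if rayleigh_correction:
        noise_sd /= RAYLEIGH_SD_FACTOR
    blood_mean = float(frame[rois["blood"]].mean())
    myo_mean = float(frame[rois["myocardium"]].mean())
    return QualityResult(
        snr=blood_mean / noise_sd,
        cnr=(blood_mean - myo_mean) / noise_sd,
        rayleigh_corrected=rayleigh_correction,
        blood_voxels=int(rois["blood"].sum()),
        myocardium_voxels=int(rois["myocardium"].sum()),
        background_voxels=int(rois["background"].sum()),
        myocardium_brighter=myo_mean > blood_mean,
    )
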