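"""NIfTI-1 readers/writers, mask manifests, and run-configuration validation.

Dialect: a complex series is carried as a pair of NIfTI-1 volumes holding the
real and imaginary parts, with on-disk axis order (rows, cols, slices, frames).
The frame spacing ``dt`` is stored in pixdim[4] with time units of seconds.
A magnitude-only single file is accepted on read (imaginary part assumed zero,
flagged on the resulting series).  Masks travel as unsigned-byte volumes named
by a JSON manifest mapping chamber/phase to files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .anatomy import CHAMBERS, PHASES, MaskSet
from .datatypes import ImageSeries, VoxelGeometry
from .errors import ConfigError, InvalidInputError
from .indices import DEFAULT_CARDIAC_BAND
from .signals import DEFAULT_CUTOFF_HZ


def _affine(geom: VoxelGeometry) -> np.ndarray:
    return np.diag([geom.pixel_spacing, geom.pixel_spacing, geom.slab_height, 1.0])


def _to_disk_order(data: np.ndarray) -> np.ndarray:
    # (slices, frames, rows, cols) -> (rows, cols, slices, frames)
    return np.transpose(data, (2, 3, 0, 1))


def _from_disk_order(data: np.ndarray) -> np.ndarray:
    return np.transpose(data, (2, 3, 0, 1))


def _make_img(data: np.ndarray, series: ImageSeries) -> nib.Nifti1Image:
    img = nib.Nifti1Image(_to_disk_order(data).astype(np.float64), _affine(series.geometry))
    hdr = img.header
    zooms = list(hdr.get_zooms()[:3]) + [series.dt]
    hdr.set_zooms(zooms)
    hdr.set_xyzt_units(xyz="mm", t="sec")
    # stash the gap so geometry round-trips exactly
    hdr["intent_p1"] = series.geometry.slice_thickness
    hdr["intent_p2"] = series.geometry.slice_gap
    return img


def write_series(series: ImageSeries, out_dir: str | Path, stem: str = "series") -> dict[str, Path]:
    """Write real/imag NIfTI pair; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "real": out_dir / f"{stem}_real.nii",
        "imag": out_dir / f"{stem}_imag.nii",
    }
    nib.save(_make_img(series.data.real, series), paths["real"])
    nib.save(_make_img(series.data.imag, series), paths["imag"])
    return paths


def _load_checked(path: str | Path) -> nib.Nifti1Image:
    try:
        img = nib.load(str(path))
        img.header  # force header parse
        return img
    except Exception as exc:  # nibabel raises several unrelated types
        raise InvalidInputError(f"cannot read NIfTI file {path}: {exc}") from exc


def _geometry_from_header(img: nib.Nifti1Image, path) -> tuple[VoxelGeometry, float]:
    # header pixdims are float32; round to recover the written decimals
    zooms = [round(float(z), 6) for z in img.header.get_zooms()]
    missing = []
    pixel_spacing = float(zooms[0]) if len(zooms) > 0 else 0.0
    dt = float(zooms[3]) if len(zooms) > 3 else 0.0
    thickness = round(float(img.header["intent_p1"]), 6)
    gap = round(float(img.header["intent_p2"]), 6)
    if thickness <= 0:
        thickness = float(zooms[2]) if len(zooms) > 2 else 0.0
        gap = 0.0
    if pixel_spacing <= 0:
        missing.append("pixel spacing (pixdim1)")
    if thickness <= 0:
        missing.append("slice thickness (pixdim3/intent_p1)")
    if dt <= 0:
        missing.append("frame spacing dt (pixdim4)")
    if missing:
        raise InvalidInputError(f"{path}: missing geometry metadata: {', '.join(missing)}")
    return VoxelGeometry(pixel_spacing, thickness, gap), dt


def read_series(real_path: str | Path, imag_path: str | Path | None = None) -> ImageSeries:
    """Read a complex series from a real/imag pair, or a magnitude-only file.

    Raises a diagnostic error (and constructs no partial object) on corrupted
    headers, missing geometry fields, or a real/imag shape mismatch.
    """
    real_img = _load_checked(real_path)
    geom, dt = _geometry_from_header(real_img, real_path)
    real = np.asarray(real_img.get_fdata())
    if real.ndim != 4:
        raise InvalidInputError(f"{real_path}: expected 4-D data, got shape {real.shape}")
    if imag_path is not None:
        imag_img = _load_checked(imag_path)
        imag = np.asarray(imag_img.get_fdata())
        if imag.shape != real.shape:
            raise InvalidInputError(
                f"real/imag shape mismatch: {real.shape} vs {imag.shape}"
            )
        data = real + 1j * imag
        magnitude_only = False
    else:
        data = real.astype(np.complex128)
        magnitude_only = True
    return ImageSeries(
        data=_from_disk_order(data),
        dt=dt,
        geometry=geom,
        magnitude_only=magnitude_only,
    )


# -- masks ----------------------------------------------------------------


def write_masks(maskset: MaskSet, out_dir: str | Path) -> Path:
    """Write the four masks as uint8 NIfTI volumes plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geom = maskset.geometry
    manifest: dict = {
        "geometry": {
            "pixel_spacing_mm": geom.pixel_spacing,
            "slice_thickness_mm": geom.slice_thickness,
            "slice_gap_mm": geom.slice_gap,
        },
        "ed_frame": maskset.ed_frame,
        "es_frame": maskset.es_frame,
        "masks": {},
    }
    for chamber in CHAMBERS:
        manifest["masks"][chamber] = {}
        for phase in PHASES:
            name = f"{chamber}_{phase}.nii"
            arr = maskset.mask(chamber, phase).astype(np.uint8)
            # (slices, rows, cols) -> (rows, cols, slices)
            img = nib.Nifti1Image(np.transpose(arr, (1, 2, 0)), _affine(geom))
            nib.save(img, out_dir / name)
            manifest["masks"][chamber][phase] = name
    manifest_path = out_dir / "masks.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_masks(manifest_path: str | Path) -> MaskSet:
    """Load a MaskSet from a JSON manifest written by :func:`write_masks`."""
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InvalidInputError(f"cannot read manifest {manifest_path}: {exc}") from exc
    try:
        g = manifest["geometry"]
        geom = VoxelGeometry(
            g["pixel_spacing_mm"], g["slice_thickness_mm"], g.get("slice_gap_mm", 0.0)
        )
        arrays = {}
        for chamber in CHAMBERS:
            for phase in PHASES:
                path = manifest_path.parent / manifest["masks"][chamber][phase]
                data = np.asarray(_load_checked(path).get_fdata())
                arrays[f"{chamber}_{phase}"] = np.transpose(data, (2, 0, 1)) > 0.5
    except KeyError as exc:
        raise InvalidInputError(f"manifest {manifest_path} missing key {exc}") from exc
    return MaskSet(
        geometry=geom,
        ed_frame=int(manifest.get("ed_frame", 0)),
        es_frame=manifest.get("es_frame"),
        **arrays,
    )


def write_correlation_map(values: np.ndarray, geom: VoxelGeometry, path: str | Path) -> None:
    """Write a (rows, cols) or (slices, rows, cols) correlation map as NIfTI."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    img = nib.Nifti1Image(np.transpose(arr, (1, 2, 0)), _affine(geom))
    nib.save(img, str(path))


# -- run configuration -----------------------------------------------------

_AGG_RULES = ("roi_weighted", "mean")


@dataclass
class RunConfig:
    """Resolved configuration for the end-to-end pipeline.

    Every analysis output embeds this (plus the package version) so runs are
    reproducible from their artifacts alone.
    """

    cutoff_hz: float = DEFAULT_CUTOFF_HZ
    band_hz: tuple[float, float] = DEFAULT_CARDIAC_BAND
    mode: str = "modulus"
    numerator_halfwidth: int = 0
    aggregation: str = "roi_weighted"
    quartile_method: str = "linear"
    seed: int = 0
    n_subjects_per_group: int = 12
    out_dir: str = "results"
    phantom_overrides: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if self.cutoff_hz < 0:
            raise ConfigError("cutoff_hz must be >= 0")
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ConfigError(f"band_hz {self.band_hz} must satisfy 0 < lo < hi")
        if self.mode not in ("modulus", "signed"):
            raise ConfigError(f"mode must be 'modulus' or 'signed', got {self.mode!r}")
        if self.numerator_halfwidth < 0:
            raise ConfigError("numerator_halfwidth must be >= 0")
        if self.aggregation not in _AGG_RULES and not self.aggregation.startswith("slice:"):
            raise ConfigError(f"unknown aggregation rule {self.aggregation!r}")
        if self.quartile_method != "linear":
            raise ConfigError("only the 'linear' quartile method is implemented")
        if self.n_subjects_per_group < 1:
            raise ConfigError("n_subjects_per_group must be >= 1")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            raw = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "band_hz" in raw:
            raw["band_hz"] = tuple(raw["band_hz"])
        return cls(**raw).validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_hz"] = list(self.band_hz)
        d["package_version"] = __version__
        return d
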