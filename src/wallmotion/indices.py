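"""Temporospatial indices of ventricular wall motion.

Two scalar indices are computed per chamber from a complex image time-series:

* **temporal periodicity** — the fraction of the high-pass-filtered reference
  signal's spectral energy (root sum square) concentrated at the positive and
  negative cardiac-frequency bins.  Because the image data are complex, the
  spectrum is generally not conjugate-symmetric and both signs contribute
  independently.
* **spatial coherence** — the mean, over the ventricular anatomy (VA), of the
  per-voxel Pearson correlation between each voxel's (filtered) time-series
  and the reference wall-motion signal.

Spectral convention: the plain unnormalized DFT (`numpy.fft.fft`), so that
``sum |x|^2 == sum |S|^2 / T`` (Parseval).  Periodicity is a ratio of spectral
magnitudes and is therefore independent of this normalization constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import CHAMBERS, MaskSet, ROIMask, VAMask, make_roi, make_va
from .datatypes import ImageSeries
from .errors import (
    DegenerateSignalError,
    EmptyROIError,
    EmptyVAMaskError,
    InvalidInputError,
    InvalidParameterError,
)
from .signals import DEFAULT_CUTOFF_HZ, ReferenceSignal, highpass, highpass_array, spatial_average

#: Default cardiac search band in Hz (42–180 bpm), covering resting and
#: exercise heart rates.
DEFAULT_CARDIAC_BAND = (0.7, 3.0)

MIN_FRAMES = 16


@dataclass
class SpectralProfile:
    """DFT of a reference signal with bins addressable by signed frequency.

    ``values`` and ``freqs`` are stored in `numpy.fft` order (bin ``k`` holds
    frequency ``k / (T*dt)`` for ``k < T/2``, negative frequencies above).
    """

    values: np.ndarray
    freqs: np.ndarray
    dt: float
    filtered: bool
    cutoff: float | None = None

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def df(self) -> float:
        """Frequency resolution in Hz."""
        return 1.0 / (self.n_bins * self.dt)

    def shifted(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (freqs, values) sorted from most negative to most positive frequency."""
        return np.fft.fftshift(self.freqs), np.fft.fftshift(self.values)

    def pair_power(self, bin_index: int) -> float:
        """|S(+f)|^2 + |S(-f)|^2 for the positive-frequency bin ``bin_index``."""
        t = self.n_bins
        if not 0 < bin_index < t:
            raise InvalidParameterError(f"bin index {bin_index} out of range")
        neg = (t - bin_index) % t
        power = abs(self.values[bin_index]) ** 2
        if neg != bin_index:
            power += abs(self.values[neg]) ** 2
        return float(power)

    def total_pair_power(self) -> float:
        """Sum of |S|^2 over every bin (each signed bin counted once)."""
        return float(np.sum(np.abs(self.values) ** 2))


@dataclass
class CardiacFrequency:
    """Dominant in-band spectral peak of the reference signal."""

    bin_index: int
    frequency: float
    band: tuple[float, float]
    peak_magnitude: float


@dataclass
class CorrelationMap:
    """Per-voxel correlation against the reference, defined on the VA.

    ``values`` is a float grid with NaN outside the VA.  ``mode`` is
    ``"modulus"`` (|r|, in [0, 1]) or ``"signed"`` (Re r, in [-1, 1]).
    """

    values: np.ndarray
    va_mask: np.ndarray
    mode: str
    chamber: str = ""
    slice_index: int = 0
    zero_variance_count: int = 0

    def va_values(self) -> np.ndarray:
        return self.values[self.va_mask]


@dataclass
class SliceResult:
    """All intermediates for one chamber on one slice."""

    chamber: str
    slice_index: int
    periodicity: float
    coherence: float
    cardiac_frequency: float
    roi_voxels: int
    va_voxels: int
    zero_variance_count: int


@dataclass
class TemporospatialResult:
    """Per-slice index measurements plus the per-subject aggregate."""

    per_slice: list[SliceResult]
    aggregated: dict[str, dict[str, float]]
    aggregation: str
    skipped_slices: dict[int, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_records(self) -> list[dict]:
        rows = [
            {
                "chamber": r.chamber,
                "slice": r.slice_index,
                "periodicity": r.periodicity,
                "coherence": r.coherence,
                "cardiac_frequency_hz": r.cardiac_frequency,
                "roi_voxels": r.roi_voxels,
                "va_voxels": r.va_voxels,
            }
            for r in self.per_slice
        ]
        return rows


def spectrum(signal: ReferenceSignal) -> SpectralProfile:
    """Discrete Fourier transform of a reference signal (unnormalized DFT)."""
    t = signal.n_frames
    if t < MIN_FRAMES:
        raise InvalidInputError(f"need at least {MIN_FRAMES} frames; got {t}")
    values = np.fft.fft(signal.values)
    freqs = np.fft.fftfreq(t, d=signal.dt)
    return SpectralProfile(
        values=values, freqs=freqs, dt=signal.dt, filtered=signal.filtered, cutoff=signal.cutoff
    )


def detect_cardiac_frequency(
    spec: SpectralProfile, band: tuple[float, float] = DEFAULT_CARDIAC_BAND
) -> CardiacFrequency:
    """Locate the dominant spectral peak within the cardiac band.

    The peak maximizes ``|S(+f)|^2 + |S(-f)|^2`` over positive in-band
    frequencies; ties break toward the lower frequency.
    """
    lo, hi = band
    nyquist = 0.5 / spec.dt
    if not (0 < lo < hi) or hi >= nyquist + 1e-12:
        raise InvalidParameterError(f"band {band} must satisfy 0 < lo < hi < Nyquist ({nyquist} Hz)")
    candidates = np.nonzero(
        (spec.freqs > 0) & (spec.freqs >= lo) & (spec.freqs <= hi)
    )[0]
    if candidates.size == 0:
        raise InvalidParameterError(
            f"band {band} contains no DFT bins at resolution {spec.df} Hz"
        )
    powers = np.array([spec.pair_power(int(k)) for k in candidates])
    # argmax returns the first maximum; candidates are in increasing frequency
    # order, so ties already break toward the lower frequency.
    best = int(candidates[int(np.argmax(powers))])
    return CardiacFrequency(
        bin_index=best,
        frequency=float(spec.freqs[best]),
        band=(lo, hi),
        peak_magnitude=float(np.sqrt(powers.max())),
    )


def temporal_periodicity(
    spec: SpectralProfile,
    fc: CardiacFrequency,
    *,
    numerator_halfwidth: int = 0,
) -> float:
    """Ratio of cardiac-frequency spectral energy to total spectral energy.

    Numerator: root sum square of S at the ±cardiac-frequency bins (optionally
    widened by ``numerator_halfwidth`` bins on each side; default exactly the
    single ± pair).  Denominator: root sum square over all retained bins.
    The value lies in [0, 1] and is invariant to global scaling and phase.

    Requires a spectrum computed from a high-pass-filtered signal, so the
    zeroed stop band (including DC) contributes nothing to the denominator.
    """
    if not spec.filtered:
        raise InvalidInputError("temporal periodicity requires a high-pass-filtered spectrum")
    if numerator_halfwidth < 0:
        raise InvalidParameterError("numerator_halfwidth must be >= 0")
    total = spec.total_pair_power()
    if total <= 0:
        raise DegenerateSignalError("all-zero spectrum: periodicity undefined")
    num = 0.0
    t = spec.n_bins
    for offset in range(-numerator_halfwidth, numerator_halfwidth + 1):
        k = fc.bin_index + offset
        if 0 < k < t:
            num += spec.pair_power(k)
    return float(np.sqrt(num) / np.sqrt(total))


def _complex_pearson(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson coefficient of complex samples along axis 0.

    ``x`` has shape (T, n_voxels); ``ref`` has shape (T,).  Returns the complex
    coefficient per voxel; zero-variance voxels yield nan.
    """
    xc = x - x.mean(axis=0, keepdims=True)
    rc = ref - ref.mean()
    num = np.einsum("t,tv->v", np.conj(rc), xc)
    denom = np.sqrt(np.sum(np.abs(xc) ** 2, axis=0)) * np.sqrt(np.sum(np.abs(rc) ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)


def correlation_map(
    frames: np.ndarray,
    ref: ReferenceSignal,
    va: VAMask | np.ndarray,
    *,
    mode: str = "modulus",
    chamber: str = "",
    slice_index: int = 0,
) -> CorrelationMap:
    """Voxelwise Pearson correlation against the reference over the VA.

    Each VA voxel's time-series is high-pass filtered with the same cutoff as
    the reference before the correlation is computed on the complex samples
    (mean-subtracted cross-covariance over the product of standard deviations).
    In modulus mode the map holds |r|; in signed mode, Re r.  Voxels with a
    zero-variance time-series are assigned R = 0 and counted.
    """
    if mode not in ("modulus", "signed"):
        raise InvalidParameterError(f"unknown correlation mode {mode!r}")
    if not ref.filtered:
        raise InvalidInputError("reference signal must be high-pass filtered first")
    mask = va.mask if isinstance(va, VAMask) else np.asarray(va, dtype=bool)
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[1:] != mask.shape:
        raise InvalidInputError("frames and VA mask must share the in-plane grid")
    t = frames.shape[0]
    if t < MIN_FRAMES:
        raise InvalidInputError(f"need at least {MIN_FRAMES} frames; got {t}")
    if t != ref.n_frames:
        raise InvalidInputError("frame count mismatch between series and reference")

    x = frames[:, mask]  # (T, n_voxels)
    if ref.cutoff is not None and ref.cutoff > 0:
        x = highpass_array(x, ref.dt, ref.cutoff, axis=0)
    coeff = _complex_pearson(x, ref.values)
    if mode == "modulus":
        r = np.abs(coeff)
    else:
        r = coeff.real
    zero_var = np.isnan(r)
    r = np.where(zero_var, 0.0, r)

    values = np.full(mask.shape, np.nan)
    values[mask] = r
    return CorrelationMap(
        values=values,
        va_mask=mask,
        mode=mode,
        chamber=chamber,
        slice_index=slice_index if not isinstance(va, VAMask) else va.slice_index,
        zero_variance_count=int(zero_var.sum()),
    )


def spatial_coherence(cmap: CorrelationMap, va: VAMask | np.ndarray | None = None) -> float:
    """Mean of the correlation map over the M voxels of the ventricular anatomy."""
    mask = cmap.va_mask if va is None else (va.mask if isinstance(va, VAMask) else np.asarray(va, dtype=bool))
    m = int(mask.sum())
    if m == 0:
        raise EmptyVAMaskError("ventricular anatomy is empty (M = 0)")
    return float(cmap.values[mask].sum() / m)


@dataclass
class CharacterizeOptions:
    """Tunable parameters of the per-subject pipeline."""

    cutoff: float = DEFAULT_CUTOFF_HZ
    band: tuple[float, float] = DEFAULT_CARDIAC_BAND
    mode: str = "modulus"
    numerator_halfwidth: int = 0
    #: "roi_weighted" (ROI-voxel-weighted mean over slices), "mean"
    #: (unweighted), or "slice:<k>" (single designated slice).
    aggregation: str = "roi_weighted"


def _aggregate(results: list[SliceResult], rule: str) -> dict[str, float]:
    if rule.startswith("slice:"):
        k = int(rule.split(":", 1)[1])
        chosen = [r for r in results if r.slice_index == k]
        if not chosen:
            raise InvalidParameterError(f"designated slice {k} produced no result")
        results = chosen
        weights = np.ones(len(results))
    elif rule == "mean":
        weights = np.ones(len(results))
    elif rule == "roi_weighted":
        weights = np.array([r.roi_voxels for r in results], dtype=float)
    else:
        raise InvalidParameterError(f"unknown aggregation rule {rule!r}")
    weights = weights / weights.sum()
    return {
        "periodicity": float(np.dot(weights, [r.periodicity for r in results])),
        "coherence": float(np.dot(weights, [r.coherence for r in results])),
        "cardiac_frequency_hz": float(np.dot(weights, [r.cardiac_frequency for r in results])),
        "n_slices": float(len(results)),
    }


def characterize_slice(
    frames: np.ndarray,
    masks: MaskSet,
    slice_index: int,
    dt: float,
    opts: CharacterizeOptions,
) -> list[SliceResult]:
    """Run the ROI → reference → filter → spectrum → map pipeline for one slice."""
    va = make_va(
        masks.mask("lv", "ed")[slice_index],
        masks.mask("rv", "ed")[slice_index],
        slice_index=slice_index,
    )
    out = []
    for chamber in CHAMBERS:
        roi = make_roi(
            masks.mask(chamber, "ed")[slice_index],
            masks.mask(chamber, "es")[slice_index],
            chamber=chamber,
            slice_index=slice_index,
        )
        ref = highpass(spatial_average(frames, roi, dt), opts.cutoff)
        spec = spectrum(ref)
        fc = detect_cardiac_frequency(spec, opts.band)
        periodicity = temporal_periodicity(
            spec, fc, numerator_halfwidth=opts.numerator_halfwidth
        )
        cmap = correlation_map(frames, ref, va, mode=opts.mode, chamber=chamber)
        coherence = spatial_coherence(cmap)
        out.append(
            SliceResult(
                chamber=chamber,
                slice_index=slice_index,
                periodicity=periodicity,
                coherence=coherence,
                cardiac_frequency=fc.frequency,
                roi_voxels=roi.voxel_count,
                va_voxels=va.m,
                zero_variance_count=cmap.zero_variance_count,
            )
        )
    return out


def characterize_subject(
    series: ImageSeries,
    masks: MaskSet,
    opts: CharacterizeOptions | None = None,
) -> TemporospatialResult:
    """Compute both temporospatial indices for every slice and aggregate.

    Slices whose ROI subtraction is empty are skipped with a per-slice
    diagnostic; if every slice fails, the subject-level computation fails.
    """
    opts = opts or CharacterizeOptions()
    if masks.shape[0] != series.n_slices or masks.shape[1:] != series.grid_shape:
        raise InvalidInputError(
            f"mask stack {masks.shape} does not match series "
            f"({series.n_slices}, *, {series.grid_shape})"
        )
    per_slice: list[SliceResult] = []
    skipped: dict[int, str] = {}
    for s in range(series.n_slices):
        try:
            per_slice.extend(
                characterize_slice(series.slice_frames(s), masks, s, series.dt, opts)
            )
        except (EmptyROIError, EmptyVAMaskError) as exc:
            skipped[s] = str(exc)
    if not per_slice:
        raise EmptyROIError(f"every slice failed ROI construction: {skipped}")
    aggregated = {
        chamber: _aggregate([r for r in per_slice if r.chamber == chamber], opts.aggregation)
        for chamber in CHAMBERS
        if any(r.chamber == chamber for r in per_slice)
    }
    return TemporospatialResult(
        per_slice=per_slice,
        aggregated=aggregated,
        aggregation=opts.aggregation,
        skipped_slices=skipped,
        params={
            "cutoff_hz": opts.cutoff,
            "band_hz": list(opts.band),
            "mode": opts.mode,
            "numerator_halfwidth": opts.numerator_halfwidth,
            "voxel_series_filtered": True,
        },
    )
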