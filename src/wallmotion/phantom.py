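"""Synthetic real-time short-axis beating-heart series with ground truth.

The phantom places two circular chambers (labelled "lv" and "rv") on each
slice.  Each chamber's endocardial radius contracts from its ED value toward
its ES value following a raised-cosine pulse occupying the systolic fraction
of every beat; beat lengths come from a jittered RR schedule.  Whole-frame
amplitude is modulated by a slow sinusoid emulating free-breathing, the image
phase varies smoothly in space (so the spectrum is genuinely not
conjugate-symmetric), and independent complex Gaussian noise is added per
voxel per frame.  An angular wedge of the moving wall can be desynchronized:
those voxels follow the same waveform delayed by a phase lag.

Noise convention: ``noise_std`` is the standard deviation of EACH of the real
and imaginary noise components, so background magnitudes are Rayleigh with
scale ``noise_std``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .anatomy import MaskSet
from .datatypes import ImageSeries, VoxelGeometry
from .errors import InvalidParameterError

_TISSUE_PHASE = {"background": 0.0, "blood": 0.4, "myocardium": 1.2}


def _per_slice(value: float | Sequence[float], n_slices: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n_slices, arr[0])
    if arr.size != n_slices:
        raise InvalidParameterError(f"{name} must be scalar or length n_slices={n_slices}")
    return arr


@dataclass
class PhantomConfig:
    """Everything needed to deterministically synthesize one subject.

    Radii are in pixels and may be scalars (same for every slice) or
    per-slice sequences.  ``contraction_scale`` in (0, 1] scales the
    ED-to-ES excursion (1 = full excursion).
    """

    rows: int = 64
    cols: int = 64
    n_slices: int = 3
    pixel_spacing: float = 1.8
    slice_thickness: float = 8.0
    slice_gap: float = 2.0
    dt: float = 0.025
    n_frames: int = 288
    mean_hr: float = 72.0
    sigma_rr: float = 0.03
    systolic_fraction: float = 0.4
    lv_ed_radius: float | Sequence[float] = 12.0
    lv_es_radius: float | Sequence[float] = 7.0
    rv_ed_radius: float | Sequence[float] = 13.0
    rv_es_radius: float | Sequence[float] = 9.0
    wall_thickness: float = 3.0
    blood_intensity: float = 1.0
    myocardium_intensity: float = 0.4
    background_intensity: float = 0.05
    noise_std: float = 0.02
    a_resp: float = 0.05
    f_resp: float = 0.25
    resp_shift_pixels: int = 0
    #: Partial-volume width of the endocardial edge, in pixels.  0 gives a
    #: binary blood/myocardium boundary; a width comparable to the ED radius
    #: makes every voxel's time course affine in the common radius waveform.
    boundary_softness: float = 0.0
    desync_fraction: float = 0.0
    desync_lag: float = 0.0
    contraction_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- geometry helpers -------------------------------------------------
    def chamber_center(self, chamber: str) -> tuple[float, float]:
        """Row/col center of a chamber; LV left of midline, RV right."""
        if chamber == "lv":
            return (self.rows / 2.0, self.cols / 3.0)
        if chamber == "rv":
            return (self.rows / 2.0, 2.0 * self.cols / 3.0)
        raise InvalidParameterError(f"unknown chamber {chamber!r}")

    def ed_radii(self, chamber: str) -> np.ndarray:
        return _per_slice(
            getattr(self, f"{chamber}_ed_radius"), self.n_slices, f"{chamber}_ed_radius"
        )

    def es_radii(self, chamber: str) -> np.ndarray:
        return _per_slice(
            getattr(self, f"{chamber}_es_radius"), self.n_slices, f"{chamber}_es_radius"
        )

    def realized_es_radii(self, chamber: str) -> np.ndarray:
        """Smallest radius actually reached given the contraction scale."""
        ed = self.ed_radii(chamber)
        return ed - (ed - self.es_radii(chamber)) * self.contraction_scale

    @property
    def geometry(self) -> VoxelGeometry:
        return VoxelGeometry(self.pixel_spacing, self.slice_thickness, self.slice_gap)

    @property
    def duration(self) -> float:
        return self.n_frames * self.dt

    def validate(self) -> None:
        if self.rows < 8 or self.cols < 8 or self.n_slices < 1:
            raise InvalidParameterError("grid must be at least 8x8 with >= 1 slice")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.n_frames < 16:
            raise InvalidParameterError("n_frames must be >= 16")
        if not 30 < self.mean_hr < 220:
            raise InvalidParameterError("mean_hr must lie in (30, 220) bpm")
        if self.sigma_rr < 0:
            raise InvalidParameterError("sigma_rr must be >= 0")
        if not 0 <= self.systolic_fraction <= 1:
            raise InvalidParameterError("systolic_fraction must lie in [0, 1]")
        if not 0 < self.contraction_scale <= 1:
            raise InvalidParameterError("contraction_scale must lie in (0, 1]")
        if not 0 <= self.desync_fraction <= 1:
            raise InvalidParameterError("desync_fraction must lie in [0, 1]")
        if self.desync_lag < 0:
            raise InvalidParameterError("desync_lag must be >= 0")
        if self.noise_std < 0 or self.wall_thickness < 0:
            raise InvalidParameterError("noise_std and wall_thickness must be >= 0")
        if self.boundary_softness < 0:
            raise InvalidParameterError("boundary_softness must be >= 0")
        for chamber in ("lv", "rv"):
            ed = self.ed_radii(chamber)
            es = self.es_radii(chamber)
            if np.any(es >= ed):
                raise InvalidParameterError(f"{chamber}: ES radius must be < ED radius per slice")
            if np.any(es < 0):
                raise InvalidParameterError(f"{chamber}: radii must be non-negative")
            ci, cj = self.chamber_center(chamber)
            reach = float(np.max(ed)) + self.wall_thickness
            if (
                ci - reach < 0
                or ci + reach > self.rows - 1
                or cj - reach < 0
                or cj + reach > self.cols - 1
            ):
                raise InvalidParameterError(
                    f"{chamber}: ED radius + wall ({reach:.1f} px) overflows the grid"
                )


def healthy_config(**overrides) -> PhantomConfig:
    """Preset emulating a healthy subject: low RR jitter, full contraction, no desync."""
    params = dict(sigma_rr=0.03, contraction_scale=1.0, desync_fraction=0.0)
    params.update(overrides)
    return PhantomConfig(**params)


def hf_config(**overrides) -> PhantomConfig:
    """Preset emulating reduced, dyssynchronous ventricular performance."""
    params = dict(
        sigma_rr=0.12, contraction_scale=0.6, desync_fraction=0.3, desync_lag=0.25
    )
    params.update(overrides)
    return PhantomConfig(**params)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated series."""

    rr_intervals: np.ndarray
    cardiac_frequency: float
    radii: dict[str, np.ndarray]  # chamber -> (n_slices, n_frames) realized radius
    ed_frames: np.ndarray
    es_frames: np.ndarray
    desync_labels: np.ndarray  # bool (n_slices, rows, cols)
    noiseless: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serializable form (the noiseless stack is kept out of JSON)."""
        return {
            "rr_intervals_s": self.rr_intervals.tolist(),
            "cardiac_frequency_hz": self.cardiac_frequency,
            "radii_px": {k: v.tolist() for k, v in self.radii.items()},
            "ed_frames": self.ed_frames.tolist(),
            "es_frames": self.es_frames.tolist(),
            "n_desync_voxels": int(self.desync_labels.sum()),
            "meta": self.meta,
        }


def generate_rr_schedule(
    mean_hr: float,
    sigma_rr: float,
    duration: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw successive RR intervals until they strictly exceed ``duration``.

    Each interval is ``(60/mean_hr) * (1 + sigma_rr * eps)`` with ``eps``
    standard normal, floored at 0.3 of the mean interval so unbounded Gaussian
    draws cannot produce non-physical beats.
    """
    if not 30 < mean_hr < 220:
        raise InvalidParameterError("mean_hr must lie in (30, 220) bpm")
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    if sigma_rr < 0:
        raise InvalidParameterError("sigma_rr must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    base = 60.0 / mean_hr
    floor = 0.3 * base
    intervals: list[float] = []
    total = 0.0
    while total <= duration:
        eps = rng.standard_normal() if sigma_rr > 0 else 0.0
        iv = max(base * (1.0 + sigma_rr * eps), floor)
        intervals.append(iv)
        total += iv
    return np.asarray(intervals)


def _raised_cosine(phase: np.ndarray, systolic_fraction: float) -> np.ndarray:
    """Contraction pulse c(phase): 0 -> 1 -> 0 over the systolic fraction, else 0."""
    if systolic_fraction <= 0:
        return np.zeros_like(phase)
    inside = phase < systolic_fraction
    c = np.zeros_like(phase)
    c[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[inside] / systolic_fraction))
    return c


def _beat_phase(times: np.ndarray, starts: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Intra-beat phase in [0, 1) of each time point given beat start times."""
    idx = np.searchsorted(starts, times, side="right") - 1
    idx = np.clip(idx, 0, intervals.size - 1)
    return (times - starts[idx]) / intervals[idx]


def generate_series(config: PhantomConfig) -> tuple[ImageSeries, MaskSet, PhantomTruth]:
    """Synthesize one subject: complex series, ED/ES masks, and ground truth.

    Deterministic for a fixed config (seed included): the RR schedule is drawn
    first, then the per-voxel noise, from a single `numpy` Generator.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rr = generate_rr_schedule(cfg.mean_hr, cfg.sigma_rr, cfg.duration + cfg.desync_lag, rng=rng)

    base = 60.0 / cfg.mean_hr
    # prepend one virtual beat so lagged lookups at t - lag < 0 stay defined
    intervals = np.concatenate([[base], rr])
    starts = np.cumsum(np.concatenate([[0.0], intervals[:-1]]))
    starts -= base  # virtual beat begins at -base, first real beat at 0

    times = np.arange(cfg.n_frames) * cfg.dt
    phase = _beat_phase(times, starts, intervals)
    phase_lag = _beat_phase(times - cfg.desync_lag, starts, intervals)
    c_sync = _raised_cosine(phase, cfg.systolic_fraction)
    c_lag = _raised_cosine(phase_lag, cfg.systolic_fraction)

    resp = 1.0 + cfg.a_resp * np.sin(2.0 * np.pi * cfg.f_resp * times)

    rowgrid, colgrid = np.meshgrid(
        np.arange(cfg.rows, dtype=float), np.arange(cfg.cols, dtype=float), indexing="ij"
    )
    smooth_phase = 0.15 * np.sin(2.0 * np.pi * rowgrid / cfg.rows) * np.cos(
        2.0 * np.pi * colgrid / cfg.cols
    )

    noiseless = np.empty((cfg.n_slices, cfg.n_frames, cfg.rows, cfg.cols), dtype=np.complex128)
    lv_ed = np.zeros((cfg.n_slices, cfg.rows, cfg.cols), dtype=bool)
    lv_es = np.zeros_like(lv_ed)
    rv_ed = np.zeros_like(lv_ed)
    rv_es = np.zeros_like(lv_ed)
    desync_labels = np.zeros_like(lv_ed)
    radii_truth = {
        "lv": np.empty((cfg.n_slices, cfg.n_frames)),
        "rv": np.empty((cfg.n_slices, cfg.n_frames)),
    }
    ed_masks = {"lv": lv_ed, "rv": rv_ed}
    es_masks = {"lv": lv_es, "rv": rv_es}

    wedge_angle = 2.0 * np.pi * cfg.desync_fraction
    for s in range(cfg.n_slices):
        intensity = np.full(
            (cfg.n_frames, cfg.rows, cfg.cols), cfg.background_intensity, dtype=float
        )
        tissue_phase = np.full((cfg.n_frames, cfg.rows, cfg.cols), _TISSUE_PHASE["background"])
        for chamber in ("lv", "rv"):
            ci, cj = cfg.chamber_center(chamber)
            dist = np.hypot(rowgrid - ci, colgrid - cj)
            angle = np.mod(np.arctan2(rowgrid - ci, colgrid - cj), 2.0 * np.pi)
            wedge = angle < wedge_angle

            r_ed = cfg.ed_radii(chamber)[s]
            r_es = cfg.es_radii(chamber)[s]
            excursion = (r_ed - r_es) * cfg.contraction_scale
            r_sync = r_ed - excursion * c_sync
            r_lag = r_ed - excursion * c_lag
            radii_truth[chamber][s] = r_sync

            # per-voxel effective endocardial radius: lagged inside the wedge
            r_eff = np.where(wedge[None, :, :], r_lag[:, None, None], r_sync[:, None, None])
            outer = dist <= r_ed + cfg.wall_thickness
            if cfg.boundary_softness > 0:
                # partial-volume edge: blood fraction ramps linearly over the
                # softness width, so voxel signals track the radius waveform
                frac = np.clip(
                    0.5 + (r_eff - dist[None, :, :]) / (2.0 * cfg.boundary_softness), 0.0, 1.0
                )
            else:
                frac = (dist[None, :, :] <= r_eff).astype(float)
            inside = np.broadcast_to(outer[None, :, :], frac.shape)
            blend_int = cfg.myocardium_intensity + (
                cfg.blood_intensity - cfg.myocardium_intensity
            ) * frac
            blend_phase = _TISSUE_PHASE["myocardium"] + (
                _TISSUE_PHASE["blood"] - _TISSUE_PHASE["myocardium"]
            ) * frac
            intensity[inside] = blend_int[inside]
            tissue_phase[inside] = blend_phase[inside]

            ed_masks[chamber][s] = dist <= r_ed
            r_es_real = r_ed - excursion
            es_masks[chamber][s] = dist <= r_es_real
            # voxels whose waveform carries the lag: wedge voxels swept by the wall
            desync_labels[s] |= wedge & (dist > r_es_real) & (dist <= r_ed)

        noiseless[s] = (
            intensity
            * np.exp(1j * (tissue_phase + smooth_phase[None, :, :]))
            * resp[:, None, None]
        )

    data = noiseless.copy()
    if cfg.noise_std > 0:
        shape = data.shape
        data = data + cfg.noise_std * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        )

    # ED at phase 0 of each real beat, ES at the contraction peak (phase = s/2)
    real_starts = starts[1:]
    in_window = real_starts < cfg.duration - cfg.dt / 2
    beat_starts = real_starts[in_window]
    beat_lengths = intervals[1:][in_window]
    ed_frames = np.round(beat_starts / cfg.dt).astype(int)
    es_times = beat_starts + beat_lengths * cfg.systolic_fraction / 2.0
    es_frames = np.round(es_times / cfg.dt).astype(int)
    keep = es_frames < cfg.n_frames
    es_frames = es_frames[keep]
    ed_frames = ed_frames[np.clip(ed_frames, 0, None) < cfg.n_frames]

    series = ImageSeries(data=data, dt=cfg.dt, geometry=cfg.geometry, meta={"phantom_seed": cfg.seed})
    maskset = MaskSet(
        lv_ed=lv_ed,
        lv_es=lv_es,
        rv_ed=rv_ed,
        rv_es=rv_es,
        geometry=cfg.geometry,
        ed_frame=int(ed_frames[0]) if ed_frames.size else 0,
        es_frame=int(es_frames[0]) if es_frames.size else None,
    )
    truth = PhantomTruth(
        rr_intervals=rr,
        cardiac_frequency=float(1.0 / rr.mean()),
        radii=radii_truth,
        ed_frames=ed_frames,
        es_frames=es_frames,
        desync_labels=desync_labels,
        noiseless=noiseless,
        meta={"seed": cfg.seed, "mean_hr_bpm": cfg.mean_hr},
    )
    return series, maskset, truth
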