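"""Reference wall-motion signal: spatial averaging within an ROI plus high-pass filtering.

The filter is an ideal (brick-wall) spectral mask applied symmetrically to
positive and negative frequencies: every DFT bin with |frequency| strictly
below the cutoff — including the zero-frequency bin — is zeroed, and the
inverse transform is returned.  The realization is zero-phase, exactly linear
and idempotent, and leaves the energy of surviving bins untouched, which makes
it compose transparently with the downstream spectral periodicity index.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .anatomy import ROIMask
from .errors import EmptyROIError, InvalidInputError, InvalidParameterError

#: Default high-pass cutoff in Hz.  Adult free-breathing respiration sits
#: around 0.2–0.4 Hz while resting cardiac frequency is >= ~0.7 Hz, so 0.5 Hz
#: separates the respiratory band from the cardiac band.
DEFAULT_CUTOFF_HZ = 0.5


@dataclass
class ReferenceSignal:
    """Complex time-series obtained by spatially averaging an ROI.

    ``filtered`` and ``cutoff`` record whether (and at which cutoff, Hz) the
    high-pass filter has been applied.
    """

    values: np.ndarray
    dt: float
    chamber: str = ""
    slice_index: int = 0
    roi_voxels: int = 0
    filtered: bool = False
    cutoff: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 1:
            raise InvalidInputError("reference signal must be 1-D")
        if not np.isfinite(self.values).all():
            raise InvalidInputError("reference signal contains non-finite values")
        if self.dt <= 0:
            raise InvalidInputError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def to_csv(self, path: str | Path) -> None:
        """Export as CSV with columns frame, time_s, real, imag."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame", "time_s", "real", "imag"])
            for k, (t, v) in enumerate(zip(self.times, self.values)):
                writer.writerow([k, f"{t:.9g}", f"{v.real:.12g}", f"{v.imag:.12g}"])


def spatial_average(
    frames: np.ndarray,
    roi: ROIMask | np.ndarray,
    dt: float,
    *,
    chamber: str = "",
    slice_index: int = 0,
) -> ReferenceSignal:
    """Average the complex voxel values within the ROI, frame by frame.

    Parameters
    ----------
    frames : (n_frames, rows, cols) complex array for one slice.
    roi : ROIMask or boolean array sharing the in-plane grid.
    dt : frame spacing in seconds.
    """
    mask = roi.mask if isinstance(roi, ROIMask) else np.asarray(roi, dtype=bool)
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise InvalidInputError("frames must be 3-D (n_frames, rows, cols)")
    if frames.shape[1:] != mask.shape:
        raise InvalidInputError(
            f"grid mismatch: frames {frames.shape[1:]} vs roi {mask.shape}"
        )
    n = int(mask.sum())
    if n == 0:
        raise EmptyROIError("cannot average over an empty ROI")
    values = frames[:, mask].mean(axis=1)
    if isinstance(roi, ROIMask):
        chamber = chamber or roi.chamber
        slice_index = roi.slice_index
    return ReferenceSignal(
        values=values,
        dt=dt,
        chamber=chamber,
        slice_index=slice_index,
        roi_voxels=n,
        filtered=False,
        cutoff=None,
    )


def highpass_array(x: np.ndarray, dt: float, cutoff: float, *, axis: int = -1) -> np.ndarray:
    """Brick-wall high-pass along ``axis``: zero all bins with |f| < cutoff.

    With ``cutoff == 0`` no bin is removed (identity).  The zero-frequency bin
    is removed for any positive cutoff.
    """
    x = np.asarray(x, dtype=np.complex128)
    n = x.shape[axis]
    if cutoff < 0:
        raise InvalidParameterError("cutoff must be >= 0")
    if cutoff >= 0.5 / dt:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must lie below the Nyquist frequency {0.5 / dt} Hz"
        )
    spectrum = np.fft.fft(x, axis=axis)
    freqs = np.fft.fftfreq(n, d=dt)
    stop = np.abs(freqs) < cutoff
    shape = [1] * x.ndim
    shape[axis] = n
    spectrum = np.where(stop.reshape(shape), 0.0, spectrum)
    return np.fft.ifft(spectrum, axis=axis)


def highpass(signal: ReferenceSignal, cutoff: float = DEFAULT_CUTOFF_HZ) -> ReferenceSignal:
    """Return the high-pass-filtered copy of ``signal``.

    Raises
    ------
    InvalidParameterError
        If the cutoff is negative or at/above the Nyquist frequency.
    """
    filtered = highpass_array(signal.values, signal.dt, cutoff)
    return replace(signal, values=filtered, filtered=True, cutoff=cutoff)
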