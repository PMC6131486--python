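"""Signal-to-concentration conversion and temporal resampling for DSC-MRI.

Dynamic susceptibility contrast imaging records a T2*-weighted intensity
time series I(t) per voxel while a gadolinium bolus transits the brain.
The contrast concentration is recovered from the susceptibility-induced
signal drop through the log-ratio relation

    CTC(t) = (1/TE) * ln(I(t0) / I(t)),

where TE is the echo time and t0 a pre-bolus baseline frame.  All curves
(tissue and arterial) are put on a common fixed-length time grid so that
downstream deconvolution and feature extraction see one temporal shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "DscSeries",
    "CtcVolume",
    "Aif",
    "signal_to_ctc",
    "synthesize_signal",
    "resample_temporal",
    "aif_from_voxels",
    "moving_average",
]

#: default length of the common resampled time grid
DEFAULT_N_TIME = 40

#: relative floor applied to non-positive intensities before the log
INTENSITY_FLOOR_FRACTION = 1e-6


@dataclass
class DscSeries:
    """A 4-D DSC-MR signal-intensity series with acquisition metadata.

    Parameters
    ----------
    intensities : ndarray, shape (x, y, z, t)
        Raw scanner signal values (arbitrary units).
    te_seconds : float
        Echo time TE of the acquisition, in seconds; must be positive.
    dt_seconds : float
        Frame spacing of the dynamic series, in seconds; must be positive.
    baseline_index : int
        Index t0 of the pre-bolus reference frame (default 0).
    baseline_frames : int
        Number of leading frames averaged to form the baseline (default 1;
        1 reproduces the plain single-frame reference, >1 reduces baseline
        noise).
    brain_mask : ndarray of bool, shape (x, y, z), optional
        Voxels to process; everything outside is zeroed.
    """

    intensities: np.ndarray
    te_seconds: float
    dt_seconds: float
    baseline_index: int = 0
    baseline_frames: int = 1
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be a 4-D (x, y, z, t) array")
        if self.intensities.shape[3] < 2:
            raise ValueError("time dimension must have length >= 2")
        if self.te_seconds <= 0:
            raise ValueError("te_seconds must be strictly positive")
        if self.dt_seconds <= 0:
            raise ValueError("dt_seconds must be strictly positive")
        nt = self.intensities.shape[3]
        if not 0 <= self.baseline_index < nt:
            raise ValueError("baseline_index outside the time range")
        if self.baseline_frames < 1:
            raise ValueError("baseline_frames must be >= 1")
        if self.baseline_index + self.baseline_frames > nt:
            raise ValueError("baseline window exceeds the time range")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.intensities.shape[:3]:
                raise ValueError("brain_mask shape does not match the volume")

    @property
    def n_time(self) -> int:
        return self.intensities.shape[3]

    def baseline(self) -> np.ndarray:
        """Per-voxel baseline intensity I(t0) (mean of the baseline window)."""
        i0, k = self.baseline_index, self.baseline_frames
        return self.intensities[..., i0 : i0 + k].mean(axis=3)


@dataclass
class CtcVolume:
    """Per-voxel concentration-time curves on a common grid.

    ``curves`` has shape (x, y, z, n_time); ``dt_seconds`` is the grid
    spacing after any resampling.
    """

    curves: np.ndarray
    dt_seconds: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.ndim != 4:
            raise ValueError("curves must be 4-D (x, y, z, n_time)")
        if not np.all(np.isfinite(self.curves)):
            raise ValueError("concentration curves contain non-finite values")
        if self.dt_seconds <= 0:
            raise ValueError("dt_seconds must be strictly positive")

    @property
    def n_time(self) -> int:
        return self.curves.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.curves.shape[:3]


@dataclass
class Aif:
    """An arterial input function on the same grid as a :class:`CtcVolume`."""

    values: np.ndarray
    dt_seconds: float
    source: str = "supplied curve"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValueError("AIF must have at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("AIF contains non-finite values")
        if self.values.max() <= 0:
            # a non-positive AIF is representable (e.g. a degenerate average)
            # but unusable for deconvolution, which raises at point of use
            warnings.warn("AIF peak is not positive", stacklevel=2)
        if self.dt_seconds <= 0:
            raise ValueError("dt_seconds must be strictly positive")

    @property
    def n_time(self) -> int:
        return self.values.size


def signal_to_ctc(series: DscSeries) -> tuple[CtcVolume, np.ndarray]:
    """Convert a DSC signal series to concentration-time curves.

    Applies the log-ratio relation voxel-wise.  Non-positive intensities
    I(t) inside the mask are clamped to ``1e-6 * I(t0)`` before the log;
    voxels whose baseline I(t0) is non-positive cannot be converted and are
    excluded (zeroed and reported).

    Returns
    -------
    ctc : CtcVolume
        Concentration curves; out-of-mask and excluded voxels are zero.
    excluded : ndarray of bool, shape (x, y, z)
        In-mask voxels dropped because of a non-positive baseline.
    """
    vol = series.intensities
    mask = (
        series.brain_mask
        if series.brain_mask is not None
        else np.ones(vol.shape[:3], dtype=bool)
    )
    base = series.baseline()
    excluded = mask & (base <= 0)
    valid = mask & (base > 0)

    curves = np.zeros_like(vol)
    if np.any(valid):
        b = base[valid][:, None]
        inten = vol[valid]
        floor = INTENSITY_FLOOR_FRACTION * b
        inten = np.maximum(inten, floor)
        curves[valid] = np.log(b / inten) / series.te_seconds
    ctc = CtcVolume(curves=curves, dt_seconds=series.dt_seconds, mask=valid)
    return ctc, excluded


def synthesize_signal(
    ctc: np.ndarray, te_seconds: float, baseline_intensity: float = 100.0
) -> np.ndarray:
    """Invert the log-ratio relation: I(t) = I0 * exp(-TE * CTC(t)).

    The exact forward counterpart of :func:`signal_to_ctc`; used by the
    simulator to turn known concentration curves into scanner-like
    intensities.
    """
    if te_seconds <= 0:
        raise ValueError("te_seconds must be strictly positive")
    if baseline_intensity <= 0:
        raise ValueError("baseline_intensity must be strictly positive")
    return baseline_intensity * np.exp(-te_seconds * np.asarray(ctc, dtype=float))


def resample_temporal(curve: np.ndarray, src_dt: float, n_out: int) -> tuple[np.ndarray, float]:
    """Resample a 1-D curve to ``n_out`` points over the same time window.

    Cubic (not-a-knot) spline interpolation along time; endpoints are
    preserved exactly and polynomials of degree <= 3 are reproduced.  The
    returned spacing rescales so that ``(n-1)*dt`` — the physical window —
    is unchanged.

    Raises
    ------
    ValueError
        If the input has fewer than 4 samples (cubic support) or
        ``n_out < 2``.
    """
    y = np.asarray(curve, dtype=float).ravel()
    if y.size < 4:
        raise ValueError("cubic resampling needs at least 4 input samples")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    if src_dt <= 0:
        raise ValueError("src_dt must be strictly positive")
    window = (y.size - 1) * src_dt
    t_src = np.arange(y.size) * src_dt
    t_out = np.linspace(0.0, window, n_out)
    out = CubicSpline(t_src, y)(t_out)
    # endpoints are shared grid points; enforce bitwise preservation
    out[0], out[-1] = y[0], y[-1]
    return out, window / (n_out - 1)


def moving_average(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centred moving average with edge replication (odd window)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return np.asarray(values, dtype=float).copy()
    half = window // 2
    padded = np.pad(np.asarray(values, dtype=float), half, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def aif_from_voxels(
    ctc: CtcVolume,
    coordinates: list[tuple[int, int, int]],
    lowpass_window: int | None = None,
) -> Aif:
    """Average user-designated arterial voxels into an AIF.

    ``coordinates`` are 0-based (x, y, z) indices of voxels in major
    arteries (selected manually or by an external tool).  Optionally
    low-pass filters the mean curve with a centred moving average.
    """
    if len(coordinates) == 0:
        raise ValueError("at least one arterial voxel coordinate is required")
    shape = ctc.shape
    curves = []
    for coord in coordinates:
        x, y, z = coord
        if not (0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]):
            raise ValueError(f"coordinate {coord} outside volume of shape {shape}")
        curves.append(ctc.curves[x, y, z])
    mean_curve = np.mean(curves, axis=0)
    source = f"voxel coordinates (n={len(coordinates)})"
    if lowpass_window is not None:
        mean_curve = moving_average(mean_curve, lowpass_window)
        source += f", low-pass window {lowpass_window}"
    return Aif(values=mean_curve, dt_seconds=ctc.dt_seconds, source=source)
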