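"""Block-circulant SVD deconvolution and perfusion parameter maps.

The indicator-dilution model relates the tissue concentration curve to the
arterial input through a convolution with the residue function R(t):

    CTC(t) = CBF * (AIF ⊛ R)(t),

so recovering ``CBF * R`` is a deconvolution.  Discretised, the convolution
is a matrix product ``c = A r`` with A built from the AIF.  Using a
block-circulant A on a zero-padded grid makes the inversion insensitive to
bolus arrival delay between artery and tissue.  The inversion regularises
the ill-conditioned A by truncating small singular values, either at a
fixed fraction of the largest singular value (cSVD / tSVD) or per voxel by
raising the threshold until the recovered curve's oscillation index drops
below a limit (oSVD).

From the recovered residue and the curves themselves the five standard
perfusion parameters follow:

    rCBF = max_t CBF*R(t)            (relative units, kappa = 1)
    rCBV = ∫CTC dt / ∫AIF dt
    MTT  = rCBV / rCBF               (central volume theorem)
    TTP  = argmax_t CTC(t)           (seconds)
    Tmax = argmax_t CBF*R(t)         (seconds)

This module is the repository's reference ("ground truth") generator: the
maps it produces are the regression targets for the learned models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .signal import Aif, CtcVolume

__all__ = [
    "DeconvConfig",
    "ResidueCurve",
    "PerfusionMaps",
    "build_circulant",
    "oscillation_index",
    "deconvolve_voxel",
    "deconvolve_volume",
    "compute_cbv",
    "compute_scalar_params",
    "maps_from_case",
]

#: CBF below this floor marks a voxel as unreliable; its MTT is masked
CBF_FLOOR = 1e-9

#: sentinel written into masked MTT voxels
MTT_SENTINEL = np.nan


@dataclass(frozen=True)
class DeconvConfig:
    """Regularisation settings for the SVD deconvolution.

    method : ``"tsvd"`` (fixed threshold, the cSVD baseline) or ``"osvd"``
        (per-voxel adaptive threshold via the oscillation index).
    truncation_fraction : fraction of the largest singular value below
        which singular values are zeroed in tsvd mode (default 0.10).
    oscillation_threshold : oscillation-index limit for osvd (default
        0.095).
    pad_factor : zero-padding multiple of the time grid (default 2).
    """

    method: Literal["tsvd", "osvd"] = "osvd"
    truncation_fraction: float = 0.10
    oscillation_threshold: float = 0.095
    pad_factor: int = 2

    def __post_init__(self) -> None:
        if self.method not in ("tsvd", "osvd"):
            raise ValueError(f"unknown deconvolution method {self.method!r}")
        if not 0.0 < self.truncation_fraction < 1.0:
            raise ValueError("truncation_fraction must lie in (0, 1)")
        if not 0.0 < self.oscillation_threshold < 1.0:
            raise ValueError("oscillation_threshold must lie in (0, 1)")
        if self.pad_factor < 2:
            raise ValueError("pad_factor must be >= 2")


@dataclass
class ResidueCurve:
    """The recovered ``CBF * R(t)`` on the padded time grid."""

    values: np.ndarray
    dt_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("residue curve contains non-finite values")


@dataclass
class PerfusionMaps:
    """The five perfusion parameter volumes plus provenance.

    cbf/cbv are in relative (arbitrary) units with kappa fixed at 1;
    mtt/ttp/tmax are in seconds.  ``flags`` marks voxels whose MTT was
    masked because CBF fell below the floor.
    """

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    ttp: np.ndarray
    tmax: np.ndarray
    provenance: dict = field(default_factory=dict)
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.cbf, self.cbv, self.mtt, self.ttp, self.tmax)}
        if len(shapes) != 1:
            raise ValueError("all five maps must share one shape")

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in ("cbf", "cbv", "mtt", "ttp", "tmax"):
            raise KeyError(name)
        return getattr(self, name)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cbf.shape


def build_circulant(aif: Aif, n_pad: int) -> np.ndarray:
    """Build the n_pad x n_pad block-circulant convolution matrix.

    The AIF is zero-padded to ``n_pad`` and each column is a cyclic shift
    of the first, scaled by the frame spacing, so that ``A @ r`` is the
    discrete circular convolution of AIF and r times dt.
    """
    a = np.asarray(aif.values, dtype=float)
    if n_pad < a.size:
        raise ValueError(f"n_pad ({n_pad}) must be >= AIF length ({a.size})")
    col = np.zeros(n_pad)
    col[: a.size] = a
    idx = (np.arange(n_pad)[:, None] - np.arange(n_pad)[None, :]) % n_pad
    return col[idx] * aif.dt_seconds


def oscillation_index(residue: np.ndarray) -> float:
    """Normalised sum of second differences of a residue curve.

    OI = (1/L) * (1/max|R|) * sum_k |R[k] - 2 R[k-1] + R[k-2]|.  Zero for
    an all-zero curve.
    """
    r = np.asarray(residue, dtype=float).ravel()
    peak = np.abs(r).max()
    if peak == 0:
        return 0.0
    return float(np.abs(np.diff(r, 2)).sum() / (r.size * peak))


class _CirculantSolver:
    """Pre-factorised circulant system shared by all voxels of a case.

    The SVD of A depends only on the AIF, so it is computed once and the
    per-voxel work reduces to two small matrix products per candidate
    threshold.
    """

    # candidate thresholds swept by the adaptive (osvd) mode, lowest first;
    # noiseless curves typically satisfy the OI limit at zero truncation
    OSVD_FRACTIONS = np.concatenate([[0.0], np.geomspace(1e-4, 0.95, 60)])

    def __init__(self, aif: Aif, n_time: int, cfg: DeconvConfig):
        if np.all(aif.values == 0):
            raise ValueError("cannot deconvolve with an all-zero AIF")
        if aif.values.max() <= 0:
            raise ValueError("AIF peak must be positive for deconvolution")
        if aif.n_time != n_time:
            raise ValueError("AIF and CTC must be on the same time grid")
        self.cfg = cfg
        self.n_time = n_time
        self.n_pad = cfg.pad_factor * n_time
        A = build_circulant(aif, self.n_pad)
        self.U, self.s, self.Vt = np.linalg.svd(A)

    def _filtered(self, utc: np.ndarray, fraction: float) -> np.ndarray:
        sinv = np.where(self.s >= fraction * self.s[0], 1.0 / self.s, 0.0)
        return self.Vt.T @ (sinv[:, None] * utc)

    def solve(self, curves: np.ndarray) -> np.ndarray:
        """Deconvolve a (n_voxels, n_time) batch; returns (n_voxels, n_pad)."""
        c = np.zeros((curves.shape[0], self.n_pad))
        c[:, : self.n_time] = curves
        utc = self.U.T @ c.T  # (n_pad, n_voxels)
        if self.cfg.method == "tsvd":
            return self._filtered(utc, self.cfg.truncation_fraction).T

        # osvd: per voxel, raise the threshold until the oscillation index
        # of the recovered curve falls below the configured limit
        n_vox = curves.shape[0]
        out = np.empty((n_vox, self.n_pad))
        done = np.zeros(n_vox, dtype=bool)
        for frac in self.OSVD_FRACTIONS:
            todo = ~done
            if not np.any(todo):
                break
            r = self._filtered(utc[:, todo], frac).T
            peaks = np.abs(r).max(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                oi = np.abs(np.diff(r, 2, axis=1)).sum(axis=1) / (self.n_pad * peaks)
            oi = np.where(peaks == 0, 0.0, oi)
            ok = oi <= self.cfg.oscillation_threshold
            idx = np.flatnonzero(todo)
            out[idx[ok]] = r[ok]
            done[idx[ok]] = True
            last_r, last_idx = r, idx  # keep the most-truncated solution
        if not np.all(done):
            # no threshold satisfied the limit; keep the smoothest curve
            rem = np.flatnonzero(~done)
            pos = {v: i for i, v in enumerate(last_idx)}
            out[rem] = last_r[[pos[v] for v in rem]]
        return out


def deconvolve_voxel(
    ctc: np.ndarray, aif: Aif, cfg: DeconvConfig | None = None
) -> ResidueCurve:
    """Recover ``CBF * R`` for a single tissue curve.

    An all-zero CTC yields an all-zero residue; an all-zero AIF raises.
    """
    cfg = cfg or DeconvConfig()
    c = np.asarray(ctc, dtype=float).ravel()
    solver = _CirculantSolver(aif, c.size, cfg)
    if np.all(c == 0):
        return ResidueCurve(np.zeros(solver.n_pad), aif.dt_seconds)
    return ResidueCurve(solver.solve(c[None, :])[0], aif.dt_seconds)


def deconvolve_volume(
    ctc: CtcVolume, aif: Aif, cfg: DeconvConfig | None = None
) -> np.ndarray:
    """Deconvolve every in-mask voxel of a volume; returns (x, y, z, n_pad)."""
    cfg = cfg or DeconvConfig()
    solver = _CirculantSolver(aif, ctc.n_time, cfg)
    mask = ctc.mask if ctc.mask is not None else np.ones(ctc.shape, dtype=bool)
    out = np.zeros(ctc.shape + (solver.n_pad,))
    if np.any(mask):
        out[mask] = solver.solve(ctc.curves[mask])
    return out


def compute_cbv(ctc: np.ndarray, aif: Aif) -> float:
    """Relative cerebral blood volume: ∫CTC dt / ∫AIF dt (trapezoid, kappa=1)."""
    denom = np.trapezoid(aif.values, dx=aif.dt_seconds)
    if denom <= 0:
        raise ValueError("AIF time-integral must be positive")
    return float(np.trapezoid(np.asarray(ctc, dtype=float), dx=aif.dt_seconds) / denom)


def compute_scalar_params(
    residue: ResidueCurve, ctc: np.ndarray, aif: Aif
) -> tuple[float, float, float, float, float]:
    """Read (cbf, cbv, mtt, ttp, tmax) off one voxel's curves.

    cbf is the residue peak; tmax its time, both restricted to the first
    n_time samples of the padded grid to avoid wrap-around lobes; ttp is
    the time of the CTC peak; mtt = cbv/cbf, masked (NaN) when cbf is at
    or below the floor.
    """
    c = np.asarray(ctc, dtype=float).ravel()
    n_time = c.size
    r = residue.values[:n_time]
    cbf = float(r.max())
    cbv = compute_cbv(c, aif)
    dt = residue.dt_seconds
    tmax = float(np.argmax(r) * dt)
    ttp = float(np.argmax(c) * dt)
    mtt = cbv / cbf if cbf > CBF_FLOOR else MTT_SENTINEL
    return cbf, cbv, mtt, ttp, tmax


def maps_from_case(
    ctc: CtcVolume, aif: Aif, cfg: DeconvConfig | None = None
) -> PerfusionMaps:
    """Compute all five perfusion maps for one case.

    Applies the shared-SVD deconvolution to every in-mask voxel, then the
    scalar parameter readout, fully vectorised.  Per-voxel failures (CBF
    at the floor) are flagged, never fatal.
    """
    cfg = cfg or DeconvConfig()
    mask = ctc.mask if ctc.mask is not None else np.ones(ctc.shape, dtype=bool)
    shape = ctc.shape
    cbf = np.zeros(shape)
    cbv = np.zeros(shape)
    mtt = np.zeros(shape)
    ttp = np.zeros(shape)
    tmax = np.zeros(shape)
    flags = np.zeros(shape, dtype=bool)

    if not np.any(mask):
        warnings.warn("empty mask: returning all-zero perfusion maps", stacklevel=2)
    else:
        solver = _CirculantSolver(aif, ctc.n_time, cfg)
        curves = ctc.curves[mask]  # (n_vox, n_time)
        residues = solver.solve(curves)[:, : ctc.n_time]
        dt = aif.dt_seconds
        aif_integral = np.trapezoid(aif.values, dx=dt)
        if aif_integral <= 0:
            raise ValueError("AIF time-integral must be positive")
        cbf_v = residues.max(axis=1)
        cbv_v = np.trapezoid(curves, dx=dt, axis=1) / aif_integral
        tmax_v = residues.argmax(axis=1) * dt
        ttp_v = curves.argmax(axis=1) * dt
        bad = cbf_v <= CBF_FLOOR
        with np.errstate(divide="ignore", invalid="ignore"):
            mtt_v = np.where(bad, MTT_SENTINEL, cbv_v / np.where(bad, 1.0, cbf_v))
        cbf[mask] = cbf_v
        cbv[mask] = cbv_v
        mtt[mask] = mtt_v
        ttp[mask] = ttp_v
        tmax[mask] = tmax_v
        fl = np.zeros(shape, dtype=bool)
        fl[mask] = bad
        flags = fl

    provenance = {
        "method": cfg.method,
        "truncation_fraction": cfg.truncation_fraction,
        "oscillation_threshold": cfg.oscillation_threshold,
        "pad_factor": cfg.pad_factor,
        "aif_source": aif.source,
        "n_flagged": int(flags.sum()),
    }
    return PerfusionMaps(
        cbf=cbf, cbv=cbv, mtt=mtt, ttp=ttp, tmax=tmax, provenance=provenance, flags=flags
    )
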