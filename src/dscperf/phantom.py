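"""Synthetic DSC cases and the CBF noise phantom.

Two generators live here.

``simulate_case`` builds a fully synthetic DSC acquisition with known
per-voxel perfusion parameters.  A gamma-variate bolus serves as the
arterial input,

    AIF(t) = amp * (t - t0)^alpha * exp(-(t - t0) / beta)   for t > t0,

and each voxel carries a delayed mono-exponential residue function
R(t) = exp(-(t - delay)/MTT) for t >= delay.  The tissue curve is the
convolution CTC = CBF * (AIF ⊛ R), computed either directly on the
acquisition grid (``quadrature='grid'``: the discrete forward model that
the block-circulant deconvolver inverts exactly) or on a finely
oversampled grid then sampled at the frame times
(``quadrature='oversampled'``: emulates a scanner sampling a continuous
system, at the cost of quadrature mismatch with any discrete inverse).
Concentration converts to signal intensity through the exact inverse of
the log-ratio relation, optionally with additive white Gaussian noise.

Parameter fields are spatially smooth random fields (Gaussian-filtered
noise rank-mapped onto the configured ranges), so that neighbouring
voxels are correlated the way tissue regions are and spatial patches
carry real information.

``build_phantom`` condenses a case into the 12-level CBF phantom used for
noise-robustness benchmarking: CBF values between their 5th and 95th
percentile are split into 12 equal-width bins and each level's curve is
the per-timepoint 10%-trimmed mean of the member voxels' CTCs.
``noise_robustness_experiment`` then perturbs the level curves with AWGN
over an SNR grid and scores every model against its own noiseless
predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import trim_mean

from .deconv import DeconvConfig, PerfusionMaps, _CirculantSolver
from .evaluation import nrmse
from .regressors import FittedModel, predict
from .signal import Aif, CtcVolume, DscSeries, moving_average, synthesize_signal

__all__ = [
    "SimulationConfig",
    "PhantomCase",
    "gamma_variate",
    "simulate_case",
    "build_phantom",
    "add_awgn",
    "CsvdBaseline",
    "noise_robustness_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Forward-simulation settings; defaults are the package's reference
    study conditions.

    The bolus (amp 1, arrival 10 s, shape 3, scale 1.5 s) and grid (40
    frames, 1.5 s apart) match a standard clinical DSC protocol; CBF spans
    a 10x log-uniform range and MTT 4-12 s, the physiological span from
    healthy tissue to severely delayed perfusion; bolus delays up to 6 s
    cover normal-to-penumbral arrival times.
    """

    shape: tuple[int, int, int] = (24, 24, 4)
    n_time: int = 40
    dt_seconds: float = 1.5
    te_seconds: float = 0.030
    baseline_intensity: float = 100.0
    aif_amplitude: float = 1.0
    aif_t0: float = 10.0
    aif_alpha: float = 3.0
    aif_beta: float = 1.5
    cbf_range: tuple[float, float] = (0.2, 2.0)
    mtt_range: tuple[float, float] = (4.0, 12.0)
    delay_range: tuple[float, float] = (0.0, 6.0)
    noise_snr_db: float | None = None
    smoothness: float = 2.0
    delay_on_grid: bool = True
    quadrature: str = "grid"
    oversample: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aif_alpha <= 0 or self.aif_beta <= 0:
            raise ValueError("gamma-variate alpha and beta must be positive")
        if self.n_time < 4:
            raise ValueError("n_time must be >= 4")
        for name in ("cbf_range", "mtt_range", "delay_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty")
        if self.quadrature not in ("grid", "oversampled"):
            raise ValueError("quadrature must be 'grid' or 'oversampled'")


@dataclass
class PhantomCase:
    """Idealised per-level CTC curves with known reference CBF values."""

    level_curves: np.ndarray  # (n_levels, n_time)
    level_values: np.ndarray  # (n_levels,) strictly increasing
    aif: Aif
    case_id: str = "phantom"

    def __post_init__(self) -> None:
        self.level_curves = np.atleast_2d(np.asarray(self.level_curves, dtype=float))
        self.level_values = np.asarray(self.level_values, dtype=float).ravel()
        if self.level_curves.shape[0] != self.level_values.size:
            raise ValueError("level curves and values are misaligned")
        if self.level_values.size > 1 and not np.all(np.diff(self.level_values) > 0):
            raise ValueError("level_values must be strictly increasing")


def gamma_variate(
    t: np.ndarray, amplitude: float = 1.0, t0: float = 10.0, alpha: float = 3.0, beta: float = 1.5
) -> np.ndarray:
    """Gamma-variate bolus model, zero before arrival time t0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    m = t > t0
    tt = t[m] - t0
    out[m] = amplitude * tt**alpha * np.exp(-tt / beta)
    return out


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Spatially smooth field with values rank-mapped to uniform (0, 1)."""
    raw = rng.standard_normal(shape)
    if sigma > 0:
        raw = ndimage.gaussian_filter(raw, sigma=(sigma, sigma, 0))
    flat = raw.ravel()
    ranks = np.empty_like(flat)
    ranks[np.argsort(flat, kind="stable")] = np.arange(flat.size)
    return ((ranks + 0.5) / flat.size).reshape(shape)


def _forward_ctc_grid(
    aif_samples: np.ndarray, residues: np.ndarray, dt: float
) -> np.ndarray:
    """CTC = dt * (AIF ⊛ R) on the acquisition grid, per voxel (rows)."""
    n = aif_samples.size
    nfft = 2 * n
    fa = np.fft.rfft(aif_samples, nfft)
    fr = np.fft.rfft(residues, nfft, axis=1)
    conv = np.fft.irfft(fa[None, :] * fr, nfft, axis=1)[:, :n]
    return conv * dt


def simulate_case(
    cfg: SimulationConfig,
) -> tuple[DscSeries, Aif, PerfusionMaps, CtcVolume]:
    """Simulate one DSC case with known ground truth.

    Returns the intensity series (with noise if configured), the sampled
    AIF, the analytic ground-truth maps, and the *noiseless* CTC volume
    (handy for phantom construction and oracle checks).

    Ground truth per voxel: cbf and mtt as drawn; cbv = cbf * mtt; ttp as
    the argmax time of the noiseless CTC; tmax as the bolus-arrival delay
    rounded up to the acquisition grid (where the discrete residue peaks).
    """
    rng = np.random.default_rng(cfg.seed)
    nx, ny, nz = cfg.shape
    n_vox = nx * ny * nz
    dt = cfg.dt_seconds
    t = np.arange(cfg.n_time) * dt

    lo, hi = cfg.cbf_range
    if lo == hi:
        cbf = np.full(cfg.shape, float(lo))
        _smooth_field(rng, cfg.shape, cfg.smoothness)  # keep the rng stream aligned
    elif lo <= 0:
        raise ValueError("cbf_range lower bound must be positive for log-uniform draws")
    else:
        cbf = np.exp(
            np.log(lo)
            + _smooth_field(rng, cfg.shape, cfg.smoothness) * (np.log(hi) - np.log(lo))
        )
    mtt = cfg.mtt_range[0] + _smooth_field(rng, cfg.shape, cfg.smoothness) * (
        cfg.mtt_range[1] - cfg.mtt_range[0]
    )
    delay = cfg.delay_range[0] + _smooth_field(rng, cfg.shape, cfg.smoothness) * (
        cfg.delay_range[1] - cfg.delay_range[0]
    )
    if cfg.delay_on_grid:
        # quantise bolus arrival to the frame grid: sub-frame arrival
        # offsets attenuate the sampled residue peak below CBF and are
        # deliberately not modelled (see methods note)
        delay = np.round(delay / dt) * dt

    aif_samples = gamma_variate(t, cfg.aif_amplitude, cfg.aif_t0, cfg.aif_alpha, cfg.aif_beta)
    aif = Aif(values=aif_samples, dt_seconds=dt, source="simulated gamma-variate")

    cbf_f = cbf.ravel()
    mtt_f = mtt.ravel()
    delay_f = delay.ravel()
    if np.any(mtt_f <= dt):
        warnings.warn("some MTT values are below the frame spacing (under-resolved)")

    if cfg.quadrature == "grid":
        resid = np.where(
            t[None, :] >= delay_f[:, None],
            np.exp(-(t[None, :] - delay_f[:, None]) / mtt_f[:, None]),
            0.0,
        )
        ctc_flat = cbf_f[:, None] * _forward_ctc_grid(aif_samples, resid, dt)
    else:
        q = cfg.oversample
        dtf = dt / q
        n_f = cfg.n_time * q
        tf = np.arange(2 * n_f) * dtf
        aif_f = gamma_variate(tf, cfg.aif_amplitude, cfg.aif_t0, cfg.aif_alpha, cfg.aif_beta)
        resid_f = np.where(
            tf[None, :] >= delay_f[:, None],
            np.exp(-(tf[None, :] - delay_f[:, None]) / mtt_f[:, None]),
            0.0,
        )
        nfft = 4 * n_f
        conv = np.fft.irfft(
            np.fft.rfft(aif_f, nfft)[None, :] * np.fft.rfft(resid_f, nfft, axis=1),
            nfft,
            axis=1,
        )[:, : 2 * n_f] * dtf
        ctc_flat = cbf_f[:, None] * conv[:, :: q][:, : cfg.n_time]

    ctc = CtcVolume(curves=ctc_flat.reshape(cfg.shape + (cfg.n_time,)), dt_seconds=dt)

    intens = synthesize_signal(ctc.curves, cfg.te_seconds, cfg.baseline_intensity)
    if cfg.noise_snr_db is not None:
        power = np.mean(intens**2)
        sigma = np.sqrt(power / 10 ** (cfg.noise_snr_db / 10.0))
        intens = intens + rng.normal(0.0, sigma, size=intens.shape)

    series = DscSeries(
        intensities=intens,
        te_seconds=cfg.te_seconds,
        dt_seconds=dt,
        baseline_index=0,
    )

    ttp = (np.argmax(ctc_flat, axis=1) * dt).reshape(cfg.shape)
    tmax = (np.ceil(delay_f / dt - 1e-12) * dt).reshape(cfg.shape)
    truth = PerfusionMaps(
        cbf=cbf,
        cbv=cbf * mtt,
        mtt=mtt,
        ttp=ttp,
        tmax=tmax,
        provenance={
            "method": "simulation",
            "quadrature": cfg.quadrature,
            "seed": cfg.seed,
            "noise_snr_db": cfg.noise_snr_db,
        },
    )
    return series, aif, truth, ctc


def build_phantom(
    ctc: CtcVolume,
    cbf_map: np.ndarray,
    aif: Aif,
    n_bins: int = 12,
    pct_low: float = 5.0,
    pct_high: float = 95.0,
    trim_frac: float = 0.10,
    lowpass_window: int = 3,
    case_id: str = "phantom",
    mask: np.ndarray | None = None,
) -> PhantomCase:
    """Condense a case into idealised per-level CTC curves.

    CBF values between the ``pct_low`` and ``pct_high`` percentiles are
    split into ``n_bins`` equal-width bins; each level curve is the
    per-timepoint trimmed mean (``trim_frac`` per tail) of the curves whose
    CBF falls in the bin.  Empty bins are dropped with a warning.  The AIF
    is low-pass filtered with a centred moving average.
    """
    mask = np.ones(ctc.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    vals = np.asarray(cbf_map, dtype=float)[mask]
    curves = ctc.curves[mask]
    if vals.size < n_bins * 10:
        raise ValueError(f"need at least {n_bins * 10} in-mask voxels, got {vals.size}")
    lo, hi = np.percentile(vals, [pct_low, pct_high])
    edges = np.linspace(lo, hi, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    level_curves, level_values = [], []
    for b in range(n_bins):
        sel = (vals >= edges[b]) & (
            vals <= edges[b + 1] if b == n_bins - 1 else vals < edges[b + 1]
        )
        if not np.any(sel):
            warnings.warn(f"phantom bin {b} is empty and was dropped", stacklevel=2)
            continue
        level_curves.append(trim_mean(curves[sel], proportiontocut=trim_frac, axis=0))
        level_values.append(centres[b])
    filtered = moving_average(aif.values, lowpass_window)
    aif_lp = Aif(values=filtered, dt_seconds=aif.dt_seconds, source=aif.source + ", low-pass")
    return PhantomCase(
        level_curves=np.array(level_curves),
        level_values=np.array(level_values),
        aif=aif_lp,
        case_id=case_id,
    )


def add_awgn(
    curve: np.ndarray, snr_db: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Additive white Gaussian noise at the given power SNR (dB).

    Noise variance is ``mean(curve^2) / 10^(snr_db/10)``; deterministic
    per seed.  Raises on a zero-power curve.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = np.asarray(curve, dtype=float)
    power = float(np.mean(c**2))
    if power <= 0:
        raise ValueError("cannot set an SNR for a zero-power curve")
    sigma = np.sqrt(power / 10 ** (snr_db / 10.0))
    return c + rng.normal(0.0, sigma, size=c.shape)


class CsvdBaseline:
    """Block-circulant fixed-threshold SVD as a curve -> CBF predictor.

    Wraps the deconvolver behind the same predict surface as the learned
    models so the noise experiment can score it alongside them.  Expects
    feature rows of ``[CTC, AIF]`` (a 1x1 patch).
    """

    family = "csvd"

    def __init__(self, truncation_fraction: float = 0.10):
        self.cfg = DeconvConfig(method="tsvd", truncation_fraction=truncation_fraction)
        self._solvers: dict = {}

    def predict_curves(self, curves: np.ndarray, aif: Aif) -> np.ndarray:
        key = (aif.values.tobytes(), aif.dt_seconds, curves.shape[1])
        solver = self._solvers.get(key)
        if solver is None:
            solver = _CirculantSolver(aif, curves.shape[1], self.cfg)
            self._solvers[key] = solver
        residues = solver.solve(np.atleast_2d(curves))
        return residues[:, : curves.shape[1]].max(axis=1)


def _phantom_features(case: PhantomCase, curves: np.ndarray, e: int) -> np.ndarray:
    """Feature rows for phantom curves: the level curve tiled over the
    patch positions, AIF appended — a spatially uniform 'tissue block'."""
    reps = (2 * e + 1) ** 2
    tiled = np.tile(curves, (1, reps))
    return np.hstack([tiled, np.tile(case.aif.values, (curves.shape[0], 1))])


def _model_half_width(model: FittedModel, n_time: int) -> int:
    blocks = model.n_features / n_time - 1
    e = (int(round(np.sqrt(blocks))) - 1) // 2
    if ((2 * e + 1) ** 2 + 1) * n_time != model.n_features:
        raise ValueError("model feature width is not a patch+AIF layout")
    return e


def noise_robustness_experiment(
    models: dict[str, FittedModel | CsvdBaseline],
    phantoms: list[PhantomCase],
    snr_grid_db: list[float],
    n_reps: int = 20,
    seed: int = 0,
    allow_tiling: bool = True,
) -> pd.DataFrame:
    """Score each model's CBF stability under increasing phantom noise.

    For every model x SNR x repetition, each phantom's level curves are
    perturbed with AWGN and predictions compared — via NRMSE, averaged
    over phantoms — against the same model's predictions on the noiseless
    curves (so the metric isolates noise sensitivity from bias).  Returns
    a tidy table with columns (model, snr_db, rep, nrmse).
    """
    if not phantoms:
        raise ValueError("at least one phantom case is required")
    if not snr_grid_db:
        raise ValueError("snr_grid_db must be non-empty")
    n_time = phantoms[0].level_curves.shape[1]

    refs: dict[str, list[np.ndarray]] = {}
    usable: dict[str, FittedModel | CsvdBaseline] = {}
    for name, model in models.items():
        try:
            if isinstance(model, CsvdBaseline):
                refs[name] = [
                    model.predict_curves(ph.level_curves, ph.aif) for ph in phantoms
                ]
            else:
                e = _model_half_width(model, n_time)
                if e > 0 and not allow_tiling:
                    warnings.warn(
                        f"model {name!r} needs {2*e+1}x{2*e+1} patches; skipped",
                        stacklevel=2,
                    )
                    continue
                refs[name] = [
                    predict(model, _phantom_features(ph, ph.level_curves, e))
                    for ph in phantoms
                ]
            usable[name] = model
        except ValueError as err:
            warnings.warn(f"model {name!r} skipped: {err}", stacklevel=2)

    rows = []
    rng = np.random.default_rng(seed)
    for snr in snr_grid_db:
        for rep in range(n_reps):
            noisy = [
                np.vstack([add_awgn(c, snr, rng) for c in ph.level_curves])
                for ph in phantoms
            ]
            for name, model in usable.items():
                errs = []
                for ph, noisy_curves, ref in zip(phantoms, noisy, refs[name]):
                    if isinstance(model, CsvdBaseline):
                        pred = model.predict_curves(noisy_curves, ph.aif)
                    else:
                        e = _model_half_width(model, n_time)
                        pred = predict(model, _phantom_features(ph, noisy_curves, e))
                    errs.append(nrmse(ref, pred))
                rows.append(
                    {"model": name, "snr_db": snr, "rep": rep, "nrmse": float(np.mean(errs))}
                )
    return pd.DataFrame(rows)
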