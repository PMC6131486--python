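# Methods

## The model

Dynamic susceptibility contrast (DSC) MR perfusion images a gadolinium
bolus transiting the brain through a T2*-weighted time series I(t).  The
per-voxel contrast concentration follows from the susceptibility-induced
signal drop,

    CTC(t) = (1/TE) · ln( I(t0) / I(t) ),

with TE the echo time and t0 a pre-bolus baseline frame.  The
indicator-dilution model relates tissue concentration to the arterial
input function (AIF) through the residue function R(t), the fraction of
tracer still inside the voxel t seconds after an idealised instantaneous
arterial input:

    CTC(t) = CBF · (AIF ⊛ R)(t),      R(0) = 1, R non-increasing.

Recovering CBF·R is a deconvolution.  Discretised on the acquisition grid
the convolution is a matrix product c = A r with A built from the AIF; we
use the block-circulant form (AIF zero-padded to twice the grid, each
column a cyclic shift, scaled by Δt), which makes the inversion
insensitive to the bolus-arrival delay between artery and tissue.  The
ill-conditioned inversion is regularised by truncating singular values:

* **cSVD / tSVD** — zero all singular values below a fixed fraction λ of
  the largest (default λ = 0.10, the standard literature value for the
  fixed-threshold baseline);
* **oSVD** — per voxel, raise the threshold through a geometric ladder
  (0, 1e-4 … 0.95) until the oscillation index of the recovered curve,

      OI = (1/L) · (1/max|R|) · Σ |R[k] − 2R[k−1] + R[k−2]|,

  falls below a limit (default 0.095).  On noiseless curves the ladder
  exits at zero truncation and the inversion is exact.

From the residue and the curves the five parameters are read off as
rCBF = max CBF·R (relative units, the hematocrit/density constant κ fixed
at 1), rCBV = ∫CTC/∫AIF (trapezoid), MTT = rCBV/rCBF (central volume
theorem, exact by construction), TTP = Δt·argmax CTC, and
Tmax = Δt·argmax CBF·R, with the argmax restricted to the un-padded half
of the grid to avoid wrap-around lobes.  Voxels whose CBF falls below
1e-9 get a masked (NaN) MTT and a QC flag.

## Learned map reconstruction

The regression task maps a voxel's local curve data directly to one map
value, bypassing deconvolution at inference time.  A feature vector
concatenates, row-major over an in-plane (2e+1)×(2e+1) window, the CTC of
every window voxel followed by the AIF: ((2e+1)² + 1)·n_time entries
(n_time = 40).  Targets are taken from the package's own oSVD maps, so
the models learn to reproduce the reference algorithm, not the simulation
ground truth.  Training voxels are sampled *uniformly over the target
range* (12 equal-width bins per case, equal per-case quotas, shortfall in
sparse bins redistributed to the fullest bins) so rare extreme values are
represented; the lowest 20% of slices are excluded by default, mirroring
the unreliable inferior slices of in vivo acquisitions.  Train/test
splits are at case level only.

Six families share one fit/predict/persist contract: QR-solved ordinary
least squares; linear ridge (Cholesky, α = 1); Gaussian-kernel ridge
(dual Cholesky, width σ from the median-pairwise-distance heuristic,
targets centred); ε-SVR with RBF kernel (C = 10, ε = 0.1 in units of the
standardised target — ε = 0.01 sd makes essentially every sample a
support vector at 5× the cost for no measurable accuracy gain); a
feedforward network with five tanh hidden layers (256/128/64/32/16;
seven layers counting input and output) trained with Adam (early
stopping, 10% validation split); and a 100-tree random forest (CART
regression trees on bootstrap resamples, min 5 samples per leaf, √d
features per split — the canonical forest choice; set 1.0 for pure
bagging).  Features are standardised for the scale-sensitive families
(ridge, kernel ridge, SVR, MLP) with statistics fit on the training set
only; a near-zero feature scale (pre-bolus time points are constant up to
floating-point dust) is clamped to 1 so noise on degenerate features is
never amplified.  Targets are standardised for SVR and MLP.  All fits are
deterministic given their seed and serialise to identical predictions.

## The synthetic cohort

No patient data ships with the package; a forward simulator stands in
for the clinical cohort.  Per case, a gamma-variate bolus

    AIF(t) = (t − t0)^α · exp(−(t − t0)/β),   t0 = 10 s, α = 3, β = 1.5 s

feeds voxels with mono-exponential residues R(t) = e^{−(t−delay)/MTT}.
Parameter fields are spatially smooth (Gaussian-filtered noise
rank-mapped onto the ranges), so patches carry real neighbourhood
information: CBF log-uniform over 0.2–2.0 (a 10× relative range), MTT
uniform in 4–12 s, bolus delay 0–6 s.  Concentration converts to signal
via I = I0·e^{−TE·CTC} (TE = 30 ms, I0 = 100), optionally with white
Gaussian intensity noise at a configured power SNR (reference cohort:
40 dB).  The default benchmark simulates 20 cases of 24×24×4 voxels at
40 frames × 1.5 s and splits them 16/4 at case level; model-comparison
experiments use 15,000 training rows with 5×5 patches, and the
noise-phantom experiment 20 repetitions over SNR 50–1 dB.  These sizes
are the package's reference conditions and keep every experiment
tractable on a single CPU.

Two quadratures for the forward convolution are provided:

* `grid` (default) — the discrete convolution Δt·(AIF ⊛ R) on the
  acquisition grid.  This is the exact forward counterpart of the
  block-circulant inverse, so noiseless oSVD recovery of CBF is exact and
  recovery tests measure regularisation error only.
* `oversampled` — the continuous convolution evaluated on a 20×-finer
  grid and sampled at frame times, emulating a scanner sampling a
  continuous system.  Under it the central-volume identity
  ∫CTC/∫AIF = CBF·MTT holds numerically to ~1% (up to ~2.6% at
  MTT = 12 s, where the 58.5 s acquisition window clips the tail), at the
  cost of a quadrature mismatch with any discrete inverse.

Two discrete-sampling biases are inherent and documented rather than
hidden.  First, with `grid` quadrature the rectangle sum Δt·ΣR[k]
overestimates the continuous ∫R = MTT by a factor
(Δt/MTT)/(1 − e^{−Δt/MTT}) — +19.7% at MTT = 4 s, +6.4% at 12 s — so
MTT = CBV/CBF estimated from exactly recovered residues still carries
that bias at short MTT.  Second, a bolus delay falling between frames
attenuates the sampled residue peak to e^{−φ/MTT}·CBF (φ the sub-frame
offset, up to 31% at MTT = 4 s); delays are therefore quantised to the
frame grid by default (`delay_on_grid`), which makes the stored
ground-truth Tmax exact and keeps CBF-recovery tests free of a
definition mismatch.  Stored truth: cbf and mtt as drawn,
cbv = cbf·mtt, ttp from the noiseless CTC, tmax the grid-aligned delay.

The fixed-threshold cSVD baseline has the textbook truncation bias: at
λ = 0.10 only 37 of 80 singular values survive for this bolus shape, the
residue is low-passed, and its peak is attenuated by 0.77 (MTT = 4 s) to
0.94 (MTT = 12 s) even without noise; the attenuation inflates
MTT = CBV/CBF correspondingly.  The error vanishes as λ → 0 and under
the adaptive oSVD rule.  Tests assert the oSVD behaviour exactly and
treat the cSVD bias as a property of the method, not a defect.

## The CBF noise phantom

Each simulated case is condensed into 12 idealised curves: CBF values
between their 5th and 95th percentiles are split into 12 equal-width
bins, and each level curve is the per-timepoint 10%-trimmed mean of the
member voxels' CTCs; the AIF is low-pass filtered (centred moving
average, window 3).  The robustness experiment perturbs the level curves
with additive white Gaussian noise over an SNR grid (power SNR in dB,
relative to the mean squared curve amplitude) and scores each model's
predictions against *that same model's* noiseless predictions via NRMSE
(averaged over levels, then cases), isolating noise sensitivity from
bias.  Patch-based models see a level curve tiled across the window — a
spatially uniform tissue block.  The relative ranking of forest versus
network at low SNR is data-dependent and is logged rather than asserted.

## Metrics

NRMSE = RMSE / (y_max − y_min), normalised by the range of the reference
values; CR = 1.96·RMSE, the half-width of the interval expected to
contain 95% of prediction-reference differences.  Bland-Altman points
are the conventional ((ŷ+y)/2, ŷ−y) pairs — mean on the abscissa — and
CR = 1.96·RMSE is asserted as an identity.  For comparing two models'
NRMSE on a shared test set a paired bootstrap (10,000 seeded resamples)
is provided.

## Numerical and design choices

* Temporal resampling to the common 40-point grid uses a cubic
  (not-a-knot) spline per curve — the 1-D analogue of an image-resize
  cubic — preserving endpoints exactly, reproducing cubics, and
  conserving the time-integral of smooth curves to well under 2%.
* Non-positive intensities are clamped to 1e-6·I(t0) before the log;
  voxels with a non-positive baseline are excluded and reported.  The
  baseline is the mean of the first k frames (k = 1 by default).
* No leakage/recirculation correction is applied to the CTCs before
  deconvolution.
* The tSVD/oSVD defaults (λ = 0.10, OI = 0.095, padding 2N) are the
  standard values from the block-circulant deconvolution literature; all
  are configurable and recorded in each map's provenance sidecar.
* Uniform-over-range sampling uses per-case quotas (pooled-cohort
  sampling is the alternative; per-case keeps every patient represented
  at every parameter level).
* The MLP optimiser is Adam rather than scaled conjugate gradients; the
  substitution is recorded in the model provenance.  Layer widths for
  the seven-layer network are a package choice.
* Tmax is the raw argmax of the residue, not delay-corrected relative to
  AIF bolus arrival.

## Limitations

The simulator omits recirculation, contrast leakage, partial-volume
effects, motion, and AIF dispersion; its residues are mono-exponential.
Passing tests therefore show that the pipeline is internally consistent
and that learned models reproduce the reference algorithm under
controlled noise — not that clinical accuracy on patient data is
matched.  Absolute error values depend on the synthetic cohort and are
not comparable to numbers measured on clinical registries.
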