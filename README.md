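# dscperf

Perfusion quantification for dynamic susceptibility contrast (DSC) MRI:
block-circulant SVD deconvolution producing the five standard perfusion
maps, plus patch-based regression models that learn to reproduce those
maps directly from concentration-time curves — with a forward simulator
and a 12-level CBF noise phantom for robustness benchmarking.

## Who this is for

Researchers in neurovascular imaging who need (a) a transparent,
scriptable reference implementation of SVD-based DSC perfusion
processing, (b) a framework for training and evaluating regression
models (linear, ridge, kernel ridge, SVR, neural network, random forest)
that map source perfusion data to map values, and (c) controlled
synthetic benchmarks where ground truth is known and noise is dialled in
dB.

## The model in brief

Signal to concentration: `CTC(t) = (1/TE)·ln(I(t0)/I(t))`.  The
indicator-dilution model `CTC = CBF·(AIF ⊛ R)` is inverted per voxel by
truncated SVD of the block-circulant convolution matrix built from the
arterial input function (delay-insensitive); the truncation threshold is
either fixed (cSVD, λ·σ_max) or adapted per voxel via an oscillation
index (oSVD).  The maps are rCBF = max CBF·R, rCBV = ∫CTC/∫AIF,
MTT = rCBV/rCBF, TTP and Tmax the peak times of CTC and CBF·R (seconds).
Learned reconstruction poses map computation as regression from a
flattened (2e+1)×(2e+1) patch of CTCs plus the AIF to the map value at
the centre voxel, trained against the package's own oSVD maps.  See
`docs/methods.md` for the full treatment.

## Worked example

```python
import numpy as np
from dscperf import (SimulationConfig, simulate_case, signal_to_ctc,
                     maps_from_case, DeconvConfig)

# a synthetic acquisition: 24x24x4 voxels, 40 frames at 1.5 s, known truth
cfg = SimulationConfig(seed=1, noise_snr_db=40.0)
series, aif, truth, _ = simulate_case(cfg)

ctc, excluded = signal_to_ctc(series)            # log-ratio conversion
maps = maps_from_case(ctc, aif, DeconvConfig())  # oSVD reference maps

err = np.abs(maps.cbf - truth.cbf) / truth.cbf
print(f"median rCBF error: {np.median(err):.1%}")
print(f"Tmax agreement:    {np.mean(maps.tmax == truth.tmax):.1%}")
```

prints (40 dB intensity noise):

```
median rCBF error: 9.3%
Tmax agreement:    2.2%
```

— at 40 dB the adaptive truncation trades accuracy for stability and the
residue argmax wanders off the true arrival frame; rerun with
`noise_snr_db=None` and the same script prints `0.0%` and `92.7%`:
noiseless oSVD inversion is essentially exact, with the remaining Tmax
disagreements at voxels whose recovered residue peaks one frame late.

Training a model to reproduce the maps, end to end, from a config:

```bash
dscperf run --config demo.yaml     # simulate -> maps -> dataset -> train -> evaluate
```

with `demo.yaml`:

```yaml
seed: 7
simulate: {n_cases: 3, shape: [18, 18, 3], noise_snr_db: 40.0}
dataset: {parameter: tmax, e: 2, n_samples: 2000, n_test: 600, train_fraction: 0.67}
train: {families: [linear, random_forest]}
```

writes per-case maps, a dataset, serialised models and `evaluation.csv`
with one row per family (NRMSE, RMSE, CR, n).  The CLI also exposes
`simulate`, `compute-maps`, `build-dataset`, `train`, `evaluate`,
`sweep` (sample-size / patch-size experiments) and `phantom-eval`
(noise robustness).

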