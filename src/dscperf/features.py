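"""Patch-based regression datasets from concentration curves and maps.

A training sample pairs one voxel's flattened feature vector with the value
of a single perfusion parameter at that voxel, taken from the reference
(deconvolution) maps.  The feature vector concatenates, in row-major order
over an in-plane (2e+1) x (2e+1) window centred on the voxel, the CTC of
every window voxel, followed by the arterial input function:

    x = [C(x-e,y-e), ..., C(x,y), ..., C(x+e,y+e), A]

giving ((2e+1)^2 + 1) * n_time entries.  No coordinates or explicit
temporal encoding are included: spatial and temporal structure is only
implicit in the ordering.

Sampling is *uniform over the parameter range* rather than over the voxel
population: the target range is split into equal-width bins and an equal
quota drawn from each, so that rare high/low parameter values are not
swamped by the bulk of the distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .deconv import PerfusionMaps
from .signal import Aif, CtcVolume

__all__ = [
    "FeatureDataset",
    "extract_patch",
    "patch_feature_length",
    "uniform_range_sample",
    "build_dataset",
]

#: number of equal-width bins for uniform-over-range sampling
DEFAULT_N_BINS = 12

#: fraction of the lowest slices excluded by default (unreliable in vivo)
DEFAULT_LOW_SLICE_DROP = 0.2

PARAMETERS = ("cbf", "cbv", "mtt", "ttp", "tmax")


def patch_feature_length(e: int, n_time: int) -> int:
    """Length of a patch feature vector: ((2e+1)^2 + 1) * n_time."""
    return ((2 * e + 1) ** 2 + 1) * n_time


@dataclass
class FeatureDataset:
    """Aligned feature rows and targets for one perfusion parameter.

    features : (n_rows, ((2e+1)^2+1)*n_time) array
    targets : (n_rows,) array of reference parameter values
    voxel_ids : list of (case, x, y, z) tuples, one per row
    provenance : parameter name, e, n_time, seed, sampling details
    """

    features: np.ndarray
    targets: np.ndarray
    voxel_ids: list[tuple]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float).ravel()
        if self.features.shape[0] != self.targets.size:
            raise ValueError("features and targets are misaligned")
        if self.features.shape[0] != len(self.voxel_ids):
            raise ValueError("voxel_ids and features are misaligned")
        if self.targets.size and not np.all(np.isfinite(self.targets)):
            raise ValueError("targets contain non-finite values")
        if len(set(self.voxel_ids)) != len(self.voxel_ids):
            raise ValueError("duplicate voxel ids in dataset")

    def __len__(self) -> int:
        return self.targets.size

    def save(self, path) -> None:
        import json

        np.savez(
            path,
            features=self.features,
            targets=self.targets,
            voxel_ids=np.array([tuple(map(str, v)) for v in self.voxel_ids]),
        )
        with open(str(path) + ".json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)

    @classmethod
    def load(cls, path) -> "FeatureDataset":
        import json

        with np.load(path, allow_pickle=False) as npz:
            feats = npz["features"]
            targets = npz["targets"]
            raw_ids = npz["voxel_ids"]
        ids = [(v[0], int(v[1]), int(v[2]), int(v[3])) for v in raw_ids]
        try:
            with open(str(path) + ".json") as fh:
                prov = json.load(fh)
        except FileNotFoundError:
            prov = {}
        return cls(features=feats, targets=targets, voxel_ids=ids, provenance=prov)


def extract_patch(
    ctc: CtcVolume, aif: Aif, x: int, y: int, z: int, e: int, pad: bool = False
) -> np.ndarray:
    """Extract one voxel's patch feature vector.

    Patches are 2-D in-plane; ``z`` selects the slice.  With ``pad`` off a
    window crossing the in-plane border raises ``IndexError`` (callers skip
    and log such voxels); with ``pad`` on, border voxels are edge-replicated
    so every voxel yields a full-length vector.
    """
    if e < 0:
        raise ValueError("half-width e must be >= 0")
    nx, ny, nz = ctc.shape
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise IndexError(f"voxel ({x}, {y}, {z}) outside volume {ctc.shape}")
    if aif.n_time != ctc.n_time:
        raise ValueError("AIF and CTC grids differ")
    if not pad and not (e <= x < nx - e and e <= y < ny - e):
        raise IndexError(
            f"patch of half-width {e} at ({x}, {y}) crosses the in-plane border"
        )
    xs = np.clip(np.arange(x - e, x + e + 1), 0, nx - 1)
    ys = np.clip(np.arange(y - e, y + e + 1), 0, ny - 1)
    block = ctc.curves[np.ix_(xs, ys, [z])][:, :, 0, :]  # (2e+1, 2e+1, n_time)
    return np.concatenate([block.reshape(-1), aif.values])


def uniform_range_sample(
    targets: np.ndarray,
    n: int,
    n_bins: int = DEFAULT_N_BINS,
    seed: int | np.random.Generator = 0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ~n voxel indices uniformly over the target-value range.

    The finite-target range is split into ``n_bins`` equal-width bins and
    ``n // n_bins`` indices drawn without replacement from each; shortfall
    in sparse bins is redistributed to the bins with most remaining
    voxels.  Returns flat indices into ``targets``; deterministic for a
    fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(targets, dtype=float).ravel()
    eligible = np.isfinite(t)
    if mask is not None:
        eligible &= np.asarray(mask, dtype=bool).ravel()
    idx_all = np.flatnonzero(eligible)
    if n < n_bins:
        raise ValueError("n must be >= n_bins")
    if idx_all.size == 0:
        raise ValueError("no finite target values to sample from")
    if idx_all.size <= n:
        warnings.warn(
            f"only {idx_all.size} finite voxels available for {n} requested",
            stacklevel=2,
        )
        return rng.permutation(idx_all)

    vals = t[idx_all]
    lo, hi = vals.min(), vals.max()
    if hi == lo:  # degenerate range: a single occupied bin
        return rng.choice(idx_all, size=n, replace=False)
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, n_bins - 1)
    bins = [idx_all[which == b] for b in range(n_bins)]

    quota = np.full(n_bins, n // n_bins)
    quota[: n % n_bins] += 1
    avail = np.array([len(b) for b in bins])
    take = np.minimum(quota, avail)
    shortfall = n - take.sum()
    while shortfall > 0:  # hand leftover quota to the fullest bins
        room = avail - take
        if room.max() == 0:
            break
        b = int(np.argmax(room))
        extra = min(shortfall, room[b])
        take[b] += extra
        shortfall -= extra

    picks = [rng.choice(bins[b], size=take[b], replace=False) for b in range(n_bins) if take[b] > 0]
    return np.concatenate(picks)


def _resolve_slice_range(nz: int, slice_range: tuple[int, int] | None) -> tuple[int, int]:
    if slice_range is None:
        return int(np.ceil(DEFAULT_LOW_SLICE_DROP * nz)), nz
    lo, hi = slice_range
    if not (0 <= lo < hi <= nz):
        raise ValueError(f"invalid slice_range {slice_range} for {nz} slices")
    return lo, hi


def build_dataset(
    cases: list[tuple[str, CtcVolume, Aif, PerfusionMaps]],
    parameter: str,
    e: int = 0,
    n_samples: int = 1000,
    slice_range: tuple[int, int] | None = None,
    seed: int = 0,
    n_bins: int = DEFAULT_N_BINS,
) -> FeatureDataset:
    """Assemble a regression dataset across cases.

    Each case contributes an equal quota ``n_samples // n_cases`` of voxels
    drawn uniformly over the parameter range *within that case*.  The
    lowest slices are excluded (default: bottom 20%, mirroring the
    unreliable inferior sections of in vivo acquisitions), as are voxels
    whose patch would cross the in-plane border.

    ``cases`` holds (case_id, ctc, aif, maps) tuples.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    if not cases:
        raise ValueError("no cases supplied")
    rng = np.random.default_rng(seed)
    quota = n_samples // len(cases)
    rows, targets, ids = [], [], []
    for case_id, ctc, aif, maps in cases:
        try:
            target_map = maps[parameter]
        except (KeyError, AttributeError) as err:
            raise ValueError(f"case {case_id!r} lacks parameter {parameter!r}") from err
        nx, ny, nz = ctc.shape
        zlo, zhi = _resolve_slice_range(nz, slice_range)
        eligible = np.zeros(ctc.shape, dtype=bool)
        eligible[e : nx - e or None, e : ny - e or None, zlo:zhi] = True
        if ctc.mask is not None:
            eligible &= ctc.mask
        flat = uniform_range_sample(
            target_map, quota, n_bins=n_bins, seed=rng, mask=eligible
        )
        for fi in flat:
            x, y, z = np.unravel_index(fi, ctc.shape)
            rows.append(extract_patch(ctc, aif, int(x), int(y), int(z), e))
            targets.append(target_map[x, y, z])
            ids.append((case_id, int(x), int(y), int(z)))
    provenance = {
        "parameter": parameter,
        "e": e,
        "n_time": cases[0][1].n_time,
        "n_samples_requested": n_samples,
        "n_bins": n_bins,
        "seed": seed,
        "slice_range": slice_range,
        "cases": [c[0] for c in cases],
        "sampling": "uniform-over-range, per-case quota",
    }
    return FeatureDataset(
        features=np.array(rows) if rows else np.empty((0, patch_feature_length(e, cases[0][1].n_time))),
        targets=np.array(targets),
        voxel_ids=ids,
        provenance=provenance,
    )
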