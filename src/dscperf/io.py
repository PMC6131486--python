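"""File round-trips: NIfTI volumes, two-column AIF text, provenance sidecars.

Echo time and frame spacing are not reliably carried by NIfTI headers, so
4-D series are read together with a YAML/JSON sidecar holding
``te_seconds`` and ``dt_seconds`` (and optionally ``baseline_index``).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .deconv import PerfusionMaps
from .signal import Aif, CtcVolume, DscSeries

__all__ = [
    "read_series",
    "write_ctc",
    "read_ctc",
    "write_aif",
    "read_aif",
    "write_maps",
    "read_maps",
    "load_config",
]

MAP_NAMES = ("cbf", "cbv", "mtt", "ttp", "tmax")


def load_config(path) -> dict:
    """Load a YAML or JSON parameter file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def read_series(nifti_path, sidecar_path, brain_mask_path=None) -> DscSeries:
    """Read a 4-D NIfTI series with its acquisition-metadata sidecar."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    meta = load_config(sidecar_path)
    mask = None
    if brain_mask_path is not None:
        mask = np.asarray(nib.load(str(brain_mask_path)).dataobj) > 0
    return DscSeries(
        intensities=data,
        te_seconds=float(meta["te_seconds"]),
        dt_seconds=float(meta["dt_seconds"]),
        baseline_index=int(meta.get("baseline_index", 0)),
        baseline_frames=int(meta.get("baseline_frames", 1)),
        brain_mask=mask,
    )


def write_ctc(ctc: CtcVolume, path) -> None:
    nib.save(nib.Nifti1Image(ctc.curves, np.eye(4)), str(path))
    sidecar = {"dt_seconds": ctc.dt_seconds, "n_time": ctc.n_time}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_ctc(path) -> CtcVolume:
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return CtcVolume(curves=data, dt_seconds=float(meta["dt_seconds"]))


def write_aif(aif: Aif, path) -> None:
    """Two-column text: time in seconds, concentration."""
    t = np.arange(aif.n_time) * aif.dt_seconds
    header = f"source: {aif.source}\ntime_s concentration"
    np.savetxt(str(path), np.column_stack([t, aif.values]), header=header)


def read_aif(path) -> Aif:
    arr = np.loadtxt(str(path))
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("AIF file must have two columns (time_s, concentration)")
    dt = float(arr[1, 0] - arr[0, 0])
    return Aif(values=arr[:, 1], dt_seconds=dt, source=f"file {path}")


def write_maps(maps: PerfusionMaps, out_dir) -> None:
    """One 3-D NIfTI per parameter plus a JSON provenance sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in MAP_NAMES:
        nib.save(nib.Nifti1Image(maps[name].astype(np.float64), np.eye(4)), str(out / f"{name}.nii.gz"))
    (out / "provenance.json").write_text(json.dumps(maps.provenance, indent=2, default=str))


def read_maps(map_dir) -> PerfusionMaps:
    d = Path(map_dir)
    vols = {
        name: np.asarray(nib.load(str(d / f"{name}.nii.gz")).dataobj, dtype=float)
        for name in MAP_NAMES
    }
    prov_path = d / "provenance.json"
    prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    return PerfusionMaps(provenance=prov, **vols)
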