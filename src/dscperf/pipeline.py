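"""End-to-end driver: simulate -> maps -> dataset -> train -> evaluate.

The pipeline is configured by a nested dictionary (usually loaded from
YAML), validated against a schema of known keys, and writes every stage's
artifacts — plus the fully resolved configuration — into one output
directory, so a run is reproducible from the directory alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .deconv import DeconvConfig, maps_from_case
from .evaluation import evaluate_model, split_cases
from .features import build_dataset
from .phantom import SimulationConfig, simulate_case
from .regressors import fit_family, save_model
from .signal import signal_to_ctc

__all__ = ["run_pipeline", "validate_config", "DEFAULT_CONFIG", "simulate_cohort"]

log = logging.getLogger("dscperf")

DEFAULT_CONFIG: dict = {
    "schema_version": 1,
    "seed": 0,
    "out_dir": "pipeline_out",
    "simulate": {
        "n_cases": 3,
        "shape": [24, 24, 4],
        "noise_snr_db": 40.0,
    },
    "deconvolution": {
        "method": "osvd",
        "truncation_fraction": 0.10,
        "oscillation_threshold": 0.095,
    },
    "dataset": {
        "parameter": "tmax",
        "e": 2,
        "n_samples": 2000,
        "n_test": 1000,
        "train_fraction": 0.8,
    },
    "train": {
        "families": ["linear", "random_forest"],
    },
}

_KNOWN_KEYS = {
    "": {"schema_version", "seed", "out_dir", "simulate", "deconvolution", "dataset", "train"},
    "simulate": {"n_cases", "shape", "noise_snr_db", "n_time", "dt_seconds", "te_seconds"},
    "deconvolution": {"method", "truncation_fraction", "oscillation_threshold", "pad_factor"},
    "dataset": {"parameter", "e", "n_samples", "n_test", "train_fraction", "slice_range"},
    "train": {"families", "hyperparameters"},
}


def validate_config(config: dict) -> dict:
    """Merge over defaults and reject unknown keys before any compute."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for section, value in config.items():
        if section not in _KNOWN_KEYS[""]:
            raise ValueError(f"unknown config key {section!r}")
        if isinstance(value, dict):
            for key in value:
                if key not in _KNOWN_KEYS.get(section, set()):
                    raise ValueError(f"unknown config key {section}.{key}")
            merged[section].update(value)
        else:
            merged[section] = value
    return merged


def simulate_cohort(
    n_cases: int, base: SimulationConfig | None = None, seed: int = 0
) -> list[tuple]:
    """Simulate ``n_cases`` independent cases; returns (id, series, aif,
    truth, noiseless ctc) tuples.  Case seeds derive from ``seed``."""
    base = base or SimulationConfig()
    out = []
    for i in range(n_cases):
        cfg = replace(base, seed=seed * 10_007 + i)
        series, aif, truth, ctc = simulate_case(cfg)
        out.append((f"case{i:03d}", series, aif, truth, ctc))
    return out


def run_pipeline(config: dict) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    cfg = validate_config(config)
    rng_seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "resolved_config.json").write_text(json.dumps(cfg, indent=2))

    timings = {}
    t0 = time.time()
    sim = cfg["simulate"]
    sim_cfg = SimulationConfig(
        shape=tuple(sim["shape"]),
        noise_snr_db=sim.get("noise_snr_db"),
        **{k: sim[k] for k in ("n_time", "dt_seconds", "te_seconds") if k in sim},
    )
    cohort = simulate_cohort(sim["n_cases"], sim_cfg, seed=rng_seed)
    timings["simulate"] = time.time() - t0
    log.info("simulated %d cases in %.1fs", len(cohort), timings["simulate"])

    t0 = time.time()
    dcfg = DeconvConfig(**cfg["deconvolution"])
    cases = []
    for case_id, series, aif, truth, _ in cohort:
        ctc, _excluded = signal_to_ctc(series)
        maps = maps_from_case(ctc, aif, dcfg)
        io.write_maps(maps, out_dir / "maps" / case_id)
        cases.append((case_id, ctc, aif, maps))
    timings["compute_maps"] = time.time() - t0
    log.info("deconvolved %d cases in %.1fs", len(cases), timings["compute_maps"])

    t0 = time.time()
    ds = cfg["dataset"]
    ids = [c[0] for c in cases]
    train_ids, test_ids = split_cases(ids, ds["train_fraction"], seed=rng_seed)
    by_id = {c[0]: c for c in cases}
    train = build_dataset(
        [by_id[i] for i in train_ids], ds["parameter"], e=ds["e"],
        n_samples=ds["n_samples"], seed=rng_seed,
        slice_range=tuple(ds["slice_range"]) if ds.get("slice_range") else None,
    )
    test = build_dataset(
        [by_id[i] for i in test_ids], ds["parameter"], e=ds["e"],
        n_samples=ds["n_test"], seed=rng_seed + 1,
        slice_range=tuple(ds["slice_range"]) if ds.get("slice_range") else None,
    )
    train.save(out_dir / "train_dataset.npz")
    timings["build_dataset"] = time.time() - t0

    t0 = time.time()
    rows = []
    hp = cfg["train"].get("hyperparameters", {})
    for family in cfg["train"]["families"]:
        model = fit_family(family, train.features, train.targets, seed=rng_seed, **hp.get(family, {}))
        model.training_provenance = {
            "n_rows": len(train),
            "parameter": ds["parameter"],
            "e": ds["e"],
            "seed": rng_seed,
        }
        save_model(model, out_dir / f"model_{family}.joblib")
        res = evaluate_model(model, test.features, test.targets)
        rows.append({"family": family, "parameter": ds["parameter"], "e": ds["e"],
                     "n_train": len(train), "seed": rng_seed, **res})
        log.info("%s: NRMSE=%.4f CR=%.4f", family, res["nrmse"], res["cr"])
    timings["train_evaluate"] = time.time() - t0

    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "evaluation.csv", index=False)
    (out_dir / "timings.json").write_text(json.dumps(timings, indent=2))
    return out_dir
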