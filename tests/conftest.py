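"""Shared fixtures: a synthetic 20-case cohort with reference maps.

The cohort mirrors the package's reference study conditions (24x24x4
voxels, 40 frames at 1.5 s, 40 dB intensity noise) and is simulated once
per session because the model-comparison tests all consume it.
"""

import numpy as np
import pytest

from dscperf.deconv import maps_from_case
from dscperf.phantom import SimulationConfig, simulate_case
from dscperf.pipeline import simulate_cohort
from dscperf.signal import signal_to_ctc

COHORT_SEED = 11


@pytest.fixture(scope="session")
def cohort():
    """20 simulated cases, each with (id, ctc, aif, osvd maps, truth, clean ctc)."""
    base = SimulationConfig(noise_snr_db=40.0)
    out = []
    for cid, series, aif, truth, ctc_clean in simulate_cohort(20, base, seed=COHORT_SEED):
        ctc, _ = signal_to_ctc(series)
        maps = maps_from_case(ctc, aif)
        out.append(
            {
                "id": cid,
                "ctc": ctc,
                "aif": aif,
                "maps": maps,
                "truth": truth,
                "ctc_clean": ctc_clean,
            }
        )
    return out


@pytest.fixture(scope="session")
def cohort_cases(cohort):
    """The cohort in build_dataset's (id, ctc, aif, maps) layout."""
    return [(c["id"], c["ctc"], c["aif"], c["maps"]) for c in cohort]


@pytest.fixture()
def tiny_case():
    """A fast noiseless 6x6x2 case for unit tests."""
    cfg = SimulationConfig(shape=(6, 6, 2), seed=5)
    series, aif, truth, ctc = simulate_case(cfg)
    return series, aif, truth, ctc
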