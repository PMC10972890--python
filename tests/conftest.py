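from pathlib import Path

import numpy as np
import pytest

from microstatekit import (
    ClusterConfig,
    Recording,
    SynthConfig,
    extract_peak_maps,
    simulate_recording,
)

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    return Recording(
        rng.normal(0, 20, size=(8, 512)),
        200.0,
        [f"CH{i}" for i in range(8)],
        {"subject": "s01", "trial": 3},
    )


@pytest.fixture(scope="session")
def planted():
    """Standard planted-microstate simulation shared across tests.

    K_true=4 well-separated templates, 32 channels, 120 s at 200 Hz,
    geometric segment durations with 100 ms mean, SNR 4.
    """
    cfg = SynthConfig(
        K_true=4, C=32, fs=200.0, duration_s=120.0, mean_duration_ms=100.0,
        snr=4.0, seed=1,
    )
    rec, truth, segs, templates = simulate_recording(cfg)
    return dict(cfg=cfg, rec=rec, truth=truth, segs=segs, templates=templates)


@pytest.fixture(scope="session")
def planted_bank(planted):
    return extract_peak_maps(planted["rec"], cap_per_recording=1000, seed=1)


@pytest.fixture(scope="session")
def fast_cluster_cfg():
    return ClusterConfig(restarts=5, max_iter=50, seed=1)


@pytest.fixture(scope="session")
def gev_tables():
    import pandas as pd

    out = {}
    for name, path, C in [
        ("seed", DATA_DIR / "gev_seed_62ch.tsv", 62),
        ("deap", DATA_DIR / "gev_deap_32ch.tsv", 32),
    ]:
        t = pd.read_csv(path, sep="\t")
        out[name] = (dict(zip(t["K"].astype(int), t["GEV"].astype(float))), C)
    return out
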