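import numpy as np
import pytest

from libsid import preprocess as pp
from libsid import sim


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated study: 5 varieties × 8 seeds × 3 spectra
    on a coarse 230-500 nm grid (fast enough for many tests)."""
    cfg = sim.SimConfig(n_varieties=5, seeds_per_variety=8,
                        grid_start_nm=230.0, grid_end_nm=500.0,
                        grid_step_nm=0.5, rng_seed=42)
    lines = [l for l in sim.default_line_table() if l.wavelength_nm < 500]
    profiles = sim.default_profiles(5, n_lines=len(lines), separation=0.4,
                                    rng_seed=7)
    return sim.simulate_dataset(cfg, profiles, lines), cfg


@pytest.fixture(scope="session")
def small_prep(small_dataset):
    ds, _ = small_dataset
    return pp.preprocess_dataset(ds, lo_nm=242.0, hi_nm=490.0,
                                 ratio=(3, 1, 1), rng_seed=5)


@pytest.fixture(scope="session")
def tiny_net_spec():
    from libsid import models
    return models.NetworkSpec(dims=1, input_length=64, stem_channels=8,
                              block_channels=(8, 16), n_classes=4,
                              mode=models.PropagationMode.PER_BLOCK,
                              dtype="float64")
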