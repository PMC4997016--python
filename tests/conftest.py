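"""Shared fixtures: small simulated ensembles reused across test modules.

Everything is generated at test time from fixed seeds; no stored data.
"""

import numpy as np
import pytest

import raftspt as r


@pytest.fixture(scope="session")
def lo_model():
    """All-Lo membrane patch with the default nano-trap field at the
    nominal calibrated density."""
    return r.MembraneModel.uniform_lo(
        extent_um=(2.0, 2.0), trap_area_fraction=0.31, seed=7
    )


@pytest.fixture(scope="session")
def lo_ensemble(lo_model):
    """30 tracks of 1,500 frames simulated deep inside the Lo trap field
    (20 us frames, 3 nm noise, burn-in discarded)."""
    trajs = []
    for i in range(30):
        cfg = r.SimConfig(n_steps=1500, d_free=0.26, seed=3000 + i)
        trajs.append(
            r.simulate_membrane(cfg, lo_model, d_lo_free=0.26, burn_in_steps=250)
        )
    return trajs


@pytest.fixture(scope="session")
def brownian_track():
    """One long free-diffusion track at the benchmark rate."""
    return r.simulate_brownian(r.SimConfig(n_steps=20000, d_free=1.48, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
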