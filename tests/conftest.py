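"""Shared fixtures: presets, the calibrated escape model, and the
standard 500-trace batches at saturating ATP reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import kinrun as kr

#: master seed for the shared batches (fixed once for reproducibility)
SEED = 101
N_TRACES = 500


@pytest.fixture(scope="session")
def escape_model():
    return kr.default_escape_model()


@pytest.fixture(scope="session")
def k1_params():
    return kr.default_parameters(kr.KINESIN1)


@pytest.fixture(scope="session")
def k3_params():
    return kr.default_parameters(kr.KINESIN3)


def _batch(params, seed_offset=0, n=N_TRACES, **cfg_kwargs):
    cfg = kr.SimulationConfig(n_traces=n, rng_seed=SEED + seed_offset, **cfg_kwargs)
    return kr.simulate_traces(params, cfg)


@pytest.fixture(scope="session")
def k1_traces(k1_params):
    """Kinesin-1 preset, 2 mM ATP, no load."""
    return _batch(k1_params, 0)


@pytest.fixture(scope="session")
def k3_traces(k3_params):
    """Kinesin-3 preset (n = 10), 2 mM ATP, no load."""
    return _batch(k3_params, 1)


@pytest.fixture(scope="session")
def enhanced_k1_traces(k1_params):
    """Kinesin-1 with E_w2 raised to 45 k_BT."""
    return _batch(kr.preset_variant(k1_params, "ew2_enhanced_k1"), 2)


@pytest.fixture(scope="session")
def kif1a_traces(k3_params):
    """KIF1A(1-393)-like construct: INT-state ATPase active from t = 0."""
    return _batch(kr.preset_variant(k3_params, "kif1a_393"), 3)


@pytest.fixture(scope="session")
def l8_traces(k3_params):
    """Kinesin-3 loop-8 mutant emulation: E_w2 = 39 k_BT."""
    return _batch(kr.preset_variant(k3_params, "l8_mutant"), 4)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
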