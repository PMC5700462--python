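import warnings

import numpy as np
import pytest

from smfet import (
    extract_dwells,
    kinetic_summary,
    load_reference_models,
    render_trace,
    simulate_state_path,
)

#: Long-run time fractions (low/intermediate/high, %) implied by the reference
#: transition-probability / mean-lifetime matrices: embedded-chain stationary
#: distribution weighted by destination-averaged mean dwells, computed by an
#: independent linear solve and frozen here.  These deliberately differ from
#: the measured occupancy profiles (missed events in real recordings).
STATIONARY_ORACLE = {
    "WT-C": (87.73, 11.13, 1.14),
    "MT-A": (6.22, 84.05, 9.73),
    "MT-G": (7.39, 82.16, 10.45),
    "MT-T": (1.32, 90.51, 8.17),
}


@pytest.fixture(scope="session")
def models():
    return load_reference_models()


@pytest.fixture(scope="session")
def wtc_model(models):
    return models["WT-C"]


@pytest.fixture(scope="session")
def allele_matrices(models):
    """Kinetic matrices estimated from a 20,000-exit simulation per allele."""
    out = {}
    for i, (label, model) in enumerate(models.items()):
        path = simulate_state_path(model, 20_000, seed=100 + i)
        out[label] = kinetic_summary(extract_dwells(path), seed=0)
    return out


@pytest.fixture(scope="session")
def wtc_rendered(wtc_model):
    """A rendered WT-C trace (noise sd 0.5 nA) plus its generating path."""
    path = simulate_state_path(wtc_model, 300, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        trace = render_trace(path, wtc_model, seed=4)
    return path, trace


def per_sample_labels(path, dt, clamp=True):
    """Expand a StatePath to per-sample labels on the grid render_trace uses."""
    edges = np.concatenate([[0.0], np.cumsum(path.durations)])
    counts = np.diff(np.round(edges / dt).astype(np.int64))
    if clamp:
        counts[counts < 1] = 1
    return np.repeat(np.asarray(path.states, dtype=object), counts)
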