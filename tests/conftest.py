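"""Shared fixtures: all test data are generated programmatically and seeded."""

import numpy as np
import pytest

from txdecomp.model import DecompositionModel
from txdecomp.simulate import simulate_counts, simulate_multicell, simulate_universe


@pytest.fixture(scope="session")
def recovery_fit():
    """One expensive hurdle-NB recovery fit shared across tests.

    Conditions: 2,000 bins, 3 replicates, tau_rw=1, tau_iid=4, k=5, p0=0.3.
    """
    Y, depths, truth = simulate_counts(
        n_bins=2000, n_reps=3, tau_rw=1.0, tau_iid=4.0, k=5.0, p0=0.3, seed=42
    )
    model = DecompositionModel(Y, depths=depths, family="hurdle")
    results = model.fit()
    return {"Y": Y, "depths": depths, "truth": truth, "results": results}


@pytest.fixture(scope="session")
def multicell_tracks():
    """Three-cell PD tracks with 20 planted boundary steps over 5,000 bins."""
    rng = np.random.default_rng(7)
    positions = np.sort(rng.choice(np.arange(100, 4900), size=20, replace=False))
    tracks, sds, truth = simulate_multicell(
        n_cells=3, n_bins=5000, boundary_positions=positions, seed=7
    )
    return {"tracks": tracks, "sds": sds, "truth": truth}


@pytest.fixture(scope="session")
def planted_universe():
    """Pair universe with a strong planted logistic signal."""
    coefficients = np.array([1.5, 1.5, -0.5, -0.5, 0.5, 0.5, 1.0, 2.0, -1.0, 0.5, -2.0])
    X, y, truth = simulate_universe(
        n_pairs=5000, coefficients=coefficients, intercept=-1.5, seed=11
    )
    return {"X": X, "y": y, "truth": truth}
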