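import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pseshift import (
    aggregate_proportions,
    build_design,
    fit_table,
    make_observers,
    shift_table,
    simulate_experiment,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def e4_sim():
    """One fully simulated saline/oxytocin experiment (24 high-AQ observers)."""
    design = build_design("E4")
    observers = make_observers(design, 11)
    trials, manifest = simulate_experiment(design, observers, 11)
    return design, observers, trials, manifest


@pytest.fixture(scope="session")
def e4_tables(e4_sim):
    """Derived tables (proportions, fits, shifts) for the simulated experiment."""
    _, _, trials, _ = e4_sim
    cells = aggregate_proportions(trials)
    agg = cells.groupby(
        ["participant_id", "drug", "odor", "z_level"], observed=True, as_index=False
    ).agg(p_norm=("p_norm", "mean"))
    fits = fit_table(agg)
    shifts = shift_table(fits)
    return cells, fits, shifts


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
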