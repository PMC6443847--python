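import dataclasses

import pytest

from n15budget.budget import compute_budgets
from n15budget.simulate import SimConfig, generate_experiment


@pytest.fixture(scope="session")
def noiseless_cohort():
    """A fully idealized experiment (no noise, no between-plant variation,
    perfect leach) and its per-plant budgets."""
    config = SimConfig().noiseless()
    records, truth = generate_experiment(config, seed=11)
    budgets = compute_budgets(records)
    return records, truth, budgets


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default study conditions, one labelled plant per block/cell/phase."""
    config = SimConfig()
    records, truth = generate_experiment(config, seed=12)
    budgets = compute_budgets(records)
    return records, truth, budgets


@pytest.fixture(scope="session")
def large_noisy_cohort():
    """Default noise at Monte-Carlo size: ~1000 labelled plants per phase."""
    config = dataclasses.replace(SimConfig(), maturity_replicates=32)
    records, truth = generate_experiment(config, seed=13)
    budgets = compute_budgets(records)
    return records, truth, budgets
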