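"""Shared fixtures: small synthetic datasets and one session-scoped
hierarchical fit with a planted attentional-control factor, reused by the
posterior-dependent tests to keep the suite fast."""

import numpy as np
import pandas as pd
import pytest

from driftsem import (
    HierarchicalDiffusionModel,
    ScenarioConfig,
    TrialDataset,
    make_ground_truth,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def planted_truth():
    """Three tasks whose drift congruency differences share a single factor
    with loading 0.7 (pairwise correlation 0.49)."""
    cfg = ScenarioConfig(
        n_subjects=16, n_tasks=3, trials_per_cell=24, delta_corr=0.49, seed=21
    )
    return make_ground_truth(cfg)


@pytest.fixture(scope="session")
def planted_data(planted_truth):
    return simulate_dataset(planted_truth)


@pytest.fixture(scope="session")
def planted_fit(planted_data):
    model = HierarchicalDiffusionModel(planted_data, coding="difference")
    return model.fit(chains=2, warmup=200, draws=200, seed=22, max_treedepth=9)


@pytest.fixture(scope="session")
def tiny_fit():
    """Very small fit for smoke tests of posterior plumbing."""
    cfg = ScenarioConfig(
        n_subjects=6, n_tasks=3, trials_per_cell=12, delta_corr=0.0, seed=5
    )
    gt = make_ground_truth(cfg)
    ds = simulate_dataset(gt)
    model = HierarchicalDiffusionModel(ds, coding="difference")
    return model.fit(chains=2, warmup=80, draws=60, seed=6)


@pytest.fixture()
def five_trials():
    return TrialDataset(pd.DataFrame({
        "subject": ["s1", "s1", "s1", "s2", "s2"],
        "task": ["stroop"] * 5,
        "condition": ["congruent", "incongruent", "congruent",
                      "incongruent", "congruent"],
        "rt": [0.45, 0.62, 0.51, 0.70, 0.48],
        "correct": [1, 1, 0, 1, 1],
    }))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
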