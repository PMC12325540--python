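from __future__ import annotations

import numpy as np
import pytest

import nichetda as nt

COHORT_SEED = 101
COHORT_N_PER_REGIME = 20


@pytest.fixture(scope="session")
def regime_cohort():
    """The 60-run (20 per regime) generator cohort used by the end-to-end and
    cohort-property tests; generated once per session."""
    return nt.generate_cohort(COHORT_N_PER_REGIME, base_seed=COHORT_SEED)


@pytest.fixture(scope="session")
def short_run():
    """A single cheap escape-regime run with a reduced horizon."""
    from dataclasses import replace

    params = replace(nt.preset_params("escape", 5), horizon=200)
    return nt.simulate_run(params)


def random_cloud(rng: np.random.Generator, n: int, scale: float = 50.0) -> np.ndarray:
    return rng.uniform(0.0, scale, (n, 2))
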