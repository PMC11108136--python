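"""Shared fixtures: small synthetic panels and randomized chains."""

from __future__ import annotations

import numpy as np
import pytest

import healthexp as hx
from healthexp.matrices import ABSORBING_ROW, TransitionMatrixSet
from healthexp.simulation import TrajectorySample
from healthexp.states import SEXES

#: Seed fixed once for every stochastic fixture in the suite.
SEED = 20240521


@pytest.fixture(scope="session")
def small_spec():
    return hx.default_study_like_spec(scale=0.1, seed=SEED)


@pytest.fixture(scope="session")
def small_panel(small_spec):
    return hx.generate_panel(small_spec)


@pytest.fixture(scope="session")
def small_group_matrices(small_panel):
    counts = hx.count_transitions(small_panel)
    mset, _ = hx.estimate_group_matrices(counts)
    return mset


@pytest.fixture(scope="session")
def small_yearly(small_group_matrices):
    return hx.interpolate_yearly(small_group_matrices)


@pytest.fixture(scope="session")
def small_init(small_panel):
    return hx.initial_state_distribution(small_panel)


def random_stochastic_matrix(rng, mortality: float) -> np.ndarray:
    """Random 7x7 row-stochastic matrix with absorbing death.

    Each living row gets a Dirichlet draw over the living states scaled
    to 1 - q, with an annual death probability q jittered around
    ``mortality``.
    """
    m = np.empty((7, 7))
    for i in range(6):
        q = mortality * rng.uniform(0.5, 1.5)
        alive = rng.dirichlet(np.ones(6) + 4 * np.eye(6)[i])
        m[i, :6] = (1.0 - q) * alive
        m[i, 6] = q
    m[6] = ABSORBING_ROW
    return m


def stationary_chain(seed: int, mortality: float = 0.1) -> TransitionMatrixSet:
    """A single-age randomized stationary chain (same matrix at all ages)."""
    rng = np.random.default_rng(seed)
    matrices = {(sex, 0): random_stochastic_matrix(rng, mortality)
                for sex in SEXES}
    return TransitionMatrixSet(index_kind="single_year", matrices=matrices)


def uniform_init() -> dict[str, np.ndarray]:
    return {sex: np.full(6, 1 / 6) for sex in SEXES}


def sample_from_states(per_sex: dict[str, list[tuple[tuple[int, ...], bool]]]
                       ) -> TrajectorySample:
    """Build a TrajectorySample from explicit (states, censored) tuples."""
    T = max(len(s) for trajs in per_sex.values() for s, _ in trajs)
    sample = TrajectorySample(seed=None, max_attained_age=T, source="manual")
    for sex, trajs in per_sex.items():
        states = np.zeros((len(trajs), T), dtype=np.int8)
        cens = np.zeros(len(trajs), dtype=bool)
        for p, (seq, censored) in enumerate(trajs):
            states[p, :len(seq)] = seq
            cens[p] = censored
        sample._states[sex] = states
        sample._censored[sex] = cens
    return sample
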