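"""Monte Carlo engine vs forced cases and the analytic oracle."""

import numpy as np
import pandas as pd
import pytest

import healthexp as hx
from healthexp.errors import ValidationError
from healthexp.matrices import ABSORBING_ROW, TransitionMatrixSet
from healthexp.states import SEXES

from conftest import SEED, stationary_chain, uniform_init


def single_matrix_chain(matrix):
    return TransitionMatrixSet("single_year", {
        (sex, 0): np.asarray(matrix, float) for sex in SEXES})


def all_death_chain():
    m = np.zeros((7, 7))
    m[:, 6] = 1.0
    return single_matrix_chain(m)


class TestInitialStateDistribution:
    def test_degenerate_composition(self):
        df = pd.DataFrame({"person_id": ["a", "b"], "sex": ["female", "male"],
                           "age": [0, 0], "state_t": [1, 1], "state_t1": [1, 1]})
        init = hx.initial_state_distribution(df)
        np.testing.assert_array_equal(init["female"], [1, 0, 0, 0, 0, 0])

    def test_direct_frequency(self):
        rows = [("m%d" % k, "male", 0, 1, 1) for k in range(8)] \
            + [("m8", "male", 0, 2, 1), ("m9", "male", 0, 2, 1)] \
            + [("f", "female", 0, 1, 1)]
        df = pd.DataFrame(rows, columns=["person_id", "sex", "age",
                                         "state_t", "state_t1"])
        init = hx.initial_state_distribution(df)
        np.testing.assert_allclose(init["male"], [0.8, 0.2, 0, 0, 0, 0])

    def test_matches_independent_tally(self, small_panel, small_init):
        infants = small_panel[small_panel["age"] == 0]
        for sex in SEXES:
            sub = infants[infants["sex"] == sex]["state_t"]
            freq = np.array([(sub == j).mean() for j in range(1, 7)])
            np.testing.assert_allclose(small_init[sex], freq, atol=1e-12)

    def test_empty_under_one_stratum_fails_with_suggestion(self):
        df = pd.DataFrame({"person_id": ["a"], "sex": ["male"], "age": [40],
                           "state_t": [1], "state_t1": [1]})
        with pytest.raises(ValidationError, match="override"):
            hx.initial_state_distribution(df)


class TestSimulateTrajectories:
    def test_forced_immediate_absorption(self):
        sample = hx.simulate_trajectories(all_death_chain(), uniform_init(),
                                          n_per_sex=50, seed=SEED)
        for sex in SEXES:
            years = sample.years(sex)
            assert (years == 1).all()
            for tr in sample.trajectories(sex):
                assert tr.age_at_death == 0 and tr.years_lived == 1

    def test_identity_dynamics_censor_everyone(self):
        chain = single_matrix_chain(np.eye(7))
        with pytest.warns(UserWarning, match="censored"):
            sample = hx.simulate_trajectories(chain, uniform_init(),
                                              n_per_sex=50, seed=SEED,
                                              max_attained_age=30)
        for sex in SEXES:
            assert sample.censored(sex).all()
            states = sample.states(sex)
            # initial state retained for all 30 years
            assert (states == states[:, :1]).all()

    def test_geometric_survival_mean(self):
        # constant annual death probability q from every living state:
        # completed years are geometric with mean 1/q
        q = 0.5
        m = np.zeros((7, 7))
        m[:6, :6] = np.eye(6) * (1 - q)
        m[:6, 6] = q
        m[6] = ABSORBING_ROW
        sample = hx.simulate_trajectories(single_matrix_chain(m),
                                          uniform_init(), n_per_sex=20_000,
                                          seed=SEED, max_attained_age=60)
        mean_years = np.concatenate([sample.years(s) for s in SEXES]).mean()
        n = 40_000
        se = np.sqrt((1 - q) / q ** 2 / n)
        assert abs(mean_years - 1 / q) < 3 * se

    def test_reproducible_given_seed(self, small_yearly, small_init):
        a = hx.simulate_trajectories(small_yearly, small_init, 200, seed=SEED)
        b = hx.simulate_trajectories(small_yearly, small_init, 200, seed=SEED)
        for sex in SEXES:
            np.testing.assert_array_equal(a.states(sex), b.states(sex))
            np.testing.assert_array_equal(a.censored(sex), b.censored(sex))

    def test_no_state_after_death(self, small_yearly, small_init):
        sample = hx.simulate_trajectories(small_yearly, small_init, 500,
                                          seed=SEED)
        for sex in SEXES:
            states = sample.states(sex)
            alive = states != 0
            # once dead (0), never alive again: alive mask is a prefix
            assert (alive[:, :-1] >= alive[:, 1:]).all()
            for tr in sample.trajectories(sex):
                assert all(1 <= s <= 6 for s in tr.states)

    def test_requires_single_year_set(self, small_group_matrices, small_init):
        with pytest.raises(ValidationError, match="single_year"):
            hx.simulate_trajectories(small_group_matrices, small_init, 10)

    def test_markov_property_next_state_depends_on_current_only(self):
        # conditional frequency of next state given current state at a
        # fixed age matches the matrix row regardless of earlier history
        chain = stationary_chain(SEED, mortality=0.02)
        sample = hx.simulate_trajectories(chain, uniform_init(), 20_000,
                                          seed=SEED, max_attained_age=10)
        states = sample.states("female")
        row = chain.matrix("female", 0)
        at3, at4, at2 = states[:, 3], states[:, 4], states[:, 2]
        for hist in (1, 2):  # condition on different histories at age 2
            sel = (at3 == 1) & (at2 == hist)
            if sel.sum() < 500:
                continue
            nxt = at4[sel]
            for j in (1, 2, 7):
                obs = (nxt == (0 if j == 7 else j)).mean() if j == 7 \
                    else (nxt == j).mean()
                expected = row[0, 6] if j == 7 else row[0, j - 1]
                assert abs(obs - expected) < 4 * np.sqrt(
                    expected * (1 - expected) / sel.sum()) + 0.01


class TestAnalyticExpectancies:
    def test_forced_absorption_le_is_one_year(self):
        table = hx.analytic_expectancies(all_death_chain(), uniform_init(),
                                         max_attained_age=10)
        for sex in SEXES:
            assert table.expectancy(sex, 0) == pytest.approx(1.0)

    def test_state_partition_sums_exactly(self):
        chain = stationary_chain(SEED + 1)
        table = hx.analytic_expectancies(chain, uniform_init(), 60)
        for sex in SEXES:
            df = table.tables[sex]
            total = sum(df[f"e{j}"] for j in range(1, 7))
            np.testing.assert_allclose(total, df["e_total"], atol=1e-9)

    def test_monte_carlo_agrees_within_three_se(self):
        chain = stationary_chain(SEED + 2, mortality=0.08)
        init = uniform_init()
        analytic = hx.analytic_expectancies(chain, init, 60)
        sample = hx.simulate_trajectories(chain, init, 10_000, seed=SEED,
                                          max_attained_age=60)
        mc = hx.expectancies_from_sample(sample)
        ses = hx.expectancy_standard_errors(sample)
        for sex in SEXES:
            merged = mc.tables[sex].merge(ses[sex], on="age")
            merged = merged[merged["lx_x"] >= 100]
            an = analytic.tables[sex].iloc[merged["age"]]
            for j in list(range(1, 7)) + ["total"]:
                col = f"e{j}" if j != "total" else "e_total"
                secol = f"se{j}" if j != "total" else "se_total"
                z = np.abs(merged[col].to_numpy() - an[col].to_numpy()) \
                    / merged[secol].to_numpy()
                assert np.nanmax(z) < 3.0

    def test_survivors_nonincreasing(self, small_yearly, small_init):
        table = hx.analytic_expectancies(small_yearly, small_init)
        for sex in SEXES:
            lx = table.tables[sex]["lx"].to_numpy()
            assert (np.diff(lx) <= 1e-12).all()


class TestTrajectoryIO:
    def test_round_trip(self, small_yearly, small_init, tmp_path):
        sample = hx.simulate_trajectories(small_yearly, small_init, 100,
                                          seed=SEED)
        p = tmp_path / "traj.csv"
        hx.write_trajectories(sample, p)
        back = hx.read_trajectories(p)
        for sex in SEXES:
            a, b = sample.states(sex), back.states(sex)
            np.testing.assert_array_equal(a[:, :b.shape[1]], b)
            assert (a[:, b.shape[1]:] == 0).all()
            np.testing.assert_array_equal(sample.censored(sex),
                                          back.censored(sex))
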