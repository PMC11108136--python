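"""Life table, Sullivan HLE, multistate equivalence, printed comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import healthexp as hx
from healthexp.errors import ValidationError
from healthexp.reference import (hle_mms_series, hle_sullivan_series,
                                 old_age_le_overestimate)
from healthexp.states import SEXES
from healthexp.sullivan import SullivanInputs

from conftest import SEED, stationary_chain, uniform_init


def brute_force_ex(qx, terminal_m, ax=0.5):
    """Survival-product oracle for e_0 on a small table."""
    l = [1.0]
    for q in qx:
        l.append(l[-1] * (1 - q))
    person_years = sum(l[x + 1] + ax * (l[x] - l[x + 1])
                       for x in range(len(qx)))
    if terminal_m is not None:
        person_years += l[-1] / terminal_m
    return person_years


class TestBuildLifeTable:
    def test_no_deaths_before_terminal(self):
        lt = hx.build_life_table(SullivanInputs(qx=[0.0, 0.0], terminal_m=1.0))
        assert lt.ex[0] == pytest.approx(3.0)  # 2 closed ages + 1

    def test_certain_death_at_birth(self):
        lt = hx.build_life_table(SullivanInputs(qx=[1.0, 0.5], terminal_m=1.0))
        assert lt.ex[0] == pytest.approx(0.5)

    def test_radix_invariance(self):
        inputs = SullivanInputs(qx=[0.1, 0.2, 0.3], terminal_m=0.8)
        a = hx.build_life_table(inputs, radix=100_000)
        b = hx.build_life_table(inputs, radix=1)
        np.testing.assert_allclose(a.ex, b.ex, atol=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0.0, 0.9), min_size=1, max_size=8),
           st.floats(0.2, 2.0))
    def test_matches_survival_product_oracle(self, qx, terminal_m):
        lt = hx.build_life_table(SullivanInputs(qx=qx, terminal_m=terminal_m),
                                 radix=1)
        assert lt.ex[0] == pytest.approx(brute_force_ex(qx, terminal_m),
                                         abs=1e-12)

    def test_rejects_invalid_qx(self):
        with pytest.raises(ValidationError):
            SullivanInputs(qx=[0.5, 1.2], terminal_m=1.0)

    def test_rejects_zero_terminal_mortality(self):
        with pytest.raises(ValidationError, match="open"):
            SullivanInputs(qx=[0.1], terminal_m=0.0)


class TestSullivanHle:
    def toy_table(self):
        return hx.build_life_table(
            SullivanInputs(qx=[0.1, 0.2], terminal_m=1.0), radix=1)

    def test_saturation_pi_one(self):
        lt = self.toy_table()
        np.testing.assert_allclose(hx.sullivan_hle(lt, np.ones(3)), lt.ex,
                                   atol=1e-12)

    def test_annihilation_pi_zero(self):
        lt = self.toy_table()
        np.testing.assert_allclose(hx.sullivan_hle(lt, np.zeros(3)), 0.0)

    def test_toy_hand_summation(self):
        lt = self.toy_table()
        pi = np.array([1.0, 0.5, 0.0])
        # hand sum: pi_0 L_0 + 0.5 L_1 + 0
        expected = (pi * lt.Lx).sum() / lt.lx[0]
        assert hx.sullivan_hle(lt, pi)[0] == pytest.approx(expected, abs=1e-12)
        l1 = 0.9
        l2 = 0.9 * 0.8
        L0 = l1 + 0.5 * (1 - l1)
        L1 = l2 + 0.5 * (l1 - l2)
        assert hx.sullivan_hle(lt, pi)[0] == pytest.approx(
            (L0 + 0.5 * L1) / 1.0, abs=1e-12)

    def test_hle_bounded_by_le(self):
        lt = self.toy_table()
        rng = np.random.default_rng(SEED)
        pi = rng.uniform(0, 1, 3)
        hle = hx.sullivan_hle(lt, pi)
        assert (hle <= lt.ex + 1e-12).all() and (hle >= 0).all()

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2), st.floats(0.01, 0.5))
    def test_monotone_in_prevalence(self, y, bump):
        lt = self.toy_table()
        pi = np.array([0.4, 0.4, 0.4])
        base = hx.sullivan_hle(lt, pi)
        pi2 = pi.copy()
        pi2[y] = min(1.0, pi2[y] + bump)
        raised = hx.sullivan_hle(lt, pi2)
        assert (raised >= base - 1e-12).all()

    def test_rejects_pi_outside_unit_interval(self):
        with pytest.raises(ValidationError):
            hx.sullivan_hle(self.toy_table(), np.array([0.5, 1.3, 0.0]))


class TestConsistencyWithMultistate:
    def test_equivalence_on_randomized_stationary_chain(self):
        chain = stationary_chain(SEED + 3, mortality=0.12)
        report = hx.sullivan_consistency_check(chain, uniform_init(),
                                               max_attained_age=80)
        assert report["abs_difference"].max() < 1e-6

    def test_no_morbidity_chain_gives_hle_equal_le(self):
        # all mass stays in state 1 except mortality
        m = np.zeros((7, 7))
        m[:6, 0] = 0.9
        m[:6, 6] = 0.1
        m[6, 6] = 1.0
        chain = hx.TransitionMatrixSet("single_year", {
            (sex, 0): m for sex in SEXES})
        init = {sex: np.array([1.0, 0, 0, 0, 0, 0]) for sex in SEXES}
        table = hx.analytic_expectancies(chain, init, 60)
        report = hx.sullivan_consistency_check(chain, init, 60)
        for sex in SEXES:
            sub = report[report["sex"] == sex]
            np.testing.assert_allclose(
                sub["hle_sullivan"].to_numpy(),
                table.tables[sex]["e_total"].to_numpy(), atol=1e-9)

    def test_midyear_convention_creates_documented_gap(self):
        # a_x = 0.5 vs the whole-year engine: LE drops by about half the
        # death-year credit; reported, not asserted as equality
        chain = stationary_chain(SEED + 4, mortality=0.2)
        table = hx.analytic_expectancies(chain, uniform_init(), 60)
        df = table.tables["female"]
        lx = df["lx"].to_numpy()
        qx = np.clip(1.0 - lx[1:] / lx[:-1], 0, 1)
        lt = hx.build_life_table(SullivanInputs(qx=np.append(qx, 1.0)), ax=0.5)
        gap = df["e_total"].iloc[0] - lt.ex[0]
        assert 0.3 < gap < 0.7


class TestCompareHle:
    def test_printed_point_estimates_reproduce_differences(self):
        rows = hx.compare_hle(
            {("female", 65): 2.43, ("male", 65): 2.17},
            {("female", 65): 10.68, ("male", 65): 11.43},
            ages=[65])
        by_sex = rows.set_index("sex")["difference"]
        assert by_sex["female"] == pytest.approx(8.25)
        assert by_sex["male"] == pytest.approx(9.26)

    def test_packaged_reference_series_agree(self):
        for sex, expected in (("female", 8.25), ("male", 9.26)):
            mms = {(sex, a): v for a, v in hle_mms_series(sex).items()}
            sul = {(sex, a): v for a, v in hle_sullivan_series(sex).items()}
            rows = hx.compare_hle(mms, sul, ages=[65], sex=sex)
            assert rows["difference"].iloc[0] == pytest.approx(expected)

    def test_identical_inputs_give_zero_difference(self):
        rows = hx.compare_hle({("male", 0): 40.0}, {("male", 0): 40.0}, [0])
        assert rows["difference"].iloc[0] == 0.0

    def test_difference_is_exact_subtraction(self):
        rows = hx.compare_hle({("female", 0): 39.94}, {("female", 0): 66.08},
                              [0])
        assert rows["difference"].iloc[0] == 66.08 - 39.94

    def test_old_age_le_overestimate_from_printed_tables(self):
        assert old_age_le_overestimate(90) == pytest.approx(1.77, abs=0.005)

    def test_expectancy_table_input(self, small_yearly, small_init):
        table = hx.analytic_expectancies(small_yearly, small_init)
        sul = {a: v for a, v in hle_sullivan_series("female").items()}
        rows = hx.compare_hle(table, sul, ages=[0, 65])
        assert set(rows["sex"]) == set(SEXES)
        assert (rows["difference"]
                == rows["hle_sullivan"] - rows["hle_mms"]).all()
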