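"""Monte Carlo lifetime trajectories and their analytic counterpart.

Trajectories follow discrete annual cycles: a person starts at age 0 in
a state drawn from the initial (under-1) composition, and each year the
next state is drawn by inverse-CDF from the (sex, age) transition row,
with death absorbing.  A person alive at exact age x who dies during the
cycle is credited the full year in the state occupied at x (whole-year
accounting); lifetimes still running at ``max_attained_age`` are
censored and flagged.

``analytic_expectancies`` propagates the same chain deterministically —
state-occupancy vectors advanced by matrix products — and serves as the
exact oracle the stochastic engine must agree with.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expectancy import ExpectancyTable
from .matrices import TransitionMatrixSet
from .states import SEXES

logger = logging.getLogger(__name__)

DEFAULT_N_PER_SEX = 10_000
DEFAULT_MAX_ATTAINED_AGE = 110


def initial_state_distribution(records: pd.DataFrame) -> dict[str, np.ndarray]:
    """Empirical baseline state frequencies of the under-1 stratum, per sex.

    Reproduces the state composition newborn simulated individuals are
    assigned from.  Fails when a sex has no under-1 records, suggesting
    an explicit override vector instead.
    """
    out: dict[str, np.ndarray] = {}
    infants = records[records["age"] < 1]
    for sex in SEXES:
        sub = infants[infants["sex"] == sex]
        if len(sub) == 0:
            raise ValidationError(
                f"no under-1 {sex} records: supply an explicit override "
                f"vector for the initial state distribution instead")
        freq = np.bincount(sub["state_t"].to_numpy(), minlength=7)[1:7]
        out[sex] = freq / freq.sum()
    return out


def _validate_init(init: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    clean = {}
    for sex in SEXES:
        if sex not in init:
            raise ValidationError(f"initial distribution missing for {sex}")
        v = np.asarray(init[sex], dtype=float)
        if v.shape != (6,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"initial distribution for {sex} is not a probability "
                f"vector over states 1..6")
        clean[sex] = v
    return clean


@dataclass(frozen=True)
class Trajectory:
    """One simulated lifetime: states occupied at each age-year lived."""

    sex: str
    states: tuple[int, ...]
    age_at_death: "int | None"  # None = censored at max attained age

    def __post_init__(self) -> None:
        if any(s not in range(1, 7) for s in self.states):
            raise ValidationError("living states must be in 1..6")
        if self.age_at_death is not None and \
                self.age_at_death != len(self.states) - 1:
            raise ValidationError("age_at_death inconsistent with state sequence")

    @property
    def years_lived(self) -> int:
        return len(self.states)

    @property
    def censored(self) -> bool:
        return self.age_at_death is None


@dataclass
class TrajectorySample:
    """A cohort of simulated lifetimes, stored column-wise per sex.

    ``_states[sex]`` is an int8 array of shape (n, max_attained_age):
    entry (p, x) is the state person p occupied during age-year x, or 0
    once dead.
    """

    seed: "int | None"
    max_attained_age: int
    source: str = ""
    _states: dict[str, np.ndarray] = field(default_factory=dict)
    _censored: dict[str, np.ndarray] = field(default_factory=dict)

    def n(self, sex: str) -> int:
        return self._states[sex].shape[0]

    def states(self, sex: str) -> np.ndarray:
        return self._states[sex]

    def years(self, sex: str) -> np.ndarray:
        return (self._states[sex] != 0).sum(axis=1)

    def censored(self, sex: str) -> np.ndarray:
        return self._censored[sex]

    def person_years(self, sex: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (L, l): person-years by (age, state) and survivors by age."""
        s = self._states[sex]
        T = s.shape[1]
        L = np.stack([(s == j).sum(axis=0) for j in range(1, 7)], axis=1)
        lx = (s != 0).sum(axis=0)
        return L.astype(float), lx.astype(float)

    def trajectories(self, sex: str) -> Iterator[Trajectory]:
        years = self.years(sex)
        cens = self._censored[sex]
        for p in range(self.n(sex)):
            y = int(years[p])
            yield Trajectory(
                sex=sex,
                states=tuple(int(v) for v in self._states[sex][p, :y]),
                age_at_death=None if cens[p] else y - 1,
            )


def simulate_trajectories(
    yearly: TransitionMatrixSet,
    init: dict[str, np.ndarray],
    n_per_sex: int = DEFAULT_N_PER_SEX,
    seed: int = 0,
    max_attained_age: int = DEFAULT_MAX_ATTAINED_AGE,
) -> TrajectorySample:
    """Draw lifetime state trajectories from a single-year matrix set.

    One pseudo-random stream per sex (seeded ``seed`` for females,
    ``seed + 1`` for males); each trajectory consumes one initial-state
    uniform plus one uniform per potential year of life, so the sample
    is bit-reproducible for a given (matrix set, init, n, seed).  Ages
    beyond the matrix set's last age reuse its last matrix.  Inverse-CDF
    draws order states 1..7 with ties at cumulative boundaries resolved
    upward.
    """
    if yearly.index_kind != "single_year":
        raise ValidationError("simulation needs a single_year matrix set")
    init = _validate_init(init)
    if n_per_sex <= 0:
        raise ValidationError("n_per_sex must be positive")
    T = int(max_attained_age)
    sample = TrajectorySample(seed=seed, max_attained_age=T,
                              source=f"simulate_trajectories(n={n_per_sex})")
    for k, sex in enumerate(SEXES):
        ages_avail = yearly.age_indices(sex)
        if not ages_avail or ages_avail != list(range(ages_avail[-1] + 1)):
            raise ValidationError(f"matrix set has age gaps for {sex}")
        last = ages_avail[-1]
        cums = np.stack([np.cumsum(yearly.matrix(sex, a), axis=1)
                         for a in range(last + 1)])  # (ages, 7, 7)
        rng = np.random.default_rng(seed + k)
        u_init = rng.random(n_per_sex)
        u = rng.random((n_per_sex, T))
        init_cum = np.cumsum(init[sex])
        state = np.minimum((init_cum <= u_init[:, None]).sum(axis=1), 5) + 1
        states = np.zeros((n_per_sex, T), dtype=np.int8)
        alive = np.ones(n_per_sex, dtype=bool)
        for age in range(T):
            states[alive, age] = state[alive]
            rows = cums[min(age, last)][state[alive] - 1]  # (n_alive, 7)
            nxt = np.minimum((rows <= u[alive, age][:, None]).sum(axis=1), 6) + 1
            died = nxt == 7
            idx = np.flatnonzero(alive)
            state[idx[~died]] = nxt[~died]
            alive[idx[died]] = False
            if not alive.any():
                break
        sample._states[sex] = states
        sample._censored[sex] = alive.copy()
        frac = alive.mean()
        if frac > 0.01:
            warnings.warn(
                f"{frac:.1%} of {sex} trajectories censored at age {T}: "
                f"the tail closure of the matrix set is inadequate",
                stacklevel=2)
    return sample


def analytic_expectancies(
    yearly: TransitionMatrixSet,
    init: dict[str, np.ndarray],
    max_attained_age: int = DEFAULT_MAX_ATTAINED_AGE,
) -> ExpectancyTable:
    """Exact expected state occupancies of the simulated chain.

    Propagates the alive-state occupancy vector age by age through the
    living-to-living blocks of the transition matrices and converts the
    occupancy masses into expectancies; equals the Monte Carlo estimate
    in the infinite-sample limit under the same whole-year accounting
    and the same censoring horizon.
    """
    if yearly.index_kind != "single_year":
        raise ValidationError("analytic expectancies need a single_year set")
    init = _validate_init(init)
    T = int(max_attained_age)
    person_years = {}
    for sex in SEXES:
        ages_avail = yearly.age_indices(sex)
        last = ages_avail[-1]
        occ = np.zeros((T, 6))
        occ[0] = init[sex]
        for x in range(T - 1):
            m = yearly.matrix(sex, min(x, last))
            occ[x + 1] = occ[x] @ m[:6, :6]
        person_years[sex] = (occ, occ.sum(axis=1))
    return ExpectancyTable.from_person_years(
        person_years,
        metadata={"kind": "analytic", "max_attained_age": T},
        lx_floor=1e-12,
    )


# -- trajectory file format ---------------------------------------------

def write_trajectories(sample: TrajectorySample, path) -> None:
    """Write one row per person: sex, years lived, censoring flag and the
    run-length-encoded state sequence (``state x years`` segments)."""
    rows = []
    for sex in SEXES:
        if sex not in sample._states:
            continue
        for tr in sample.trajectories(sex):
            segments = []
            for s in tr.states:
                if segments and segments[-1][0] == s:
                    segments[-1][1] += 1
                else:
                    segments.append([s, 1])
            rows.append({
                "sex": sex,
                "years_lived": tr.years_lived,
                "censored": int(tr.censored),
                "states_rle": ";".join(f"{s}x{n}" for s, n in segments),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trajectories(path) -> TrajectorySample:
    df = pd.read_csv(Path(path))
    need = {"sex", "years_lived", "censored", "states_rle"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    T = int(df["years_lived"].max())
    sample = TrajectorySample(seed=None, max_attained_age=T,
                              source=str(path))
    for sex in SEXES:
        sub = df[df["sex"] == sex]
        if len(sub) == 0:
            continue
        states = np.zeros((len(sub), T), dtype=np.int8)
        for p, rle in enumerate(sub["states_rle"]):
            x = 0
            for seg in str(rle).split(";"):
                s, n = seg.split("x")
                s, n = int(s), int(n)
                if not 1 <= s <= 6:
                    raise ValidationError(f"{path}: invalid state {s} in row {p}")
                states[p, x:x + n] = s
                x += n
        sample._states[sex] = states
        sample._censored[sex] = sub["censored"].to_numpy().astype(bool)
    return sample
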