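"""Health-state scheme, age groups and individual observation records.

The model tracks six morbidity states derived from Clinical Risk Groups
(CRG) health statuses, plus death as an absorbing seventh state:

1. Healthy
2. Significant acute disease
3. Minor chronic disease
4. Significant chronic disease in one or two organ systems
5. Significant chronic disease in three or more organ systems —
   Catastrophic conditions
6. Dominant and metastatic malignancies
7. Death (absorbing)

The population is stratified by sex and ten age groups (``<1``, ``1-14``,
``15-24`` ... ``>=85``); transition probabilities estimated per group are
attributed to a midpoint age ("group-centred") for later interpolation to
single years of age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ValidationError

#: State codes.
HEALTHY = 1
DEATH = 7
N_STATES = 7
LIVING_STATES = tuple(range(1, 7))

STATE_LABELS: tuple[str, ...] = (
    "Healthy",
    "Significant acute disease",
    "Minor chronic disease",
    "Significant chronic disease in one or two organ systems",
    "Significant chronic disease in three or more organ systems - "
    "Catastrophic conditions",
    "Dominant and metastatic malignancies",
    "Death",
)

SEXES: tuple[str, str] = ("female", "male")

#: Default cross-walk from the nine raw CRG health statuses to the six
#: aggregated states.  The two most severe non-malignant categories
#: (dominant chronic disease in 3+ organ systems; catastrophic
#: conditions) fold into the composite state 5; dominant and metastatic
#: malignancies stand alone as state 6.
CRG9_TO_STATE6: Mapping[int, int] = {
    1: 1, 2: 2, 3: 3, 4: 3, 5: 4, 6: 4, 7: 5, 9: 5, 8: 6,
}


def aggregate_crg_status(crg9: int, mapping: Mapping[int, int] = CRG9_TO_STATE6) -> int:
    """Aggregate a raw 9-category CRG health status to the 6-state scheme.

    Parameters
    ----------
    crg9
        Raw CRG health-status category, 1..9.
    mapping
        Alternative cross-walk; must be total on 1..9 with values in 1..6.

    Returns
    -------
    int
        Aggregated health-state code in 1..6.
    """
    try:
        key = int(crg9)
        if key != crg9:
            raise ValueError
    except (TypeError, ValueError):
        raise ValidationError(f"CRG status must be an integer 1..9, got {crg9!r}")
    if key not in mapping:
        raise ValidationError(f"CRG status {key} outside the valid range 1..9")
    return mapping[key]


@dataclass(frozen=True)
class AgeGroupScheme:
    """Half-open integer age intervals and their representative midpoints.

    ``lower_bounds[k]`` is the inclusive lower bound of group ``k``; the
    last group is open-ended.  ``midpoints`` are the ages the
    group-centred transition matrices are attributed to.
    """

    lower_bounds: tuple[int, ...] = (0, 1, 15, 25, 35, 45, 55, 65, 75, 85)
    midpoints: tuple[float, ...] = (0.5, 8.0, 20.0, 30.0, 40.0, 50.0,
                                    60.0, 70.0, 80.0, 90.0)

    def __post_init__(self) -> None:
        lb = self.lower_bounds
        mp = self.midpoints
        if len(lb) != len(mp):
            raise ValidationError("one midpoint per age group required")
        if list(lb) != sorted(set(lb)) or lb[0] != 0:
            raise ValidationError("lower bounds must be strictly increasing from 0")
        if list(mp) != sorted(set(mp)):
            raise ValidationError("midpoints must be strictly increasing")
        for k, m in enumerate(mp):
            lo = lb[k]
            hi = lb[k + 1] if k + 1 < len(lb) else np.inf
            if not (lo <= m) or (k + 1 < len(lb) and not m < hi):
                raise ValidationError(
                    f"midpoint {m} outside its group [{lo}, {hi})"
                )

    @property
    def n_groups(self) -> int:
        return len(self.lower_bounds)

    def group_of(self, age) -> "int | np.ndarray":
        """Map integer age(s) to their 0-based age-group index."""
        ages = np.asarray(age)
        if np.any(ages < 0):
            raise ValidationError("ages must be nonnegative")
        idx = np.searchsorted(np.asarray(self.lower_bounds), ages, side="right") - 1
        return int(idx) if np.isscalar(age) else idx

    def labels(self) -> list[str]:
        out = []
        for k, lo in enumerate(self.lower_bounds):
            if k + 1 < self.n_groups:
                out.append(f"[{lo},{self.lower_bounds[k + 1]})")
            else:
                out.append(f"[{lo},inf)")
        return out

    def ages_in_group(self, k: int, max_age: int = 120) -> range:
        lo = self.lower_bounds[k]
        hi = self.lower_bounds[k + 1] if k + 1 < self.n_groups else max_age + 1
        return range(lo, hi)


DEFAULT_SCHEME = AgeGroupScheme()


@dataclass(frozen=True)
class IndividualRecord:
    """One person's paired-year observation.

    ``state_t`` is the health state at baseline (never death: the
    baseline roster only contains people alive with a morbidity record);
    ``state_t1`` is the state, or death, one year later.
    """

    person_id: str
    sex: str
    age: int
    state_t: int
    state_t1: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")
        if self.state_t not in LIVING_STATES:
            raise ValidationError(
                f"baseline state must be in 1..6, got {self.state_t}"
            )
        if self.state_t1 not in range(1, N_STATES + 1):
            raise ValidationError(
                f"follow-up state must be in 1..7, got {self.state_t1}"
            )


RECORD_COLUMNS = ("person_id", "sex", "age", "state_t", "state_t1")


def records_frame(records: Iterable[IndividualRecord]):
    """Build the canonical records DataFrame from ``IndividualRecord``s."""
    import pandas as pd

    rows = [(r.person_id, r.sex, r.age, r.state_t, r.state_t1) for r in records]
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def validate_records_frame(df, warn_duplicates: bool = True):
    """Validate a records DataFrame in place; raise on violation."""
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"records table missing columns: {sorted(missing)}")
    if len(df) == 0:
        return df
    if not df["sex"].isin(SEXES).all():
        bad = df.loc[~df["sex"].isin(SEXES), "sex"].unique()
        raise ValidationError(f"invalid sex values: {list(bad)}")
    if (df["age"] < 0).any():
        raise ValidationError("negative ages present")
    if not df["state_t"].isin(LIVING_STATES).all():
        raise ValidationError("baseline states outside 1..6 present")
    if not df["state_t1"].isin(range(1, N_STATES + 1)).all():
        raise ValidationError("follow-up states outside 1..7 present")
    if warn_duplicates and df["person_id"].duplicated().any():
        n = int(df["person_id"].duplicated().sum())
        warnings.warn(f"{n} duplicate person_id rows; all rows are counted",
                      stacklevel=2)
    return df
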