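"""Maximum-likelihood estimation of group-centred transition matrices.

With stationary annual dynamics, the MLE of the probability of moving
from living state i to state j within one year, for a given sex and age
group, is the observed count ratio

    p_hat_ij = s_ij / s_i

where ``s_ij`` counts persons in state i at baseline and state j at
follow-up, and ``s_i = sum_j s_ij`` is the baseline exposure of state i.
The default ten-group scheme over two sexes yields 20 matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrices import ABSORBING_ROW, TransitionMatrixSet
from .states import AgeGroupScheme, DEFAULT_SCHEME, SEXES, validate_records_frame

logger = logging.getLogger(__name__)

DEFAULT_MIN_CELL = 30


@dataclass
class TransitionCounts:
    """Observed transition counts ``s_ij`` per (sex, age group).

    ``s_ij[sex]`` has shape (n_groups, 6, 7): baseline living state i by
    follow-up state j.  ``s_i`` is the row-sum exposure.
    """

    scheme: AgeGroupScheme
    s_ij: dict[str, np.ndarray]

    def s_i(self, sex: str) -> np.ndarray:
        return self.s_ij[sex].sum(axis=2)

    def total(self) -> int:
        return int(sum(a.sum() for a in self.s_ij.values()))


def count_transitions(records: pd.DataFrame,
                      scheme: AgeGroupScheme = DEFAULT_SCHEME) -> TransitionCounts:
    """Tally each record into its (sex, baseline-age group, i, j) cell.

    Duplicate person_ids are all counted (with a warning from
    validation); the age group is assigned from the baseline age.
    """
    validate_records_frame(records)
    s_ij = {sex: np.zeros((scheme.n_groups, 6, 7), dtype=np.int64)
            for sex in SEXES}
    if len(records) == 0:
        return TransitionCounts(scheme=scheme, s_ij=s_ij)
    groups = scheme.group_of(records["age"].to_numpy())
    for sex in SEXES:
        sel = (records["sex"] == sex).to_numpy()
        np.add.at(
            s_ij[sex],
            (groups[sel],
             records["state_t"].to_numpy()[sel] - 1,
             records["state_t1"].to_numpy()[sel] - 1),
            1,
        )
    return TransitionCounts(scheme=scheme, s_ij=s_ij)


@dataclass
class EstimationDiagnostics:
    """Cell-level warnings produced alongside the estimated matrices."""

    low_exposure: list[tuple[str, int, int, int]] = field(default_factory=list)
    #: rows with zero exposure, with the policy applied: (sex, group, state, policy detail)
    zero_exposure: list[tuple[str, int, int, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": s, "group": g, "state": i, "exposure": n, "issue": "low_exposure"}
            for s, g, i, n in self.low_exposure
        ] + [
            {"sex": s, "group": g, "state": i, "exposure": 0,
             "issue": f"zero_exposure:{detail}"}
            for s, g, i, detail in self.zero_exposure
        ]
        return pd.DataFrame(rows,
                            columns=["sex", "group", "state", "exposure", "issue"])


def estimate_group_matrices(
    counts: TransitionCounts,
    min_cell: int = DEFAULT_MIN_CELL,
    zero_exposure_policy: str = "borrow_nearest",
) -> tuple[TransitionMatrixSet, EstimationDiagnostics]:
    """Estimate the age-group matrix set from transition counts.

    Rows with positive exposure are the count-ratio MLE.  Rows with zero
    exposure cannot be estimated and are filled by policy — either
    ``"borrow_nearest"`` (copy the estimated row of the nearest age group
    with exposure for the same sex and state; default, keeps downstream
    splines well defined) or ``"identity"`` (stay put with certainty,
    zero mortality).  Every filled row and every row with exposure below
    ``min_cell`` is listed in the diagnostics; nothing is silent.
    """
    if zero_exposure_policy not in ("borrow_nearest", "identity"):
        raise ValidationError(
            f"unknown zero-exposure policy {zero_exposure_policy!r}")
    scheme = counts.scheme
    diags = EstimationDiagnostics()
    matrices: dict[tuple[str, int], np.ndarray] = {}
    for sex in SEXES:
        sij = counts.s_ij[sex].astype(float)
        si = counts.s_i(sex).astype(float)
        rows = np.full((scheme.n_groups, 6, 7), np.nan)
        np.divide(sij, si[:, :, None], out=rows, where=si[:, :, None] > 0)
        for g in range(scheme.n_groups):
            for i in range(6):
                n = int(si[g, i])
                if n == 0:
                    rows[g, i] = _fill_zero_exposure(
                        rows, si, sex, g, i, zero_exposure_policy, diags)
                elif n < min_cell:
                    diags.low_exposure.append((sex, g, i + 1, n))
        for g in range(scheme.n_groups):
            m = np.vstack([rows[g], ABSORBING_ROW])
            matrices[(sex, g)] = m
    mset = TransitionMatrixSet(index_kind="age_group", matrices=matrices)
    for s, g, i, n in diags.low_exposure:
        logger.warning("low exposure: sex=%s group=%d state=%d n=%d < %d",
                       s, g, i, n, min_cell)
    for s, g, i, d in diags.zero_exposure:
        logger.warning("zero exposure: sex=%s group=%d state=%d -> %s",
                       s, g, i, d)
    return mset, diags


def _fill_zero_exposure(rows, si, sex, g, i, policy, diags) -> np.ndarray:
    if policy == "identity":
        row = np.zeros(7)
        row[i] = 1.0
        diags.zero_exposure.append((sex, g, i + 1, "identity"))
        return row
    # borrow_nearest: nearest group (by index distance, ties to younger)
    # with exposure for the same state
    candidates = [h for h in range(si.shape[0]) if si[h, i] > 0]
    if not candidates:
        row = np.zeros(7)
        row[i] = 1.0
        diags.zero_exposure.append(
            (sex, g, i + 1, "identity (no group has exposure)"))
        return row
    h = min(candidates, key=lambda h: (abs(h - g), h))
    diags.zero_exposure.append((sex, g, i + 1, f"borrowed from group {h}"))
    return rows[h, i]
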