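"""Expansion of group-centred matrices to single-year-of-age matrices.

Each transition probability is treated as a smooth function of age: a
natural cubic spline is fit entrywise through the group matrices placed
at their group midpoints, then evaluated at integer ages.  The infant
group (<1 year) is excluded from the fit — its matrix is carried over
verbatim for age 0, since infant dynamics do not lie on the adult age
gradient.  Interpolated rows are clipped to [0, 1] and renormalized to
restore row-stochasticity; the death row is forced absorbing.

Ages above the last midpoint reuse the last-midpoint value (constant
tail closure).  This deliberately flattens old-age mortality, which
inflates simulated life expectancy at the highest ages; a steeper
closure can be supplied via ``tail_mortality_inflation``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import StageError, ValidationError
from .matrices import ABSORBING_ROW, TransitionMatrixSet
from .states import AgeGroupScheme, DEFAULT_SCHEME, SEXES

logger = logging.getLogger(__name__)

DEFAULT_MAX_AGE = 90
RENORM_LOG_TOL = 1e-3


def extrapolation_policy(age: float, scheme: AgeGroupScheme = DEFAULT_SCHEME) -> float:
    """Age at which the spline is evaluated for a requested age.

    Ages beyond the last group midpoint evaluate at the last midpoint
    (constant extrapolation); ages below it, including those under the
    first interior midpoint, evaluate at themselves — the natural
    boundary of the spline handles them.
    """
    if age < 0:
        raise ValidationError(f"age must be nonnegative, got {age}")
    return float(min(age, scheme.midpoints[-1]))


def interpolate_yearly(
    groups: TransitionMatrixSet,
    scheme: AgeGroupScheme = DEFAULT_SCHEME,
    max_age: int = DEFAULT_MAX_AGE,
    tail_mortality_inflation: float = 0.0,
) -> TransitionMatrixSet:
    """Interpolate an age-group matrix set to single years of age 0..max_age.

    Returns ``max_age + 1`` matrices per sex (182 in total for the
    default two-sex, max_age=90 configuration).

    ``tail_mortality_inflation`` optionally multiplies the annual death
    probability by ``(1 + rate)**(age - last_midpoint)`` beyond the last
    midpoint (rows renormalized); the default 0 keeps the constant tail.
    """
    if groups.index_kind != "age_group":
        raise ValidationError("input matrix set must be of age_group kind")
    if max_age < scheme.midpoints[-1]:
        raise ValidationError(
            f"max_age {max_age} is below the last group midpoint "
            f"{scheme.midpoints[-1]}")
    for sex in SEXES:
        for g in range(scheme.n_groups):
            if (sex, g) not in groups.matrices:
                raise ValidationError(f"missing group matrix ({sex}, {g})")

    knots = np.asarray(scheme.midpoints[1:])  # infant group excluded
    out: dict[tuple[str, int], np.ndarray] = {}
    for sex in SEXES:
        # age 0: infant-group matrix verbatim
        out[(sex, 0)] = groups.matrix(sex, 0).copy()
        values = np.stack([groups.matrix(sex, g)[:6]
                           for g in range(1, scheme.n_groups)])  # (9, 6, 7)
        spline = CubicSpline(knots, values, axis=0, bc_type="natural")
        ages = np.arange(1, max_age + 1)
        eval_ages = np.array([extrapolation_policy(a, scheme) for a in ages])
        raw = spline(eval_ages)  # (n_ages, 6, 7)
        clipped = np.clip(raw, 0.0, 1.0)
        if tail_mortality_inflation > 0.0:
            over = eval_ages < ages  # ages past the constant-tail pivot
            factor = (1.0 + tail_mortality_inflation) ** (ages - eval_ages)
            q = clipped[:, :, 6] * np.where(over, factor, 1.0)[:, None]
            clipped[:, :, 6] = np.minimum(q, 1.0)
        sums = clipped.sum(axis=2)
        dev = np.abs(raw.sum(axis=2) - 1.0)
        for n, age in enumerate(ages):
            if np.any(sums[n] <= 0.0):
                i = int(np.argmax(sums[n] <= 0.0)) + 1
                raise StageError(
                    f"interpolated row has zero total mass: sex={sex} "
                    f"age={age} state={i}")
            if tail_mortality_inflation == 0.0 and np.any(dev[n] > RENORM_LOG_TOL):
                i = int(np.argmax(dev[n] > RENORM_LOG_TOL)) + 1
                logger.info(
                    "renormalizing sex=%s age=%d state=%d (row sum off by %.2g)",
                    sex, age, dev[n][i - 1])
            m = np.vstack([clipped[n] / sums[n][:, None], ABSORBING_ROW])
            out[(sex, int(age))] = m
    return TransitionMatrixSet(index_kind="single_year", matrices=out)
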