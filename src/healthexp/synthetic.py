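"""Synthetic two-year population panels with known transition dynamics.

The study population this emulates is a general mixed-age population
(~88k people) observed at two consecutive year-ends, each person carrying
a morbidity state at baseline and a state-or-death at follow-up.  The
generator draws such a panel from explicit ground-truth age-group
transition matrices, so that every downstream stage (estimation,
interpolation, simulation) can be checked against a known answer —
a parameter-recovery harness standing in for the non-public registry.

Fixture choices (age pyramid, state mix by age, mortality schedule) are
plausible for a southern-European county population; they are documented
defaults, not claims about the real registry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .matrices import ABSORBING_ROW, TransitionMatrixSet
from .states import AgeGroupScheme, DEFAULT_SCHEME, RECORD_COLUMNS, SEXES

#: Size of the emulated study population at scale 1.
STUDY_POPULATION = 87_850

# Plausible share of the total population in each of the ten age groups
# (sums to 1) and the female fraction within each group.
_GROUP_SHARES = (0.008, 0.140, 0.095, 0.110, 0.160, 0.150,
                 0.125, 0.105, 0.075, 0.032)
_FEMALE_FRACTION = (0.49, 0.49, 0.49, 0.49, 0.50, 0.50,
                    0.50, 0.52, 0.55, 0.62)

# Baseline probability of being healthy, by age group; the remainder is
# spread over states 2..6 with severity weights that shift with age.
_HEALTHY_SHARE = (0.95, 0.90, 0.82, 0.72, 0.60, 0.48, 0.36, 0.25, 0.16, 0.10)

# Annual baseline death probability by age group (before sex and
# state-severity multipliers): low in childhood, rising steeply after 75.
_BASE_Q = (0.0025, 0.0001, 0.0003, 0.0005, 0.0009,
           0.0020, 0.0050, 0.0130, 0.0350, 0.1300)
_SEX_Q_FACTOR = {"female": 0.8, "male": 1.25}
#: Death-probability multiplier per living state (severity gradient).
_STATE_Q_FACTOR = (0.6, 1.0, 0.9, 1.6, 3.0, 6.0)


@dataclass
class PopulationSpec:
    """Full description of a synthetic two-year panel.

    ``counts`` maps (sex, age-group index) to the number of persons;
    ``baseline_state_mix`` maps the same key to a probability vector over
    states 1..6; ``truth`` holds the generating age-group transition
    matrices; ``seed`` fixes the pseudo-random stream.
    """

    counts: dict[tuple[str, int], int]
    baseline_state_mix: dict[tuple[str, int], np.ndarray]
    truth: TransitionMatrixSet
    seed: int = 0
    scheme: AgeGroupScheme = field(default_factory=AgeGroupScheme)

    def __post_init__(self) -> None:
        if self.truth.index_kind != "age_group":
            raise ValidationError("truth matrices must be of age_group kind")
        for key, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"negative count for {key}")
            if key not in self.baseline_state_mix:
                raise ValidationError(f"no baseline state mix for {key}")
            if key not in self.truth.matrices:
                raise ValidationError(f"no truth matrix for {key}")
        for key, mix in self.baseline_state_mix.items():
            mix = np.asarray(mix, dtype=float)
            if mix.shape != (6,) or np.any(mix < 0) or \
                    abs(mix.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"baseline state mix for {key} is not a probability "
                    f"vector over states 1..6"
                )
            self.baseline_state_mix[key] = mix

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "age_group_lower_bounds": list(self.scheme.lower_bounds),
            "age_group_midpoints": list(self.scheme.midpoints),
            "counts": [
                {"sex": s, "group": g, "n": int(n)}
                for (s, g), n in sorted(self.counts.items())
            ],
            "baseline_state_mix": [
                {"sex": s, "group": g, "mix": [float(x) for x in v]}
                for (s, g), v in sorted(self.baseline_state_mix.items())
            ],
            "truth": [
                {"sex": s, "group": g, "matrix": m.tolist()}
                for (s, g), m in sorted(self.truth.matrices.items())
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PopulationSpec":
        scheme = AgeGroupScheme(
            lower_bounds=tuple(doc["age_group_lower_bounds"]),
            midpoints=tuple(doc["age_group_midpoints"]),
        )
        counts = {(e["sex"], int(e["group"])): int(e["n"])
                  for e in doc["counts"]}
        mix = {(e["sex"], int(e["group"])): np.asarray(e["mix"], dtype=float)
               for e in doc["baseline_state_mix"]}
        truth = TransitionMatrixSet(
            index_kind="age_group",
            matrices={(e["sex"], int(e["group"])): np.asarray(e["matrix"],
                                                             dtype=float)
                      for e in doc["truth"]},
        )
        return cls(counts=counts, baseline_state_mix=mix, truth=truth,
                   seed=int(doc.get("seed", 0)), scheme=scheme)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PopulationSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _severity_weights(group: int, n_groups: int) -> np.ndarray:
    """Weights for spreading non-healthy mass over states 2..6."""
    a = group / (n_groups - 1)  # 0 young .. 1 old
    w = np.array([
        0.55 - 0.35 * a,          # significant acute
        0.30 - 0.05 * a,          # minor chronic
        0.10 + 0.25 * a,          # significant chronic, 1-2 organ systems
        0.03 + 0.12 * a,          # significant chronic 3+ / catastrophic
        0.02 + 0.03 * a,          # malignancies
    ])
    return w / w.sum()


def _truth_row(state: int, group: int, n_groups: int, sex: str) -> np.ndarray:
    """One ground-truth transition row for a living state."""
    a = group / (n_groups - 1)
    q = min(0.9, _BASE_Q[group] * _SEX_Q_FACTOR[sex] * _STATE_Q_FACTOR[state - 1])
    moves = {
        1: {2: 0.05, 3: 0.03 + 0.07 * a, 4: 0.02 * a},
        2: {1: 0.55 - 0.20 * a, 3: 0.10 + 0.10 * a, 4: 0.05 * a},
        3: {1: 0.08 * (1 - a), 2: 0.02, 4: 0.08 + 0.12 * a},
        4: {2: 0.01, 3: 0.03 * (1 - a), 5: 0.05 + 0.10 * a},
        5: {4: 0.02 * (1 - a), 6: 0.02},
        6: {4: 0.05 * (1 - a), 5: 0.02},
    }[state]
    row = np.zeros(7)
    for j, p in moves.items():
        row[j - 1] = p
    row[6] = q
    stay = 1.0 - row.sum()
    if stay < 0:  # pragma: no cover - defensive; defaults never trigger it
        row[:6] *= (1.0 - q) / row[:6].sum()
        stay = 0.0
    row[state - 1] = stay
    return row


def study_like_truth(scheme: AgeGroupScheme = DEFAULT_SCHEME) -> TransitionMatrixSet:
    """Ground-truth age-group matrices with age-graded morbidity dynamics."""
    matrices: dict[tuple[str, int], np.ndarray] = {}
    for sex in SEXES:
        for g in range(scheme.n_groups):
            m = np.empty((7, 7))
            for i in range(1, 7):
                m[i - 1] = _truth_row(i, g, scheme.n_groups, sex)
            m[6] = ABSORBING_ROW
            matrices[(sex, g)] = m
    return TransitionMatrixSet(index_kind="age_group", matrices=matrices)


def default_study_like_spec(scale: float = 1.0, seed: int = 0) -> PopulationSpec:
    """A documented population spec sized like the emulated study.

    Total count is about ``scale`` x 87,850, with a realistic age/sex
    pyramid, morbidity prevalence rising with age and annual mortality
    rising steeply after 75.  Deterministic: two calls with the same
    arguments return identical specs.
    """
    if scale <= 0:
        raise ValidationError(f"scale must be positive, got {scale}")
    scheme = DEFAULT_SCHEME
    counts: dict[tuple[str, int], int] = {}
    mix: dict[tuple[str, int], np.ndarray] = {}
    for g in range(scheme.n_groups):
        group_total = scale * STUDY_POPULATION * _GROUP_SHARES[g]
        for sex in SEXES:
            frac = _FEMALE_FRACTION[g] if sex == "female" else 1 - _FEMALE_FRACTION[g]
            counts[(sex, g)] = int(round(group_total * frac))
            healthy = _HEALTHY_SHARE[g]
            v = np.empty(6)
            v[0] = healthy
            v[1:] = (1.0 - healthy) * _severity_weights(g, scheme.n_groups)
            mix[(sex, g)] = v / v.sum()
    return PopulationSpec(counts=counts, baseline_state_mix=mix,
                          truth=study_like_truth(scheme), seed=seed)


def generate_panel(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a two-year individual panel from a :class:`PopulationSpec`.

    For each person: baseline age uniform over the integer ages of their
    group (the open-ended last group is truncated at 100 for age
    assignment), baseline state from the group's state mix, follow-up
    state from the matching row of the truth matrix.  One seeded stream
    drives the whole panel; identical (spec, seed) give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.total == 0:
        warnings.warn("population spec has zero total count; empty panel",
                      stacklevel=2)
        return pd.DataFrame(columns=list(RECORD_COLUMNS))

    frames = []
    offset = 0
    for (sex, g) in sorted(spec.counts):
        n = spec.counts[(sex, g)]
        if n == 0:
            continue
        ages_avail = np.asarray(
            spec.scheme.ages_in_group(g, max_age=100), dtype=int)
        ages = ages_avail[rng.integers(0, len(ages_avail), size=n)]
        mix = spec.baseline_state_mix[(sex, g)]
        state_t = 1 + _inverse_cdf(np.cumsum(mix), rng.random(n))
        truth = spec.truth.matrix(sex, g)
        cum = np.cumsum(truth, axis=1)
        state_t1 = 1 + _inverse_cdf(cum[state_t - 1], rng.random(n))
        frames.append(pd.DataFrame({
            "person_id": np.char.add("p", np.arange(offset, offset + n).astype(str)),
            "sex": sex,
            "age": ages,
            "state_t": state_t,
            "state_t1": state_t1,
        }))
        offset += n
    return pd.concat(frames, ignore_index=True)


def _inverse_cdf(cum: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Index of the first cumulative bin strictly above ``u`` (ties go up)."""
    if cum.ndim == 1:
        cum = np.broadcast_to(cum, (len(u), len(cum)))
    idx = (cum <= u[:, None]).sum(axis=1)
    return np.minimum(idx, cum.shape[1] - 1)
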