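"""Row-stochastic annual transition matrices indexed by sex and age.

A :class:`TransitionMatrixSet` holds one 7x7 matrix per (sex, age index):
rows condition on the state at the start of the year, columns give the
state one year later, with death (state 7) absorbing.  ``index_kind``
distinguishes the group-centred sets (age index = age-group number) from
the interpolated single-year-of-age sets (age index = integer age).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .states import DEATH, N_STATES, SEXES, STATE_LABELS

ROW_SUM_TOL = 1e-9

#: The absorbing death row: once dead, always dead.
ABSORBING_ROW = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0])


def validate_matrix(m: np.ndarray, where: str = "") -> np.ndarray:
    m = np.asarray(m, dtype=float)
    tag = f" in {where}" if where else ""
    if m.shape != (N_STATES, N_STATES):
        raise ValidationError(f"matrix{tag} must be 7x7, got {m.shape}")
    if np.any(m < -0.0) or np.any(m > 1.0) or not np.all(np.isfinite(m)):
        raise ValidationError(f"matrix{tag} has entries outside [0, 1]")
    sums = m.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]
    if bad.size:
        i = int(bad[0])
        raise ValidationError(
            f"matrix{tag}: row {i + 1} sums to {sums[i]:.6g}, expected 1"
        )
    if not np.array_equal(m[DEATH - 1], ABSORBING_ROW):
        raise ValidationError(f"matrix{tag}: death row must be absorbing")
    return m


@dataclass
class TransitionMatrixSet:
    """Annual transition matrices keyed by ``(sex, age_index)``."""

    index_kind: str  # "age_group" | "single_year"
    matrices: dict[tuple[str, int], np.ndarray]
    state_labels: tuple[str, ...] = STATE_LABELS

    def __post_init__(self) -> None:
        if self.index_kind not in ("age_group", "single_year"):
            raise ValidationError(
                f"index_kind must be 'age_group' or 'single_year', "
                f"got {self.index_kind!r}"
            )
        for (sex, idx), m in self.matrices.items():
            if sex not in SEXES:
                raise ValidationError(f"unknown sex {sex!r} in matrix set")
            self.matrices[(sex, idx)] = validate_matrix(m, f"({sex}, {idx})")

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(s for s in SEXES if any(k[0] == s for k in self.matrices))

    def age_indices(self, sex: str) -> list[int]:
        return sorted(i for s, i in self.matrices if s == sex)

    def matrix(self, sex: str, age_index: int) -> np.ndarray:
        return self.matrices[(sex, age_index)]

    def __len__(self) -> int:
        return len(self.matrices)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TransitionMatrixSet):
            return NotImplemented
        return (
            self.index_kind == other.index_kind
            and self.matrices.keys() == other.matrices.keys()
            and all(np.array_equal(self.matrices[k], other.matrices[k])
                    for k in self.matrices)
        )


def write_matrix_set(mset: TransitionMatrixSet, path) -> None:
    """Serialize a matrix set as self-describing JSON.

    Floats are written with ``repr`` round-trip precision, so a
    write→read cycle reproduces every entry bit-exactly.
    """
    doc = {
        "format": "healthexp-transition-matrices",
        "index_kind": mset.index_kind,
        "states": list(mset.state_labels),
        "entries": [
            {"sex": sex, "age_index": idx, "matrix": m.tolist()}
            for (sex, idx), m in sorted(mset.matrices.items())
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_matrix_set(path) -> TransitionMatrixSet:
    """Read a matrix set written by :func:`write_matrix_set`."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("index_kind", "states", "entries"):
        if key not in doc:
            raise ValidationError(f"{path}: missing field {key!r}")
    matrices: dict[tuple[str, int], np.ndarray] = {}
    for n, entry in enumerate(doc["entries"]):
        try:
            sex = entry["sex"]
            idx = int(entry["age_index"])
            m = np.array(entry["matrix"], dtype=float)
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: malformed entry {n}: {exc}") from exc
        matrices[(sex, idx)] = validate_matrix(m, f"{path} entry {n} ({sex}, {idx})")
    return TransitionMatrixSet(
        index_kind=doc["index_kind"],
        matrices=matrices,
        state_labels=tuple(doc["states"]),
    )
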