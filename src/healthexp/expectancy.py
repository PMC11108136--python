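"""Expectancy tables: LE and state-specific health expectancies.

The standard demographic formula converts person-years into remaining
expectancies: with ``L_{y,j}`` the person-years lived at age y in state
j and ``l_x`` the survivors at exact age x,

    e_{x,j} = sum_{y >= x} L_{y,j} / l_x

The total life expectancy is ``e_x = sum_j e_{x,j}`` (the states
partition the person-years), and the healthy life expectancy series
HLE-MMS is ``e_{x,1}`` — expectancy in the Healthy state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .states import SEXES

logger = logging.getLogger(__name__)

STATE_COLS = [f"e{j}" for j in range(1, 7)]
PY_COLS = [f"L{j}" for j in range(1, 7)]


@dataclass
class ExpectancyTable:
    """Per-sex expectancy tables.

    Each table has one row per exact age x with survivors ``lx``,
    person-years ``L1..L6`` at age x by state, state expectancies
    ``e1..e6``, and the total ``e_total``; rows stop at the last age
    with survivors.
    """

    tables: dict[str, pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_person_years(
        cls,
        person_years: dict[str, tuple[np.ndarray, np.ndarray]],
        metadata: "dict | None" = None,
        lx_floor: float = 0.0,
    ) -> "ExpectancyTable":
        """Build tables from (L, l) arrays per sex.

        ``L`` has shape (ages, 6); ``l`` has shape (ages,).  Ages with
        ``l_x <= lx_floor`` terminate the table (no survivors to
        condition on); if any are dropped this is noted in the metadata.
        """
        tables = {}
        meta = dict(metadata or {})
        for sex, (L, lx) in person_years.items():
            L = np.asarray(L, dtype=float)
            lx = np.asarray(lx, dtype=float)
            alive = lx > lx_floor
            n_ages = int(np.argmax(~alive)) if not alive.all() else len(lx)
            if n_ages < len(lx) and alive[n_ages:].any():
                raise ValidationError(f"survivors l_x not nonincreasing for {sex}")
            if n_ages < len(lx):
                meta.setdefault("truncated_at", {})[sex] = n_ages
            rem = np.cumsum(L[::-1], axis=0)[::-1]  # sum_{y>=x} L_{y,j}
            e = rem[:n_ages] / lx[:n_ages, None]
            df = pd.DataFrame({"age": np.arange(n_ages), "lx": lx[:n_ages]})
            for j in range(6):
                df[PY_COLS[j]] = L[:n_ages, j]
            for j in range(6):
                df[STATE_COLS[j]] = e[:, j]
            df["e_total"] = e.sum(axis=1)
            tables[sex] = df
        return cls(tables=tables, metadata=meta)

    def at(self, sex: str, age: int) -> pd.Series:
        df = self.tables[sex]
        row = df[df["age"] == age]
        if len(row) == 0:
            raise KeyError(f"age {age} beyond table for {sex}")
        return row.iloc[0]

    def expectancy(self, sex: str, age: int, state: "int | None" = None) -> float:
        row = self.at(sex, age)
        return float(row["e_total"] if state is None else row[f"e{state}"])

    def hle(self, sex: str) -> pd.Series:
        """Healthy life expectancy series (expectancy in state 1) by age."""
        df = self.tables[sex]
        return pd.Series(df["e1"].to_numpy(), index=df["age"].to_numpy(),
                         name="hle")


def expectancies_from_sample(sample) -> ExpectancyTable:
    """Expectancy tables from a simulated :class:`TrajectorySample`.

    ``l_x`` counts trajectories still alive during age-year x; censored
    trajectories contribute person-years up to censoring only, and their
    number is recorded in the metadata (downward bias at the highest
    ages rather than imputation).
    """
    person_years = {}
    meta = {"kind": "monte_carlo", "n": {}, "n_censored": {}}
    for sex in SEXES:
        try:
            L, lx = sample.person_years(sex)
        except KeyError:
            continue
        if sample.n(sex) == 0:
            raise ValidationError(f"empty trajectory sample for {sex}")
        person_years[sex] = (L, lx)
        meta["n"][sex] = int(sample.n(sex))
        meta["n_censored"][sex] = int(sample.censored(sex).sum())
    if not person_years:
        raise ValidationError("trajectory sample is empty")
    meta["seed"] = sample.seed
    meta["source"] = sample.source
    return ExpectancyTable.from_person_years(person_years, metadata=meta)


def expectancy_standard_errors(sample) -> dict[str, pd.DataFrame]:
    """Monte Carlo standard errors of ``e_{x,j}`` and ``e_x``.

    For each person alive at exact age x, the remaining years in state j
    is a bounded random variable whose sample mean is the estimator; the
    standard error is its sample standard deviation over the survivors
    divided by sqrt(l_x).
    """
    out = {}
    for sex in SEXES:
        try:
            states = sample.states(sex)
        except KeyError:
            continue
        n, T = states.shape
        alive = states != 0
        lx = alive.sum(axis=0)
        n_ages = int(np.argmax(lx == 0)) if (lx == 0).any() else T
        cols = {"age": np.arange(n_ages), "lx": lx[:n_ages]}
        rem_total = np.zeros((n, n_ages))
        for j in range(1, 7):
            rem = np.cumsum((states == j)[:, ::-1], axis=1)[:, ::-1][:, :n_ages]
            rem_total += rem
            cols[f"se{j}"] = _conditional_se(rem, alive[:, :n_ages], lx[:n_ages])
        cols["se_total"] = _conditional_se(rem_total, alive[:, :n_ages],
                                           lx[:n_ages])
        out[sex] = pd.DataFrame(cols)
    return out


def _conditional_se(rem: np.ndarray, alive: np.ndarray, lx: np.ndarray) -> np.ndarray:
    se = np.full(rem.shape[1], np.nan)
    for x in range(rem.shape[1]):
        vals = rem[alive[:, x], x]
        if len(vals) > 1:
            se[x] = vals.std(ddof=1) / np.sqrt(len(vals))
    return se


DEFAULT_REPORT_AGES = (0, 65)
DECADAL_AGES = tuple(range(0, 91, 10))


def expectancy_report(
    table: ExpectancyTable,
    ages=DEFAULT_REPORT_AGES,
    csv_path=None,
    figure_path=None,
) -> pd.DataFrame:
    """Tabulate e_x and e_{x,j} at requested ages; optionally plot.

    Ages beyond a sex's table are omitted with a warning.  The figure is
    a stacked-area chart of the state-specific expectancies over age,
    one panel per sex.
    """
    rows = []
    for sex in table.tables:
        for age in ages:
            try:
                r = table.at(sex, age)
            except KeyError:
                logger.warning("age %d beyond expectancy table for %s; omitted",
                               age, sex)
                continue
            rows.append({"sex": sex, "age": age,
                         **{c: r[c] for c in STATE_COLS},
                         "e_total": r["e_total"]})
    report = pd.DataFrame(rows, columns=["sex", "age", *STATE_COLS, "e_total"])
    if csv_path is not None:
        report.to_csv(csv_path, index=False)
    if figure_path is not None:
        _stacked_area_figure(table, figure_path)
    return report


def _stacked_area_figure(table: ExpectancyTable, path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "healthexp"
    sexes = list(table.tables)
    fig, axes = plt.subplots(1, len(sexes), figsize=(6 * len(sexes), 4),
                             squeeze=False)
    for ax, sex in zip(axes[0], sexes):
        df = table.tables[sex]
        ax.stackplot(df["age"], *[df[c] for c in STATE_COLS],
                     labels=[f"state {j}" for j in range(1, 7)])
        ax.set_title(f"Health expectancies by state — {sex}")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("remaining years")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
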