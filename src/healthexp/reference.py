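"""Packaged published reference values used by comparison reports.

These are transcriptions of published government and study estimates for
Catalonia, 2017: the survey-based Sullivan HLE series
(with standard errors), official life-expectancy tables from two
government sources alongside the multistate-microsimulation (MMS)
results, and the MMS point estimates at birth and 65.  They are report
inputs only — nothing in the estimation pipeline reads them.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

_DATA = resources.files(__package__) / "data"


def catalonia_hle_sullivan_2017() -> pd.DataFrame:
    """Survey-based Sullivan HLE for Catalonia 2017, by age and sex."""
    with (_DATA / "hle_sullivan_catalonia_2017.csv").open() as fh:
        return pd.read_csv(fh)


def hle_sullivan_series(sex: str) -> dict[int, float]:
    """Sullivan HLE as an ``age -> years`` mapping for one sex."""
    df = catalonia_hle_sullivan_2017()
    return dict(zip(df["age"].astype(int), df[f"{sex}_hle"]))


def le_mms_vs_official_2017() -> pd.DataFrame:
    """Decadal LE: multistate-model estimates vs two official sources."""
    with (_DATA / "le_mms_vs_official_2017.csv").open() as fh:
        return pd.read_csv(fh)


def mms_point_estimates() -> dict:
    """Published MMS point estimates: HLE and LE at birth and at 65."""
    return json.loads((_DATA / "mms_point_estimates.json").read_text())


def hle_mms_series(sex: str) -> dict[int, float]:
    """Published MMS healthy-life-expectancy points for one sex."""
    est = mms_point_estimates()["hle_mms"][sex]
    return {int(a): v for a, v in est.items()}


def old_age_le_overestimate(age: int = 90) -> float:
    """MMS total LE minus the mean official total LE at the given age.

    Quantifies the constant-tail closure bias of the interpolated
    matrices at the highest ages (about +1.77 years at 90).
    """
    df = le_mms_vs_official_2017().set_index("age")
    row = df.loc[age]
    official = (row["catalonia_total"] + row["spain_total"]) / 2.0
    return float(row["mms_total"] - official)
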