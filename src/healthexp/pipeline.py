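"""End-to-end pipeline: records → matrices → trajectories → expectancies.

A :class:`RunConfig` names the inputs and knobs of every stage; the
pipeline then runs estimate → interpolate → simulate → expectancies
(→ Sullivan comparison when inputs are given), writing each stage's
artifact plus a provenance record (config hash, seed, package version)
so any stage can be re-run in isolation.  Identical configs produce
bit-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import StageError, ValidationError
from .estimation import DEFAULT_MIN_CELL, count_transitions, estimate_group_matrices
from .expectancy import (DEFAULT_REPORT_AGES, expectancies_from_sample,
                         expectancy_report)
from .interpolation import DEFAULT_MAX_AGE, interpolate_yearly
from .io import read_records, write_records
from .matrices import write_matrix_set
from .simulation import (DEFAULT_MAX_ATTAINED_AGE, DEFAULT_N_PER_SEX,
                         initial_state_distribution, simulate_trajectories,
                         write_trajectories)
from .states import AgeGroupScheme, SEXES
from .sullivan import compare_hle
from .synthetic import PopulationSpec, default_study_like_spec, generate_panel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``records_path`` (an existing records CSV) or
    ``synthetic_scale`` / ``synthetic_spec_path`` (generate the panel)
    must be provided.
    """

    out_dir: str = "healthexp_run"
    records_path: "str | None" = None
    synthetic_scale: "float | None" = None
    synthetic_spec_path: "str | None" = None
    seed: int = 0
    n_per_sex: int = DEFAULT_N_PER_SEX
    max_age: int = DEFAULT_MAX_AGE
    max_attained_age: int = DEFAULT_MAX_ATTAINED_AGE
    min_cell: int = DEFAULT_MIN_CELL
    zero_exposure_policy: str = "borrow_nearest"
    report_ages: tuple[int, ...] = DEFAULT_REPORT_AGES
    figure_format: str = "svg"
    age_group_lower_bounds: "tuple[int, ...] | None" = None
    age_group_midpoints: "tuple[float, ...] | None" = None
    sullivan_path: "str | None" = None  # CSV: age,sex,qx,pi or published series

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("report_ages", "age_group_lower_bounds", "age_group_midpoints"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def scheme(self) -> AgeGroupScheme:
        kwargs = {}
        if self.age_group_lower_bounds is not None:
            kwargs["lower_bounds"] = tuple(self.age_group_lower_bounds)
        if self.age_group_midpoints is not None:
            kwargs["midpoints"] = tuple(self.age_group_midpoints)
        return AgeGroupScheme(**kwargs)

    def digest(self) -> str:
        doc = asdict(self)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()

    def validate(self) -> None:
        sources = [self.records_path, self.synthetic_scale,
                   self.synthetic_spec_path]
        if all(s is None for s in sources):
            raise ValidationError(
                "config must name a records file, a synthetic spec, or a "
                "synthetic scale")
        if self.records_path is not None and not Path(self.records_path).exists():
            raise ValidationError(f"records file not found: {self.records_path}")
        if self.synthetic_spec_path is not None and \
                not Path(self.synthetic_spec_path).exists():
            raise ValidationError(
                f"synthetic spec not found: {self.synthetic_spec_path}")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the paths of every artifact.

    Stage failures raise :class:`StageError` naming the stage; artifacts
    already written are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = config.scheme()
    artifacts: dict[str, Path] = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("records")
        if config.records_path is not None:
            records, _ = read_records(config.records_path)
        else:
            if config.synthetic_spec_path is not None:
                spec = PopulationSpec.from_yaml(config.synthetic_spec_path)
            else:
                spec = default_study_like_spec(config.synthetic_scale,
                                               seed=config.seed)
            records = generate_panel(spec)
            artifacts["records"] = out / "records.csv"
            write_records(records, artifacts["records"])
    except ValidationError:
        raise
    except Exception as exc:
        raise StageError(f"records stage failed: {exc}") from exc

    try:
        stage("estimate")
        counts = count_transitions(records, scheme)
        groups, diags = estimate_group_matrices(
            counts, min_cell=config.min_cell,
            zero_exposure_policy=config.zero_exposure_policy)
        artifacts["group_matrices"] = out / "group_matrices.json"
        write_matrix_set(groups, artifacts["group_matrices"])
        artifacts["diagnostics"] = out / "estimation_diagnostics.csv"
        diags.to_frame().to_csv(artifacts["diagnostics"], index=False)
    except Exception as exc:
        raise StageError(f"estimate stage failed: {exc}") from exc

    try:
        stage("interpolate")
        yearly = interpolate_yearly(groups, scheme, max_age=config.max_age)
        artifacts["yearly_matrices"] = out / "yearly_matrices.json"
        write_matrix_set(yearly, artifacts["yearly_matrices"])
    except Exception as exc:
        raise StageError(f"interpolate stage failed: {exc}") from exc

    try:
        stage("simulate")
        init = initial_state_distribution(records)
        sample = simulate_trajectories(
            yearly, init, n_per_sex=config.n_per_sex, seed=config.seed,
            max_attained_age=config.max_attained_age)
        artifacts["trajectories"] = out / "trajectories.csv"
        write_trajectories(sample, artifacts["trajectories"])
    except Exception as exc:
        raise StageError(f"simulate stage failed: {exc}") from exc

    try:
        stage("expectancies")
        table = expectancies_from_sample(sample)
        for sex in table.tables:
            p = out / f"expectancy_{sex}.csv"
            table.tables[sex].to_csv(p, index=False)
            artifacts[f"expectancy_{sex}"] = p
        artifacts["report"] = out / "expectancy_report.csv"
        artifacts["figure"] = out / f"expectancies.{config.figure_format}"
        expectancy_report(table, ages=config.report_ages,
                          csv_path=artifacts["report"],
                          figure_path=artifacts["figure"])
    except Exception as exc:
        raise StageError(f"expectancies stage failed: {exc}") from exc

    if config.sullivan_path is not None:
        try:
            stage("compare")
            sul = pd.read_csv(config.sullivan_path)
            series = {(r["sex"], int(r["age"])): float(r["hle"])
                      for _, r in sul.iterrows()}
            ages = sorted({a for _, a in series})
            comparison = compare_hle(table, series, ages)
            artifacts["comparison"] = out / "hle_comparison.csv"
            comparison.to_csv(artifacts["comparison"], index=False)
        except Exception as exc:
            raise StageError(f"compare stage failed: {exc}") from exc

    provenance = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "config_sha256": config.digest(),
        "seed": config.seed,
        "package_version": _version(),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "n_records": int(len(records)),
        "censored": {s: int(sample.censored(s).sum()) for s in SEXES
                     if s in sample._states},
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=1, sort_keys=True))
    artifacts["provenance"] = prov_path
    return artifacts


def _version() -> str:
    from . import __version__
    return __version__
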