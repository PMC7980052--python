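"""End-to-end pipeline: simulate -> classify -> build cohort -> analyze.

A run is driven by one :class:`PipelineConfig` (YAML-serializable); the
effective configuration is written next to the outputs so any run can be
reproduced exactly.  The global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([global_seed, stage_index])`` so a stage can be
rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, classify, cohort, simulate
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "build-cohort", "analyze")


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    ss = np.random.SeedSequence([int(global_seed), int(stage_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Everything a full run needs; absent fields take these defaults."""

    out_dir: str = "alcodoc_run"
    seed: int = 0
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    rules_dir: str | None = None        # None -> packaged rules
    policy: str = "most-recent"
    age_cut: float | None = None
    provider_age_cut: float | None = None
    unknown_counts_as_documented: bool = True
    working_correlation: str = "exchangeable"
    log_level: str = "INFO"

    def validate(self) -> None:
        self.sim.validate()
        if self.policy not in classify.POLICIES:
            raise ConfigurationError(f"unknown policy {self.policy!r}")
        if self.working_correlation not in ("exchangeable", "independence"):
            raise ConfigurationError(
                f"unknown working correlation {self.working_correlation!r}")
        if self.rules_dir is not None and not Path(self.rules_dir).is_dir():
            raise ConfigurationError(
                f"rules directory {self.rules_dir!r} does not exist")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["date_window"] = list(d["sim"]["date_window"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim_d = dict(d.pop("sim", {}))
        if "date_window" in sim_d:
            sim_d["date_window"] = tuple(sim_d["date_window"])
        known_sim = {f.name for f in dataclasses.fields(simulate.SimConfig)}
        bad = set(sim_d) - known_sim
        if bad:
            raise ConfigurationError(f"unknown sim config keys: {sorted(bad)}")
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        return cls(sim=simulate.SimConfig(**sim_d), **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _setup_logging(out: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(out / "run.log", mode="w",
                                  encoding="utf-8")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("alcodoc")
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    root.addHandler(handler)
    return handler


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory.

    Each stage's outputs are written before the next starts.  On failure a
    ``FAILED`` marker naming the stage is left in the artifact directory and
    the error propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out, config.log_level)
    stage = STAGES[0]
    try:
        sim_cfg = dataclasses.replace(config.sim,
                                      seed=stage_seed(config.seed, 0))
        extract = simulate.simulate_extract(sim_cfg)
        simulate.write_extract(extract, out)
        logger.info("simulate: %d patients, %d encounters, %d notes",
                    len(extract.patients), len(extract.encounters),
                    len(extract.riskfactor))

        stage = STAGES[1]
        rules = classify.load_rules(config.rules_dir)
        classified = classify.classify_table(extract.riskfactor, rules,
                                             policy=config.policy)
        _write_csv(classified, out / "classified.csv")
        logger.info("classify: %d patients classified", len(classified))

        stage = STAGES[2]
        cohort_df = cohort.assemble_cohort(
            _datestr(extract.patients, "birth_date"),
            _datestr(extract.encounters, "date"),
            extract.conditions,
            _datestr(extract.providers, "birth_date"),
            classified,
            window=config.sim.date_window,
            age_cut=config.age_cut,
            provider_age_cut=config.provider_age_cut,
            unknown_counts_as_documented=config.unknown_counts_as_documented)
        _write_csv(cohort_df, out / "cohort.csv")
        logger.info("build-cohort: %d rows", len(cohort_df))

        stage = STAGES[3]
        prev = analysis.prevalence_table(cohort_df)
        bivs = [analysis.bivariate_compare(cohort_df, v)
                for v in analysis.BIVARIATE_VARIABLES]
        models = [
            analysis.fit_documentation_model(
                cohort_df, working_correlation=config.working_correlation),
            analysis.fit_risk_model(
                cohort_df, working_correlation=config.working_correlation),
        ]
        analysis.report(prev, bivs, models, out)
        logger.info("analyze: prevalence + %d bivariates + %d models",
                    len(bivs), len(models))

        config.to_yaml(out / "config.yaml")
        failed = out / "FAILED"
        if failed.exists():
            failed.unlink()
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n",
                                    encoding="utf-8")
        logger.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        logging.getLogger("alcodoc").removeHandler(handler)
        handler.close()


def _datestr(df: pd.DataFrame, col: str) -> pd.DataFrame:
    df = df.copy()
    df[col] = df[col].dt.strftime("%Y-%m-%d")
    return df


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\r\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Extract validation

_REQUIRED_COLUMNS = {
    "patients.csv": ("patient_id", "provider_id", "sex", "birth_date",
                     "cma_population"),
    "providers.csv": ("provider_id", "sex", "birth_date", "provider_type"),
    "encounters.csv": ("encounter_id", "patient_id", "provider_id", "date"),
    "conditions.csv": ("patient_id", "condition"),
    "riskfactor.csv": ("patient_id", "date", "text"),
}
_DATE_COLUMNS = {
    "patients.csv": ("birth_date",),
    "providers.csv": ("birth_date",),
    "encounters.csv": ("date",),
    "riskfactor.csv": ("date",),
}
_ISO_DATE = r"^\d{4}-\d{2}-\d{2}$"


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "extract valid: 0 violations"
        return "\n".join(f"VIOLATION: {v}" for v in self.violations)


def validate_extract(extract_dir) -> ValidationReport:
    """Schema, foreign-key, date-format and truth-invariant checks."""
    root = Path(extract_dir)
    if not root.is_dir():
        raise DataError(f"extract directory {extract_dir!r} does not exist")
    violations: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    for name, cols in _REQUIRED_COLUMNS.items():
        path = root / name
        if not path.is_file():
            violations.append(f"{name}: file missing")
            continue
        df = pd.read_csv(path, dtype=str)
        tables[name] = df
        missing = set(cols) - set(df.columns)
        if missing:
            violations.append(f"{name}: missing columns {sorted(missing)}")

    def ids(name: str, col: str) -> set:
        df = tables.get(name)
        if df is None or col not in df.columns:
            return set()
        return set(df[col].dropna())

    fks = [
        ("encounters.csv", "patient_id", "patients.csv"),
        ("encounters.csv", "provider_id", "providers.csv"),
        ("patients.csv", "provider_id", "providers.csv"),
        ("conditions.csv", "patient_id", "patients.csv"),
        ("riskfactor.csv", "patient_id", "patients.csv"),
    ]
    parents = {"patients.csv": ids("patients.csv", "patient_id"),
               "providers.csv": ids("providers.csv", "provider_id")}
    for child, col, parent in fks:
        df = tables.get(child)
        if df is None or col not in df.columns or not parents[parent]:
            continue
        orphan = ~df[col].isin(parents[parent])
        if orphan.any():
            violations.append(
                f"{child}.{col}: {int(orphan.sum())} unresolved foreign keys")

    for name, cols in _DATE_COLUMNS.items():
        df = tables.get(name)
        if df is None:
            continue
        for col in cols:
            if col not in df.columns:
                continue
            bad = ~df[col].fillna("").str.match(_ISO_DATE)
            if bad.any():
                violations.append(
                    f"{name}.{col}: {int(bad.sum())} malformed dates")

    truth_path = root / "truth.csv"
    if truth_path.is_file():
        truth = pd.read_csv(truth_path, dtype={"patient_id": str})
        if {"documented", "rendered_text"} <= set(truth.columns):
            doc = truth["documented"].astype(str).str.lower().eq("true")
            text = truth["rendered_text"].fillna("").astype(str).str.len() > 0
            n_bad = int((doc != text).sum())
            if n_bad:
                violations.append(
                    f"truth.csv: {n_bad} rows violate documented <-> "
                    "non-empty text")

    return ValidationReport(tuple(violations))
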