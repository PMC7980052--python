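"""Synthetic CPCSSN-like EMR extract generator with known ground truth.

Emulates the five relational tables a primary-care alcohol-documentation
analysis touches (patients, providers, encounters, health-condition flags,
risk-factor free text) plus a truth table, so the classifier, cohort builder
and models can be validated end to end without any real extract.

Generative model (minimal structure sufficient for the downstream marginal
logistic models to be well specified):

* covariates are drawn independently per patient (sex, age, urban residence,
  eight chronic-condition flags); encounter counts per calendar year are
  overdispersed (negative binomial);
* whether alcohol is documented follows a logistic model in the derived
  binary covariates, with the intercept solved numerically so the realized
  marginal matches ``p_document_base``;
* conditional on documentation, a note is unclassifiable (UNKNOWN) with the
  mix's unknown share, independent of covariates; among classifiable notes a
  heightened-risk indicator (heavy or past drinker) follows a second logistic
  model (with age entering per year), again intercept-calibrated, and the
  remaining mass is split across NONE/LIGHT/MODERATE in mix proportion;
* each documented patient receives one rendered free-text note dated at their
  last in-window encounter.

Default marginals and effect sizes are calibrated to a national
primary-care cohort of 700,620 adults in which 40.6% had alcohol
documentation, 43.6% of classified records were light consumption and 4.7%
indicated heightened risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from . import classify as _cl
from .errors import ConfigurationError, EmptyExtractError, TemplateError

# --------------------------------------------------------------------------
# Defaults (marginals and adjusted effects of the reference cohort)

#: Category mix conditional on documentation, including the unclassified
#: share 13,992 / 284,268.
DEFAULT_CATEGORY_MIX: Mapping[str, float] = {
    _cl.NONE: 57_712 / 284_268,
    _cl.LIGHT: 117_779 / 284_268,
    _cl.MODERATE: 82_178 / 284_268,
    _cl.HEAVY: 8_088 / 284_268,
    _cl.PAST: 4_519 / 284_268,
    _cl.UNKNOWN: 13_992 / 284_268,
}

#: Adjusted log-odds of having alcohol documentation (documentation model).
DEFAULT_DOC_EFFECTS: Mapping[str, float] = {
    "male": math.log(1.09),
    "age_over_mean": math.log(1.26),
    "rural": math.log(1.00),
    "high_visits": math.log(1.11),
    "depression": math.log(1.11),
    "diabetes": math.log(0.95),
    "hypertension": math.log(1.07),
    "osteoarthritis": math.log(1.01),
    "provider_male": math.log(0.90),
    "provider_age_over_mean": math.log(1.09),
}

#: Adjusted log-odds of heightened risk (heavy/past) among classified patients.
DEFAULT_RISK_EFFECTS: Mapping[str, float] = {
    "male": math.log(3.27),
    "age_per_year": math.log(1.01),
    "rural": math.log(1.35),
    "high_visits": math.log(1.23),
    "depression": math.log(2.01),
    "diabetes": math.log(0.83),
    "hypertension": math.log(1.24),
    "osteoarthritis": math.log(1.04),
}

#: Marginal prevalence of each chronic-condition flag.
DEFAULT_COMORBIDITY_PREVALENCES: Mapping[str, float] = {
    "copd": 0.0394,
    "dementia": 0.0167,
    "hypertension": 0.2382,
    "depression": 0.1845,
    "diabetes": 0.1107,
    "epilepsy": 0.0121,
    "parkinsons": 0.0035,
    "osteoarthritis": 0.1370,
}

EXTRACT_FILES = ("patients.csv", "providers.csv", "encounters.csv",
                 "conditions.csv", "riskfactor.csv", "truth.csv")


@dataclass
class SimConfig:
    """Full parameterization of the synthetic extract.

    ``doc_logit_effects`` / ``risk_logit_effects`` map covariate names to
    log-odds increments; ``category_mix`` is the 6-category distribution
    conditional on documentation and must sum to 1.
    """

    n_patients: int = 10_000
    n_providers: int = 50
    seed: int = 0
    p_document_base: float = 0.406
    doc_logit_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_DOC_EFFECTS))
    category_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    risk_logit_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_RISK_EFFECTS))
    date_window: tuple = ("2015-01-01", "2018-01-01")
    visit_rate: float = 4.9
    visit_dispersion: float = 0.85
    comorbidity_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCES))
    text_noise_rate: float = 0.0
    p_male: float = 300_700 / 700_620
    p_urban: float = 592_274 / 700_620
    age_mean: float = 50.7
    age_sd: float = 17.5
    p_provider_male: float = 0.50
    provider_age_mean: float = 49.6
    provider_age_sd: float = 11.0
    p_provider_fp: float = 0.994
    provider_concentration: float = 50.0
    provider_intercept_sd: float = 0.0
    p_population_missing: float = 0.0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be non-negative")
        if self.n_providers < 1:
            raise ConfigurationError("n_providers must be >= 1")
        probs = {
            "p_document_base": self.p_document_base,
            "text_noise_rate": self.text_noise_rate,
            "p_male": self.p_male, "p_urban": self.p_urban,
            "p_provider_male": self.p_provider_male,
            "p_provider_fp": self.p_provider_fp,
            "p_population_missing": self.p_population_missing,
            **{f"prev[{k}]": v
               for k, v in self.comorbidity_prevalences.items()},
            **{f"mix[{k}]": v for k, v in self.category_mix.items()},
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if set(self.category_mix) != set(_cl.CATEGORIES):
            raise ConfigurationError(
                "category_mix must cover exactly the six categories")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(
                f"category_mix sums to {total!r}, expected 1")
        if self.visit_rate <= 0 or self.visit_dispersion <= 0:
            raise ConfigurationError("visit_rate and dispersion must be > 0")
        start, end = pd.Timestamp(self.date_window[0]), pd.Timestamp(
            self.date_window[1])
        if not start < end:
            raise ConfigurationError("date_window must satisfy start < end")


@dataclass(frozen=True)
class SimulatedExtract:
    """The five analysis tables plus per-patient ground truth."""

    patients: pd.DataFrame
    providers: pd.DataFrame
    encounters: pd.DataFrame
    conditions: pd.DataFrame
    riskfactor: pd.DataFrame
    truth: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "patients.csv": self.patients,
            "providers.csv": self.providers,
            "encounters.csv": self.encounters,
            "conditions.csv": self.conditions,
            "riskfactor.csv": self.riskfactor,
            "truth.csv": self.truth,
        }


# --------------------------------------------------------------------------
# Note templates.  These are an invention of this package: the source
# repository's full keyword list is not public, so templates are seeded from
# the category definitions and the four printed past-use phrases.

_WEEKLY_TEMPLATES = (
    "{q} drinks per week",
    "{q} drinks a week",
    "{q} drinks/week",
    "etoh {q}/wk",
    "alcohol - {q} drinks weekly",
    "about {q} drinks a week",
    "{q} beers per week",
)
_WORD_TEMPLATES = (
    "{w} drinks a week",
    "{w} drinks per week",
)
_DAILY_TEMPLATES = (
    "{d} drinks a day",
    "{d} beers daily",
)
_NONE_TEMPLATES = (
    "non-drinker",
    "denies alcohol use",
    "never drinks alcohol",
    "no etoh",
    "does not drink",
    "0 drinks per week",
    "denies etoh",
    "abstinent from alcohol",
)
_PAST_TEMPLATES = (
    "recovering alcoholic",
    "attends alcoholics anonymous",
    "past drinker",
    "recovered alcoholic",
    "quit drinking 3 years ago",
    "past heavy use, now sober",
    "in recovery from alcohol",
)
_UNKNOWN_TEMPLATES = (
    "father was an alcoholic",
    "family history of alcoholism",
    "drinks socially",
    "social drinker",
    "alcohol use discussed",
    "fh etoh abuse",
    "mother drinks heavily",
)
NOISE_TEMPLATES = (
    "etoh",
    "alcohol",
    "see chart",
    "rf updated",
    "?",
)

_WORD_FOR = {v: k for k, v in _cl._NUM_WORDS.items()}


def _check_band(category: str, q: float | None) -> None:
    if category in (_cl.PAST, _cl.UNKNOWN):
        if q is not None:
            raise TemplateError(f"{category} takes no quantity, got {q}")
        return
    if category == _cl.NONE:
        if q not in (None, 0, 0.0):
            raise TemplateError(f"NONE requires quantity 0, got {q}")
        return
    if q is None:
        raise TemplateError(f"{category} requires a quantity")
    ok = ((category == _cl.LIGHT and 0 < q < _cl.LIGHT_UPPER)
          or (category == _cl.MODERATE
              and _cl.LIGHT_UPPER <= q <= _cl.MODERATE_UPPER)
          or (category == _cl.HEAVY and q > _cl.MODERATE_UPPER))
    if not ok:
        raise TemplateError(f"{q} drinks/week outside the {category} band")


def render_note(category: str, quantity_per_week: float | None = None,
                rng: np.random.Generator | None = None) -> str:
    """Render one clean free-text note for a category.

    Quantified categories require a weekly quantity inside their band;
    rendering is such that :func:`alcodoc.classify.classify_note` with the
    default rules recovers the input category exactly.
    """
    rng = rng if rng is not None else np.random.default_rng()
    _check_band(category, quantity_per_week)
    if category == _cl.NONE:
        pool = _NONE_TEMPLATES
    elif category == _cl.PAST:
        pool = _PAST_TEMPLATES
    elif category == _cl.UNKNOWN:
        pool = _UNKNOWN_TEMPLATES
    else:
        q = quantity_per_week
        q_txt = str(int(q)) if float(q).is_integer() else f"{q:g}"
        pool = [t.format(q=q_txt) for t in _WEEKLY_TEMPLATES]
        if float(q).is_integer() and int(q) in _WORD_FOR:
            pool += [t.format(w=_WORD_FOR[int(q)]) for t in _WORD_TEMPLATES]
        if float(q).is_integer() and q > 0 and int(q) % 7 == 0:
            pool += [t.format(d=int(q) // 7) for t in _DAILY_TEMPLATES]
    return pool[int(rng.integers(len(pool)))]


# --------------------------------------------------------------------------
# Extract simulation

def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept b0 with mean(expit(b0 + eta)) == target on the realized eta."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    return brentq(lambda b0: expit(b0 + eta).mean() - target, -35.0, 35.0,
                  xtol=1e-12)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_extract(config: SimConfig) -> SimulatedExtract:
    """Generate the full multi-table extract for ``config``.

    Deterministic: the same config (including seed) yields byte-identical
    tables.
    """
    config.validate()
    n = config.n_patients
    if n == 0:
        raise EmptyExtractError("n_patients is 0; nothing to simulate")
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.date_window[0])
    end = pd.Timestamp(config.date_window[1])

    # ---- providers -------------------------------------------------------
    n_prov = config.n_providers
    prov_ids = np.array([f"D{i:04d}" for i in range(n_prov)])
    prov_male = rng.random(n_prov) < config.p_provider_male
    prov_age = _truncnorm(rng, config.provider_age_mean,
                          config.provider_age_sd, 25.0, 80.0, n_prov)
    prov_birth = end.to_datetime64() - (
        np.round(prov_age * 365.25).astype("int64")
    ).astype("timedelta64[D]")
    prov_fp = rng.random(n_prov) < config.p_provider_fp
    providers = pd.DataFrame({
        "provider_id": prov_ids,
        "sex": np.where(prov_male, "M", "F"),
        "birth_date": pd.to_datetime(prov_birth),
        "provider_type": np.where(prov_fp, "FP", "NP"),
    })

    # ---- patient covariates ---------------------------------------------
    weights = rng.dirichlet(np.full(n_prov, config.provider_concentration))
    prov_idx = rng.choice(n_prov, size=n, p=weights)
    pat_ids = np.array([f"P{i:07d}" for i in range(n)])
    male = rng.random(n) < config.p_male
    age = _truncnorm(rng, config.age_mean, config.age_sd, 18.0, 100.0, n)
    urban = rng.random(n) < config.p_urban
    pop = np.where(
        urban,
        np.round(100_000 * np.exp(rng.exponential(1.0, n))),
        rng.integers(200, 100_000, n).astype(float),
    )
    pop[rng.random(n) < config.p_population_missing] = np.nan
    comorb = {c: rng.random(n) < p
              for c, p in config.comorbidity_prevalences.items()}

    # ---- encounters ------------------------------------------------------
    years = np.arange(start.year, (end - pd.Timedelta(days=1)).year + 1)
    m, k = config.visit_rate, config.visit_dispersion
    counts = rng.negative_binomial(k, k / (k + m), size=(len(years), n))
    empty = counts.sum(axis=0) == 0
    if empty.any():  # guarantee >= 1 in-window encounter per patient
        counts[rng.integers(0, len(years), int(empty.sum())),
               np.nonzero(empty)[0]] = 1
    total = int(counts.sum())
    year_idx = np.repeat(np.tile(years, n) - start.year,
                         counts.T.reshape(-1))
    pat_row = np.repeat(np.arange(n), counts.sum(axis=0))
    year_starts = np.array([np.datetime64(f"{y}-01-01") for y in years])
    year_days = np.array(
        [(np.datetime64(f"{y + 1}-01-01") - np.datetime64(f"{y}-01-01"))
         .astype(int) for y in years])
    offsets = np.floor(rng.random(total) * year_days[year_idx]).astype("int64")
    dates = year_starts[year_idx] + offsets.astype("timedelta64[D]")
    encounters = pd.DataFrame({
        "encounter_id": [f"E{i:08d}" for i in range(total)],
        "patient_id": pat_ids[pat_row],
        "provider_id": prov_ids[prov_idx[pat_row]],
        "date": pd.to_datetime(dates),
    })

    last_enc = np.full(n, np.datetime64("1900-01-01"), dtype="datetime64[D]")
    np.maximum.at(last_enc, pat_row, dates)
    birth = last_enc - np.round(age * 365.25).astype("int64").astype(
        "timedelta64[D]")

    visits_median = np.median(counts, axis=0)
    high_visits = visits_median > 3

    # ---- documentation model --------------------------------------------
    age_cut = age.mean()
    prov_age_cut = prov_age[prov_idx].mean()
    covariates = {
        "male": male.astype(float),
        "age_over_mean": (age > age_cut).astype(float),
        "rural": (~urban).astype(float),
        "high_visits": high_visits.astype(float),
        "provider_male": prov_male[prov_idx].astype(float),
        "provider_age_over_mean":
            (prov_age[prov_idx] > prov_age_cut).astype(float),
        "age_per_year": age - age.mean(),
        **{c: v.astype(float) for c, v in comorb.items()},
    }

    def linpred(effects: Mapping[str, float]) -> np.ndarray:
        eta = np.zeros(n)
        for name, beta in effects.items():
            if name not in covariates:
                raise ConfigurationError(f"unknown effect covariate {name!r}")
            eta += beta * covariates[name]
        return eta

    eta_doc = linpred(config.doc_logit_effects)
    if config.provider_intercept_sd > 0:
        eta_doc = eta_doc + (rng.normal(0.0, config.provider_intercept_sd,
                                        n_prov))[prov_idx]
    b0 = _calibrate_intercept(eta_doc, config.p_document_base)
    documented = rng.random(n) < expit(b0 + eta_doc)

    # ---- category assignment --------------------------------------------
    mix = config.category_mix
    category = np.full(n, "", dtype=object)
    doc_idx = np.nonzero(documented)[0]
    is_unknown = rng.random(len(doc_idx)) < mix[_cl.UNKNOWN]
    category[doc_idx[is_unknown]] = _cl.UNKNOWN
    cls_idx = doc_idx[~is_unknown]

    p_risk = ((mix[_cl.HEAVY] + mix[_cl.PAST]) / (1.0 - mix[_cl.UNKNOWN])
              if mix[_cl.UNKNOWN] < 1.0 else 0.0)
    eta_risk = linpred(config.risk_logit_effects)[cls_idx]
    if len(cls_idx):
        b0r = _calibrate_intercept(eta_risk, p_risk)
        risky = rng.random(len(cls_idx)) < expit(b0r + eta_risk)
    else:
        risky = np.zeros(0, dtype=bool)
    hp_total = mix[_cl.HEAVY] + mix[_cl.PAST]
    p_heavy = mix[_cl.HEAVY] / hp_total if hp_total > 0 else 0.5
    risky_idx = cls_idx[risky]
    category[risky_idx] = np.where(rng.random(len(risky_idx)) < p_heavy,
                                   _cl.HEAVY, _cl.PAST)
    calm_idx = cls_idx[~risky]
    nlm = np.array([mix[_cl.NONE], mix[_cl.LIGHT], mix[_cl.MODERATE]])
    nlm_total = nlm.sum()
    if len(calm_idx):
        if nlm_total <= 0:
            raise ConfigurationError(
                "category_mix assigns no mass to NONE/LIGHT/MODERATE but "
                "non-risk patients were drawn")
        category[calm_idx] = rng.choice(
            [_cl.NONE, _cl.LIGHT, _cl.MODERATE], size=len(calm_idx),
            p=nlm / nlm_total)

    # ---- quantities and note text ---------------------------------------
    quantity = np.full(n, np.nan)
    quantity[category == _cl.NONE] = 0.0
    lab = category == _cl.LIGHT
    quantity[lab] = rng.integers(1, 3, int(lab.sum()))
    lab = category == _cl.MODERATE
    quantity[lab] = rng.integers(3, 16, int(lab.sum()))
    lab = category == _cl.HEAVY
    quantity[lab] = rng.integers(16, 41, int(lab.sum()))

    texts = np.full(n, "", dtype=object)
    noise_mask = rng.random(n) < config.text_noise_rate
    for i in doc_idx:
        if noise_mask[i]:
            texts[i] = NOISE_TEMPLATES[int(rng.integers(len(NOISE_TEMPLATES)))]
        else:
            q = None if np.isnan(quantity[i]) else float(quantity[i])
            texts[i] = render_note(category[i], q, rng)

    patients = pd.DataFrame({
        "patient_id": pat_ids,
        "provider_id": prov_ids[prov_idx],
        "sex": np.where(male, "M", "F"),
        "birth_date": pd.to_datetime(birth),
        "cma_population": pop,
    })

    cond_frames = [
        pd.DataFrame({"patient_id": pat_ids[flags], "condition": name})
        for name, flags in comorb.items() if flags.any()
    ]
    conditions = (pd.concat(cond_frames, ignore_index=True)
                  .sort_values(["patient_id", "condition"],
                               kind="mergesort").reset_index(drop=True)
                  if cond_frames
                  else pd.DataFrame(columns=["patient_id", "condition"]))

    riskfactor = pd.DataFrame({
        "patient_id": pat_ids[doc_idx],
        "date": pd.to_datetime(last_enc[doc_idx]),
        "text": texts[doc_idx],
    })

    truth = pd.DataFrame({
        "patient_id": pat_ids,
        "documented": documented,
        "true_category": np.where(documented, category, ""),
        "drinks_per_week": quantity,
        "rendered_text": texts,
    })

    return SimulatedExtract(patients, providers, encounters, conditions,
                            riskfactor, truth)


def write_extract(extract: SimulatedExtract, out_dir) -> list[str]:
    """Write all six tables as RFC-4180 CSV (UTF-8, header row, ISO dates)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in extract.tables().items():
        df = df.copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        path = out / name
        df.to_csv(path, index=False, lineterminator="\r\n",
                  encoding="utf-8")
        written.append(str(path))
    return written
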