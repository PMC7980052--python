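"""Eligibility filtering and covariate derivation.

Produces one analysis-ready row per eligible patient: adults (>= 18 years)
with at least one encounter inside the half-open study window
[2015-01-01, 2018-01-01).  Age is anchored at the patient's last in-window
encounter.  Derived covariates follow the reference analysis: urban residence
(census-metropolitan-area population >= 100,000), visit frequency as the
median of per-calendar-year encounter counts dichotomized at > 3, and age
dichotomized at the cohort mean (or an explicit cut such as the published
50.7 / 49.6 years).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify as _cl
from .errors import SchemaError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = ("2015-01-01", "2018-01-01")

CONDITION_COLUMNS = ("depression", "diabetes", "hypertension",
                     "osteoarthritis", "copd", "dementia", "epilepsy",
                     "parkinsons")

#: Fixed output column order of the cohort table.
COHORT_COLUMNS = (
    "patient_id", "provider_id", "male", "age_years", "age_over_mean",
    "urban", *CONDITION_COLUMNS, "visits_per_year_median", "high_visits",
    "documented", "category", "heightened_risk", "provider_male",
    "provider_age_over_mean", "provider_is_fp",
)


def _require(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{table} table missing columns: {sorted(missing)}")


def _parse_dates(s: pd.Series, what: str) -> pd.Series:
    if pd.api.types.is_datetime64_any_dtype(s):
        return s
    parsed = pd.to_datetime(s, errors="coerce", format="ISO8601")
    bad = int(parsed.isna().sum() - s.isna().sum())
    if bad:
        logger.warning("%s: %d unparseable dates excluded", what, bad)
    return parsed


def _in_window(dates: pd.Series, window) -> pd.Series:
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    return (dates >= start) & (dates < end)


def _age_at_last_encounter(patients: pd.DataFrame,
                           encounters: pd.DataFrame, window) -> pd.DataFrame:
    enc_dates = _parse_dates(encounters["date"], "encounters")
    mask = _in_window(enc_dates, window) & enc_dates.notna()
    last = (pd.DataFrame({"patient_id": encounters.loc[mask, "patient_id"],
                          "date": enc_dates[mask]})
            .groupby("patient_id")["date"].max())
    birth = _parse_dates(patients["birth_date"], "patients.birth_date")
    df = patients[["patient_id"]].copy()
    df["last_encounter"] = df["patient_id"].map(last)
    df["age_years"] = (df["last_encounter"]
                       - birth.to_numpy()).dt.days / 365.25
    return df


def select_eligible(patients: pd.DataFrame, encounters: pd.DataFrame,
                    window=DEFAULT_WINDOW) -> pd.Index:
    """Patient ids aged >= 18 with >= 1 encounter in the half-open window.

    Stable (ordered as in ``patients``) and duplicate-free.  Rows with
    unparseable dates are excluded with a logged count.
    """
    _require(patients, ["patient_id", "birth_date"], "patients")
    _require(encounters, ["patient_id", "date"], "encounters")
    ages = _age_at_last_encounter(patients, encounters, window)
    keep = ages["last_encounter"].notna() & (ages["age_years"] >= 18.0)
    n_minor = int((ages["last_encounter"].notna()
                   & (ages["age_years"] < 18.0)).sum())
    logger.info("eligibility: %d retained, %d minors excluded, "
                "%d without in-window encounter",
                int(keep.sum()), n_minor, int(ages["last_encounter"].isna().sum()))
    return pd.Index(ages.loc[keep, "patient_id"].drop_duplicates())


def derive_urban(population: pd.Series) -> tuple[pd.Series, int]:
    """Urban flag: CMA population >= 100,000.  Missing stays missing.

    Returns the nullable-boolean series and the count of flagged-missing rows.
    """
    pop = pd.to_numeric(population, errors="coerce")
    urban = pd.Series(pd.array(pop >= 100_000, dtype="boolean"),
                      index=population.index)
    urban[pop.isna()] = pd.NA
    n_missing = int(pop.isna().sum())
    if n_missing:
        logger.warning("derive_urban: %d rows with missing population flagged",
                       n_missing)
    return urban, n_missing


def derive_visit_split(encounters: pd.DataFrame,
                       window=DEFAULT_WINDOW) -> pd.DataFrame:
    """Median annual visit count per patient and the > 3 split.

    Visits are counted per calendar year covered by the window (years with no
    visits count as zero); the median is taken across those years.
    """
    _require(encounters, ["patient_id", "date"], "encounters")
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    years = np.arange(start.year, (end - pd.Timedelta(days=1)).year + 1)
    dates = _parse_dates(encounters["date"], "encounters")
    mask = _in_window(dates, window) & dates.notna()
    counts = (pd.DataFrame({"patient_id": encounters.loc[mask, "patient_id"],
                            "year": dates[mask].dt.year})
              .groupby(["patient_id", "year"]).size()
              .unstack(fill_value=0).reindex(columns=years, fill_value=0))
    median = counts.median(axis=1)
    return pd.DataFrame({
        "patient_id": median.index,
        "visits_per_year_median": median.to_numpy(float),
        "high_visits": (median > 3).to_numpy(),
    }).reset_index(drop=True)


def pivot_conditions(conditions: pd.DataFrame,
                     patient_ids: pd.Index) -> pd.DataFrame:
    """Long condition flags -> one boolean column per known condition."""
    _require(conditions, ["patient_id", "condition"], "conditions")
    out = pd.DataFrame(False, index=patient_ids,
                       columns=list(CONDITION_COLUMNS))
    present = conditions[conditions["condition"].isin(CONDITION_COLUMNS)]
    for cond, grp in present.groupby("condition"):
        out.loc[out.index.intersection(grp["patient_id"]), cond] = True
    return out


def assemble_cohort(patients: pd.DataFrame, encounters: pd.DataFrame,
                    conditions: pd.DataFrame, providers: pd.DataFrame,
                    classified: pd.DataFrame, *,
                    window=DEFAULT_WINDOW,
                    age_cut: float | None = None,
                    provider_age_cut: float | None = None,
                    unknown_counts_as_documented: bool = True
                    ) -> pd.DataFrame:
    """Join all sources into the analysis-ready cohort table.

    ``age_cut`` / ``provider_age_cut`` default to the observed cohort means
    (pass the published cut points to reproduce a fixed dichotomization).
    With ``unknown_counts_as_documented`` (default), patients whose note
    could not be categorized count as documented for the documentation model
    but are excluded from the heightened-risk denominator.
    """
    _require(patients, ["patient_id", "provider_id", "sex", "birth_date",
                        "cma_population"], "patients")
    _require(providers, ["provider_id", "sex", "birth_date",
                         "provider_type"], "providers")
    _require(classified, ["patient_id", "label"], "classified")

    eligible = select_eligible(patients, encounters, window)
    ages = _age_at_last_encounter(patients, encounters, window)
    pat = patients.set_index("patient_id").loc[eligible]
    pat["age_years"] = ages.set_index("patient_id")["age_years"]

    n_dropped = int((~classified["patient_id"].isin(eligible)).sum())
    if n_dropped:
        logger.warning("assemble_cohort: %d classified patients not eligible, "
                       "dropped", n_dropped)

    cohort = pd.DataFrame(index=pat.index)
    cohort["provider_id"] = pat["provider_id"]
    cohort["male"] = pat["sex"].eq("M")
    cohort["age_years"] = pat["age_years"]
    cut = float(pat["age_years"].mean()) if age_cut is None else float(age_cut)
    cohort["age_over_mean"] = pat["age_years"] > cut
    urban, _ = derive_urban(pat["cma_population"])
    cohort["urban"] = urban

    cohort = cohort.join(pivot_conditions(conditions, cohort.index))

    visits = derive_visit_split(encounters, window).set_index("patient_id")
    cohort["visits_per_year_median"] = visits["visits_per_year_median"]
    cohort["high_visits"] = visits["high_visits"]

    cls = (classified[classified["patient_id"].isin(eligible)]
           .set_index("patient_id"))
    cohort["category"] = cls["label"]
    cohort["documented"] = cohort["category"].notna()
    if not unknown_counts_as_documented:
        unk = cohort["category"].eq(_cl.UNKNOWN)
        cohort.loc[unk, "documented"] = False
        cohort.loc[unk, "category"] = None
    risk = pd.Series(pd.NA, index=cohort.index, dtype="boolean")
    has_cat = cohort["category"].notna() & cohort["category"].ne(_cl.UNKNOWN)
    risk[has_cat] = cohort.loc[has_cat, "category"].isin(
        _cl.HEIGHTENED_RISK)
    cohort["heightened_risk"] = risk

    prov = providers.set_index("provider_id")
    prov_birth = _parse_dates(prov["birth_date"], "providers.birth_date")
    end = pd.Timestamp(window[1])
    prov_age = (end - prov_birth).dt.days / 365.25
    cohort["provider_male"] = cohort["provider_id"].map(prov["sex"].eq("M"))
    pa = cohort["provider_id"].map(prov_age)
    pcut = (float(pa.mean()) if provider_age_cut is None
            else float(provider_age_cut))
    cohort["provider_age_over_mean"] = pa > pcut
    cohort["provider_is_fp"] = cohort["provider_id"].map(
        prov["provider_type"].eq("FP"))

    cohort = cohort.reset_index(names="patient_id")
    cohort = cohort[list(COHORT_COLUMNS)]
    assert (cohort["age_years"] >= 18).all()
    logger.info("cohort assembled: %d rows, %d documented, %d classified",
                len(cohort), int(cohort["documented"].sum()),
                int(has_cat.sum()))
    return cohort
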