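"""Descriptive tables, bivariate tests, and provider-clustered logistic models.

The two regression models mirror the reference analysis:

* **documentation model** — logit of having any alcohol documentation on
  patient sex, dichotomized age, rural residence, visit frequency, four
  comorbidities, and provider sex/age;
* **heightened-risk model** — among classified patients only, logit of being
  a heavy or past drinker on the same patient factors with age continuous
  (per 1-year increase) and no provider terms.

Both are marginal models fit by generalized estimating equations (GEE) with
patients clustered within provider, exchangeable working correlation by
default, and robust (sandwich) standard errors.  Unadjusted odds ratios are
single-term clustered fits; the crude cross-product ratio with a Woolf CI is
kept as an independent oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import classify as _cl
from .errors import DataError, ModelError

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile

DOC_MODEL_TERMS = ("male", "age_over_mean", "rural", "high_visits",
                   "depression", "diabetes", "hypertension", "osteoarthritis",
                   "provider_male", "provider_age_over_mean")
RISK_MODEL_TERMS = ("male", "age_years", "rural", "high_visits",
                    "depression", "diabetes", "hypertension",
                    "osteoarthritis")

#: Default variable list for the descriptive (documented vs not) comparison.
BIVARIATE_VARIABLES = ("male", "age_years", "urban", "copd", "dementia",
                       "hypertension", "depression", "diabetes", "epilepsy",
                       "parkinsons", "osteoarthritis",
                       "visits_per_year_median", "provider_male")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (the convention of the printed tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# Prevalence table

@dataclass(frozen=True)
class PrevalenceTable:
    """Per-category counts/percents among classified patients.

    Percents are relative to ``classified_total`` and rounded half-up to one
    decimal; ``documented_total = classified_total + unclassified_count``.
    """

    counts: Mapping[str, int]
    classified_total: int
    unclassified_count: int
    cohort_total: int | None = None
    percents: Mapping[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.classified_total <= 0:
            raise DataError("no classified patients; prevalence undefined")
        if sum(self.counts.values()) != self.classified_total:
            raise DataError("category counts do not sum to classified_total")
        object.__setattr__(self, "percents", {
            c: round_half_up(100.0 * n / self.classified_total, 1)
            for c, n in self.counts.items()})

    @property
    def documented_total(self) -> int:
        return self.classified_total + self.unclassified_count

    @property
    def documentation_rate_pct(self) -> float | None:
        if not self.cohort_total:
            return None
        return round_half_up(100.0 * self.documented_total /
                             self.cohort_total, 1)

    @property
    def heightened_risk_pct(self) -> float:
        n = sum(self.counts[c] for c in _cl.HEIGHTENED_RISK)
        return round_half_up(100.0 * n / self.classified_total, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"category": c, "count": self.counts[c],
                 "percent": self.percents[c]}
                for c in (_cl.NONE, _cl.LIGHT, _cl.MODERATE, _cl.HEAVY,
                          _cl.PAST)]
        return pd.DataFrame(rows)


def prevalence_from_counts(counts: Mapping[str, int], unclassified: int,
                           cohort_total: int | None = None) -> PrevalenceTable:
    """Build the table directly from printed category counts."""
    return PrevalenceTable(dict(counts), int(sum(counts.values())),
                           int(unclassified), cohort_total)


def prevalence_table(cohort: pd.DataFrame) -> PrevalenceTable:
    """Compute the prevalence table from an assembled cohort."""
    cat = cohort["category"].dropna()
    counts = {c: int((cat == c).sum())
              for c in (_cl.NONE, _cl.LIGHT, _cl.MODERATE, _cl.HEAVY,
                        _cl.PAST)}
    unclassified = int((cat == _cl.UNKNOWN).sum())
    return PrevalenceTable(counts, sum(counts.values()), unclassified,
                           len(cohort))


# --------------------------------------------------------------------------
# Bivariate comparisons

@dataclass(frozen=True)
class BivariateResult:
    variable: str
    kind: str               # "chi2", "fisher", or "t"
    statistic: float
    p_value: float
    summary: pd.DataFrame   # one row per group with n and prop/mean, 95% CI


def _prop_ci(k: int, n: int) -> tuple[float, float]:
    p = k / n
    half = Z95 * math.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def bivariate_compare(cohort: pd.DataFrame, variable: str) -> BivariateResult:
    """Compare a covariate between documented and undocumented patients.

    Boolean variables get a chi-square test on the 2x2 table (exact test if a
    cell is empty); numeric variables a pooled two-sample t-test.
    """
    if variable not in cohort.columns:
        raise DataError(f"unknown cohort variable {variable!r}")
    doc = cohort["documented"].astype(bool)
    x = cohort[variable]
    groups = {"documented": x[doc], "undocumented": x[~doc]}

    if pd.api.types.is_bool_dtype(x) or str(x.dtype) == "boolean":
        rows, table = [], []
        for name, g in groups.items():
            g = g.dropna().astype(bool)
            k, n = int(g.sum()), len(g)
            lo, hi = _prop_ci(k, n)
            rows.append({"group": name, "n": n, "estimate": k / n,
                         "ci_low": lo, "ci_high": hi})
            table.append([k, n - k])
        table = np.asarray(table)
        if (table == 0).any():
            stat, p = np.nan, stats.fisher_exact(table)[1]
            kind = "fisher"
            logger.info("bivariate %s: zero cell, exact test used", variable)
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            kind = "chi2"
    else:
        rows, samples = [], []
        for name, g in groups.items():
            g = pd.to_numeric(g, errors="coerce").dropna()
            m, sd, n = g.mean(), g.std(ddof=1), len(g)
            half = Z95 * sd / math.sqrt(n)
            rows.append({"group": name, "n": n, "estimate": m,
                         "sd": sd, "ci_low": m - half, "ci_high": m + half})
            samples.append(g.to_numpy())
        stat, p = stats.ttest_ind(*samples, equal_var=True)
        kind = "t"
    return BivariateResult(variable, kind, float(stat), float(p),
                           pd.DataFrame(rows))


# --------------------------------------------------------------------------
# Crude odds ratio (oracle for the unadjusted columns)

@dataclass(frozen=True)
class OddsRatio:
    value: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied


def crude_odds_ratio(a: float, b: float, c: float, d: float) -> OddsRatio:
    """Cross-product odds ratio (a*d)/(b*c) with a Woolf 95% CI.

    A zero cell triggers the Haldane-Anscombe 0.5 correction (flagged).
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise DataError("2x2 counts must be non-negative")
    corrected = any(x == 0 for x in cells)
    if corrected:
        a, b, c, d = (x + 0.5 for x in cells)
        logger.info("crude OR: zero cell, Haldane-Anscombe correction applied")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatio(or_, or_ * math.exp(-Z95 * se), or_ * math.exp(Z95 * se),
                     corrected)


# --------------------------------------------------------------------------
# GEE models

@dataclass(frozen=True)
class ModelResult:
    """Fitted-model summary: one row per term with adjusted and (optionally)
    unadjusted ORs, 95% CIs, and robust p-values."""

    outcome: str
    terms: pd.DataFrame
    n_used: int
    n_clusters: int
    working_correlation: str

    def odds_ratio(self, term: str, adjusted: bool = True) -> OddsRatio:
        row = self.terms.loc[term]
        pre = "adj" if adjusted else "unadj"
        return OddsRatio(row[f"{pre}_or"], row[f"{pre}_ci_low"],
                         row[f"{pre}_ci_high"])


def _gee_fit(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray,
             working_correlation: str):
    if working_correlation == "exchangeable":
        cov = sm.cov_struct.Exchangeable()
    elif working_correlation == "independence":
        cov = sm.cov_struct.Independence()
    else:
        raise ValueError(f"unknown working correlation "
                         f"{working_correlation!r}")
    model = sm.GEE(y, sm.add_constant(X), groups=groups,
                   family=sm.families.Binomial(), cov_struct=cov)
    try:
        res = model.fit(maxiter=100)
    except Exception as exc:  # pragma: no cover - statsmodels internals
        raise ModelError(f"GEE fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise ModelError("GEE did not converge to finite coefficients")
    return res


def _fit_or_model(data: pd.DataFrame, outcome: str, terms: Sequence[str],
                  working_correlation: str,
                  compute_unadjusted: bool) -> ModelResult:
    cols = [outcome, "provider_id", *terms]
    n_before = len(data)
    data = data[cols].dropna()
    n_dropped = n_before - len(data)
    if n_dropped:
        logger.info("model %s: %d rows dropped listwise for missingness",
                    outcome, n_dropped)
    y = data[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ModelError(f"outcome {outcome!r} is constant in the "
                         "analysis sample")
    groups = data["provider_id"].to_numpy()
    n_clusters = len(np.unique(groups))
    if n_clusters < 2:
        raise ModelError("at least two provider clusters are required")
    X = data[list(terms)].astype(float)

    res = _gee_fit(y, X, groups, working_correlation)
    ci = res.conf_int()
    rows = {}
    for term in terms:
        rows[term] = {
            "adj_or": math.exp(res.params[term]),
            "adj_ci_low": math.exp(ci.loc[term, 0]),
            "adj_ci_high": math.exp(ci.loc[term, 1]),
            "p_value": float(res.pvalues[term]),
        }
    if compute_unadjusted:
        for term in terms:
            r1 = _gee_fit(y, X[[term]], groups, working_correlation)
            c1 = r1.conf_int()
            rows[term]["unadj_or"] = math.exp(r1.params[term])
            rows[term]["unadj_ci_low"] = math.exp(c1.loc[term, 0])
            rows[term]["unadj_ci_high"] = math.exp(c1.loc[term, 1])
    frame = pd.DataFrame.from_dict(rows, orient="index")
    return ModelResult(outcome, frame, len(data), n_clusters,
                       working_correlation)


def fit_documentation_model(cohort: pd.DataFrame, *,
                            working_correlation: str = "exchangeable",
                            compute_unadjusted: bool = True) -> ModelResult:
    """Model 1: odds of having alcohol documentation, clustered by provider."""
    data = cohort.copy()
    data["rural"] = ~data["urban"].astype("boolean")
    return _fit_or_model(data, "documented", DOC_MODEL_TERMS,
                         working_correlation, compute_unadjusted)


def fit_risk_model(cohort: pd.DataFrame, *,
                   working_correlation: str = "exchangeable",
                   compute_unadjusted: bool = True) -> ModelResult:
    """Model 2: odds of heightened risk (heavy/past) among classified
    patients; age enters continuously per year."""
    data = cohort[cohort["category"].notna()
                  & cohort["category"].ne(_cl.UNKNOWN)].copy()
    if data.empty:
        raise ModelError("no classified patients for the risk model")
    data["rural"] = ~data["urban"].astype("boolean")
    data["heightened_risk"] = data["heightened_risk"].astype("boolean")
    return _fit_or_model(data, "heightened_risk", RISK_MODEL_TERMS,
                         working_correlation, compute_unadjusted)


# --------------------------------------------------------------------------
# Reporting

def _results_rows(prevalence: PrevalenceTable | None,
                  bivariates: Sequence[BivariateResult],
                  models: Sequence[ModelResult]) -> pd.DataFrame:
    rows = []
    if prevalence is not None:
        for cat in (_cl.NONE, _cl.LIGHT, _cl.MODERATE, _cl.HEAVY, _cl.PAST):
            rows.append({"section": "prevalence", "term": cat,
                         "estimate": prevalence.percents[cat],
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "n": prevalence.counts[cat]})
        rows.append({"section": "prevalence", "term": "heightened_risk_pct",
                     "estimate": prevalence.heightened_risk_pct,
                     "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                     "n": prevalence.classified_total})
        if prevalence.documentation_rate_pct is not None:
            rows.append({"section": "prevalence",
                         "term": "documentation_rate_pct",
                         "estimate": prevalence.documentation_rate_pct,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "n": prevalence.cohort_total})
    for b in bivariates:
        doc = b.summary.set_index("group").loc["documented"]
        rows.append({"section": "bivariate", "term": b.variable,
                     "estimate": doc["estimate"], "ci_low": doc["ci_low"],
                     "ci_high": doc["ci_high"], "p": b.p_value,
                     "n": int(b.summary["n"].sum())})
    for m in models:
        for term, r in m.terms.iterrows():
            rows.append({"section": f"model:{m.outcome}", "term": term,
                         "estimate": r["adj_or"], "ci_low": r["adj_ci_low"],
                         "ci_high": r["adj_ci_high"], "p": r["p_value"],
                         "n": m.n_used})
    return pd.DataFrame(rows, columns=["section", "term", "estimate",
                                       "ci_low", "ci_high", "p", "n"])


def report(prevalence: PrevalenceTable | None,
           bivariates: Sequence[BivariateResult],
           models: Sequence[ModelResult], out_dir) -> dict[str, str]:
    """Write ``results.csv`` (machine-readable) and ``report.txt``.

    Percents are shown half-up to one decimal, odds ratios to two decimals.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = _results_rows(prevalence, bivariates, models)
    csv_path = out / "results.csv"
    frame.to_csv(csv_path, index=False)

    lines = []
    if prevalence is not None:
        lines += ["Alcohol documentation categories (classified patients)",
                  prevalence.to_frame().to_string(index=False),
                  f"classified total : {prevalence.classified_total}",
                  f"unclassified     : {prevalence.unclassified_count}",
                  f"documented total : {prevalence.documented_total}",
                  f"heightened risk  : {prevalence.heightened_risk_pct}%"]
        if prevalence.documentation_rate_pct is not None:
            lines.append(f"documentation    : "
                         f"{prevalence.documentation_rate_pct}% of "
                         f"{prevalence.cohort_total}")
        lines.append("")
    if bivariates:
        lines.append("Bivariate comparisons (documented vs undocumented)")
        for b in bivariates:
            lines.append(f"  {b.variable}: {b.kind} stat="
                         f"{b.statistic:.3f} p={b.p_value:.4g}")
        lines.append("")
    for m in models:
        lines.append(f"GEE model — outcome: {m.outcome} "
                     f"(n={m.n_used}, clusters={m.n_clusters}, "
                     f"working correlation={m.working_correlation})")
        disp = m.terms.copy()
        for col in disp.columns:
            if col != "p_value":
                disp[col] = disp[col].map(lambda v: round_half_up(v, 2))
        lines.append(disp.to_string())
        lines.append("")
    lines.append("Note: no multiple-testing correction applied.")
    txt_path = out / "report.txt"
    txt_path.write_text("\n".join(lines), encoding="utf-8")
    return {"results.csv": str(csv_path), "report.txt": str(txt_path)}
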