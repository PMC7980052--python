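"""Deterministic rule-based classification of free-text alcohol documentation.

Each risk-factor entry is assigned exactly one of six categories:

``NONE``      non-drinker / denial of current use
``LIGHT``     < 3 drinks per week
``MODERATE``  3-15 drinks per week (both bounds inclusive)
``HEAVY``     > 15 drinks per week
``PAST``      former drinker (quit, recovering, recovered, ...)
``UNKNOWN``   documentation exists but cannot be categorized (family history,
              unquantified mention, garbled text)

The bands follow Canadian low-risk drinking guidance as applied to weekly
standard-drink counts.  Decision precedence when rules conflict inside one
note is PAST > quantity band > NONE > UNKNOWN: a former drinker whose note
also carries an old quantity is a past drinker, and a denial phrase in the
same sentence as a quantity voids that quantity.  Sentences attributed to a
relative (family-history markers) are ignored entirely.

Rule dictionaries ship as plain-text files (one phrase per line, ``#``
comments) under :mod:`alcodoc.rules` and can be replaced wholesale via
:func:`load_rules`.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError

# --------------------------------------------------------------------------
# Categories

NONE = "NONE"
LIGHT = "LIGHT"
MODERATE = "MODERATE"
HEAVY = "HEAVY"
PAST = "PAST"
UNKNOWN = "UNKNOWN"

#: All category labels, in reporting order.
CATEGORIES: tuple[str, ...] = (NONE, LIGHT, MODERATE, HEAVY, PAST, UNKNOWN)

#: Categories flagging heightened risk of alcohol-related problems.
HEIGHTENED_RISK: frozenset[str] = frozenset({HEAVY, PAST})

#: Tie-break ordering: larger rank = heavier-risk label.
SEVERITY: Mapping[str, int] = {
    UNKNOWN: 0,
    NONE: 1,
    LIGHT: 2,
    MODERATE: 3,
    PAST: 4,
    HEAVY: 5,
}

# Weekly-band edges (drinks per week).
LIGHT_UPPER = 3.0     # exclusive: LIGHT is (0, 3)
MODERATE_UPPER = 15.0  # inclusive: MODERATE is [3, 15]
FEMALE_HEAVY_LOWER = 10.0  # used only when sex-specific bands are enabled


@dataclass(frozen=True)
class Evidence:
    """One fired rule: which dictionary it came from and the matched span."""

    rule: str
    text: str
    start: int
    end: int

    def __str__(self) -> str:  # compact form used in CSV output
        return f"{self.rule}={self.text!r}@{self.start}"


@dataclass(frozen=True)
class AlcoholCategory:
    """Classification result for a single note."""

    label: str
    drinks_per_week: float | None = None
    evidence: tuple[Evidence, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in CATEGORIES:
            raise ValueError(f"unknown category label {self.label!r}")


# --------------------------------------------------------------------------
# Rule set

def _read_phrase_file(path_or_text: str) -> tuple[str, ...]:
    phrases = []
    for line in path_or_text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            phrases.append(line.lower())
    return tuple(phrases)


@dataclass(frozen=True)
class RuleSet:
    """Phrase dictionaries plus banding options for the classifier.

    All phrase matching is case-insensitive on word boundaries.
    ``sex_specific_bands`` switches the heavy threshold to the guideline
    limits (>15/week male, >10/week female) instead of the sex-agnostic
    bands; it is off by default.
    """

    past_keywords: tuple[str, ...]
    none_keywords: tuple[str, ...]
    family_markers: tuple[str, ...]
    unknown_markers: tuple[str, ...]
    sex_specific_bands: bool = False
    precedence: tuple[str, ...] = (PAST, "quantity", NONE, UNKNOWN)
    _patterns: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("past_keywords", "none_keywords"):
            phrases = getattr(self, name)
            if not phrases:
                raise ValueError(f"{name} must not be empty")
            if any(not p for p in phrases):
                raise ValueError(f"{name} contains an empty phrase")

    def _pattern(self, name: str, phrases: tuple[str, ...]) -> re.Pattern:
        pat = self._patterns.get(name)
        if pat is None:
            alts = "|".join(re.escape(p) for p in
                            sorted(phrases, key=len, reverse=True))
            pat = re.compile(rf"\b(?:{alts})\b", re.IGNORECASE)
            self._patterns[name] = pat
        return pat

    def finditer(self, name: str, text: str) -> Iterable[re.Match]:
        phrases = {
            "past": self.past_keywords,
            "none": self.none_keywords,
            "family": self.family_markers,
            "unknown": self.unknown_markers,
        }[name]
        if not phrases:
            return ()
        return self._pattern(name, phrases).finditer(text)


def load_rules(rules_dir: str | Path | None = None, *,
               sex_specific_bands: bool = False) -> RuleSet:
    """Load phrase dictionaries from ``rules_dir`` (default: packaged rules).

    Expects ``past.txt``, ``none.txt``, ``family.txt`` and ``unknown.txt``;
    the last two may be absent (empty marker lists).
    """
    def read(stem: str, required: bool) -> tuple[str, ...]:
        if rules_dir is None:
            ref = resources.files("alcodoc.rules") / f"{stem}.txt"
            if ref.is_file():
                return _read_phrase_file(ref.read_text(encoding="utf-8"))
            text = None
        else:
            p = Path(rules_dir) / f"{stem}.txt"
            text = p.read_text(encoding="utf-8") if p.is_file() else None
        if text is None:
            if required:
                raise FileNotFoundError(f"missing rule file {stem}.txt")
            return ()
        return _read_phrase_file(text)

    return RuleSet(
        past_keywords=read("past", True),
        none_keywords=read("none", True),
        family_markers=read("family", False),
        unknown_markers=read("unknown", False),
        sex_specific_bands=sex_specific_bands,
    )


_DEFAULT_RULES: RuleSet | None = None


def default_rules() -> RuleSet:
    """The packaged rule set (cached)."""
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules(None)
    return _DEFAULT_RULES


# --------------------------------------------------------------------------
# Normalization

_WS_RE = re.compile(r"\s+")
_DASH_RE = re.compile(r"[‐-―−]")
_QUOTE_RE = re.compile(r"[‘’‛]")


def normalize_text(raw: str) -> str:
    """Canonicalize a note: NFKC, lowercase, collapsed whitespace,
    standardized dashes/apostrophes, trailing sentence punctuation stripped.

    Idempotent; the empty string maps to itself.
    """
    if not raw:
        return ""
    s = unicodedata.normalize("NFKC", str(raw)).lower()
    s = _DASH_RE.sub("-", s)
    s = _QUOTE_RE.sub("'", s)
    s = _WS_RE.sub(" ", s).strip()
    return s.rstrip(" .")


# Sentence boundary: '.' or ';' not inside a decimal number.
_SENT_RE = re.compile(r"(?<!\d)\.(?!\d)|;")


def _sentences(text: str) -> list[str]:
    return [s for s in _SENT_RE.split(text) if s.strip()]


# --------------------------------------------------------------------------
# Quantity extraction

_NUM_WORDS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "thirteen": 13, "fourteen": 14, "fifteen": 15,
    "sixteen": 16, "seventeen": 17, "eighteen": 18, "nineteen": 19,
    "twenty": 20,
}
_NUM = r"\d+(?:\.\d+)?|" + "|".join(_NUM_WORDS)
_UNIT = (r"(?:standard\s+)?(?:drinks?|beers?|glasse?s?|bottles?|shots?"
         r"|units?)(?:\s+of\s+\w+)?")
_PERIOD = (
    r"(?:(?:per|a|an|each|every)\s+(?P<p1>weeks?|wk|days?|months?|mo)"
    r"|/\s*(?P<p2>weeks?|wk|w|days?|d|months?|mo)"
    r"|(?P<p3>weekly|daily|monthly))"
)
QUANTITY_RE = re.compile(
    rf"\b(?P<lo>{_NUM})(?:\s*(?:-|to)\s*(?P<hi>{_NUM}))?"
    rf"\s*(?:{_UNIT})?\s*{_PERIOD}\b",
    re.IGNORECASE,
)

#: Multiplier converting a per-period count to per-week.
_PER_WEEK = {"week": 1.0, "wk": 1.0, "w": 1.0, "day": 7.0, "d": 7.0,
             "month": 7.0 / 30.0, "mo": 7.0 / 30.0,
             "weekly": 1.0, "daily": 7.0, "monthly": 7.0 / 30.0}


def _to_number(tok: str) -> float:
    tok = tok.lower()
    if tok in _NUM_WORDS:
        return float(_NUM_WORDS[tok])
    return float(tok)


def _weekly_from_match(m: re.Match) -> float:
    lo = _to_number(m["lo"])
    value = (lo + _to_number(m["hi"])) / 2.0 if m["hi"] else lo
    period = (m["p1"] or m["p2"] or m["p3"]).lower().rstrip("s")
    if period not in _PER_WEEK:
        period = period[:2] if period[:2] in _PER_WEEK else period[0]
    return value * _PER_WEEK[period]


def extract_quantity(text: str, rules: RuleSet | None = None) -> float | None:
    """Weekly-equivalent drink count parsed from normalized text, or ``None``.

    Daily counts are multiplied by 7, monthly divided by 30/7; a range
    ("2-3 drinks a week") resolves to its midpoint.  When several quantities
    are present the largest weekly equivalent is returned (risk-conservative).
    """
    matches = list(QUANTITY_RE.finditer(text))
    if not matches:
        return None
    return max(_weekly_from_match(m) for m in matches)


# --------------------------------------------------------------------------
# Classification

def _band(q: float, *, female: bool, sex_specific: bool) -> str:
    heavy_lower = (FEMALE_HEAVY_LOWER if sex_specific and female
                   else MODERATE_UPPER)
    if q == 0:
        return NONE
    if q < LIGHT_UPPER:
        return LIGHT
    if q <= heavy_lower:
        return MODERATE
    return HEAVY


def classify_note(raw: str, rules: RuleSet | None = None, *,
                  sex: str | None = None) -> AlcoholCategory:
    """Classify one free-text alcohol entry.

    Every input yields exactly one label; empty or uninterpretable text is
    UNKNOWN.  ``evidence`` records every fired rule with its span in the
    normalized text.
    """
    rules = rules or default_rules()
    text = normalize_text(raw)
    if not text:
        return AlcoholCategory(UNKNOWN)

    evidence: list[Evidence] = []
    past_hit = False
    none_hit = False
    quantities: list[tuple[float, Evidence]] = []

    offset = 0
    for sent in _SENT_RE.split(text):
        start = offset
        offset += len(sent) + 1
        if not sent.strip():
            continue

        fam = [m for m in rules.finditer("family", sent)]
        if fam:
            # attributed to a relative: record and ignore everything else
            evidence.extend(
                Evidence("family", m.group(0), start + m.start(), start + m.end())
                for m in fam)
            continue

        sent_none = list(rules.finditer("none", sent))
        sent_past = list(rules.finditer("past", sent))
        sent_qty = list(QUANTITY_RE.finditer(sent))

        for m in sent_past:
            past_hit = True
            evidence.append(Evidence("past", m.group(0),
                                     start + m.start(), start + m.end()))
        if sent_none:
            none_hit = True
            evidence.extend(
                Evidence("none", m.group(0), start + m.start(), start + m.end())
                for m in sent_none)
            # denial voids any quantity in the same sentence
            continue
        for m in sent_qty:
            q = _weekly_from_match(m)
            quantities.append((q, Evidence("quantity", m.group(0),
                                           start + m.start(), start + m.end())))

    if past_hit:
        keep = [e for e in evidence if e.rule == "past"]
        return AlcoholCategory(PAST, None, tuple(keep))
    if quantities:
        q, ev = max(quantities, key=lambda t: t[0])
        label = _band(q, female=(sex == "F"),
                      sex_specific=rules.sex_specific_bands)
        band_q = q if label in (LIGHT, MODERATE, HEAVY) else q
        return AlcoholCategory(label, band_q, (ev,))
    if none_hit:
        keep = [e for e in evidence if e.rule == "none"]
        return AlcoholCategory(NONE, None, tuple(keep))

    for m in rules.finditer("unknown", text):
        evidence.append(Evidence("unknown", m.group(0), m.start(), m.end()))
    return AlcoholCategory(UNKNOWN, None, tuple(evidence))


# --------------------------------------------------------------------------
# Table-level classification

#: Per-patient multi-note resolution policies.
POLICIES = ("most-recent", "heaviest", "first")


def _resolve(work: pd.DataFrame, policy: str) -> pd.DataFrame:
    """One row per patient under the given multi-note policy (vectorized)."""
    if policy == "heaviest":
        order = work.sort_values(["patient_id", "severity"], kind="mergesort")
        keep = "last"
    elif policy == "first":
        # earliest note; tie on date -> heavier-risk label
        order = work.sort_values(["patient_id", "date", "severity"],
                                 ascending=[True, False, True],
                                 kind="mergesort")
        keep = "last"
    else:  # most-recent; tie on date -> heavier-risk label
        order = work.sort_values(["patient_id", "date", "severity"],
                                 kind="mergesort", na_position="first")
        keep = "last"
    return order.drop_duplicates("patient_id", keep=keep)


def classify_table(riskfactor: pd.DataFrame, rules: RuleSet | None = None, *,
                   policy: str = "most-recent",
                   text_column: str = "text") -> pd.DataFrame:
    """Classify every note and resolve one label per patient.

    ``riskfactor`` needs ``patient_id`` and a text column; a ``date`` column
    is used by the most-recent/first policies (missing dates sort earliest).
    Returns one row per patient: ``patient_id``, ``label``,
    ``drinks_per_week``, ``evidence``.
    """
    required = {"patient_id", text_column}
    missing = required - set(riskfactor.columns)
    if missing:
        raise SchemaError(f"riskfactor table missing columns: {sorted(missing)}")
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")

    out_cols = ["patient_id", "label", "drinks_per_week", "evidence"]
    if riskfactor.empty:
        return pd.DataFrame(columns=out_cols)

    rules = rules or default_rules()
    cats = [classify_note(t, rules) for t in riskfactor[text_column].fillna("")]
    work = pd.DataFrame({
        "patient_id": riskfactor["patient_id"].to_numpy(),
        "label": [c.label for c in cats],
        "drinks_per_week": [c.drinks_per_week for c in cats],
        "evidence": ["; ".join(map(str, c.evidence)) for c in cats],
    })
    work["severity"] = work["label"].map(SEVERITY)
    if "date" in riskfactor.columns:
        work["date"] = pd.to_datetime(riskfactor["date"].to_numpy(),
                                      errors="coerce")
    else:
        work["date"] = pd.NaT

    resolved = (_resolve(work, policy)
                .sort_values("patient_id", kind="mergesort")
                .reset_index(drop=True))
    return resolved[out_cols]
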