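"""Registry data model, delivery-outcome classification, analysis-set filtering
and derived covariates.

The unit of analysis is one enrolled pregnancy/birth (one row per delivered
fetus).  Records enter as CSV rows following :data:`REGISTRY_COLUMNS`; missing
values are empty fields, enumerations are lowercase snake-case strings, and
tri-state clinical condition flags are ``true``/``false``/empty (unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from ._round import round_half_up

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

SITES = ("guatemala", "drc", "zambia", "kenya", "belagavi", "nagpur", "pakistan")
AFRICAN_SITES = ("drc", "zambia", "kenya")
ASIAN_SITES = ("belagavi", "nagpur", "pakistan")

YEAR_RANGE = (2010, 2018)
GA_RANGE = (10, 50)          # completed weeks, when present
BIRTHWEIGHT_RANGE = (100, 8000)  # grams, when present

EDUCATION_LEVELS = ("none", "primary", "secondary", "university_plus")
ATTENDANTS = ("physician", "nurse_midwife_hw", "tba", "family_other")
LOCATIONS = ("hospital", "clinic", "home_other")
MODES = ("vaginal", "vaginal_assisted", "cesarean")
OUTCOME_STATUSES = ("live_birth", "fetal_death", "miscarriage", "termination", "missing")
SEXES = ("male", "female", "unknown")
PRESENTATIONS = ("cephalic", "breech_transverse", "unknown")
MACERATION_STATES = ("macerated", "non_macerated", "unknown", "not_applicable")
TRISTATES = ("yes", "no", "unknown")

#: Clinical condition flags consumed by the cause-of-death hierarchy.
CONDITION_FLAGS = (
    "trauma",
    "major_anomaly",
    "maternal_infection",
    "fetal_infection",
    "hypertensive_disease",
    "antepartum_hemorrhage",
    "obstructed_prolonged_labor",
    "breech_transverse",
    "other_asphyxia_condition",
)

#: Condition flags are flattened into the registry CSV with this prefix.
CONDITION_PREFIX = "cond_"
CONDITION_COLUMNS = tuple(CONDITION_PREFIX + f for f in CONDITION_FLAGS)

REGISTRY_COLUMNS = (
    "record_id",
    "site",
    "cluster_id",
    "year",
    "maternal_age",
    "education",
    "parity",
    "prior_pregnancy_live",
    "anc_visits",
    "attendant",
    "location",
    "mode",
    "outcome_status",
    "ga_weeks",
    "birthweight_g",
    "sex",
    "multiple",
    "presentation",
    "maceration",
) + CONDITION_COLUMNS

_INT_COLUMNS = ("year", "maternal_age", "parity", "anc_visits", "ga_weeks", "birthweight_g")
_BOOL_COLUMNS = ("multiple",) + CONDITION_COLUMNS

_ENUM_DOMAINS = {
    "site": SITES,
    "education": EDUCATION_LEVELS,
    "prior_pregnancy_live": TRISTATES,
    "attendant": ATTENDANTS,
    "location": LOCATIONS,
    "mode": MODES,
    "outcome_status": OUTCOME_STATUSES,
    "sex": SEXES,
    "presentation": PRESENTATIONS,
    "maceration": MACERATION_STATES,
}
# optional enum columns may be entirely missing; these must carry a value
_REQUIRED_ENUMS = ("site", "outcome_status")

#: Covariate columns appended by :func:`derive_covariates`.
COVARIATE_COLUMNS = (
    "preterm",
    "low_birthweight",
    "age_group",
    "education",
    "parity_group",
    "prior_loss",
    "anc_group",
    "attendant",
    "location",
    "mode",
    "multiple",
    "breech",
    "sex",
)

PRETERM_GA_LIMIT = 37        # completed weeks; <37 is preterm
LOW_BIRTHWEIGHT_LIMIT = 2500  # grams; <2500 g is low birthweight


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class ConditionFlags(BaseModel):
    """Tri-state clinical condition flags; ``None`` means unknown.

    Unknown flags are treated as absent by the cause classifier but are
    preserved for reporting.
    """

    model_config = ConfigDict(extra="forbid")

    trauma: Optional[bool] = None
    major_anomaly: Optional[bool] = None
    maternal_infection: Optional[bool] = None
    fetal_infection: Optional[bool] = None
    hypertensive_disease: Optional[bool] = None
    antepartum_hemorrhage: Optional[bool] = None
    obstructed_prolonged_labor: Optional[bool] = None
    breech_transverse: Optional[bool] = None
    other_asphyxia_condition: Optional[bool] = None


class PregnancyRecord(BaseModel):
    """One enrolled pregnancy/birth — the unit of analysis."""

    model_config = ConfigDict(extra="forbid")

    record_id: str
    site: str
    cluster_id: str
    year: int = Field(ge=YEAR_RANGE[0], le=YEAR_RANGE[1])
    maternal_age: Optional[int] = Field(default=None, ge=0)
    education: Optional[str] = None
    parity: Optional[int] = Field(default=None, ge=0)
    prior_pregnancy_live: str = "unknown"
    anc_visits: Optional[int] = Field(default=None, ge=0)
    attendant: Optional[str] = None
    location: Optional[str] = None
    mode: Optional[str] = None
    outcome_status: str = "missing"
    ga_weeks: Optional[int] = Field(default=None, ge=GA_RANGE[0], le=GA_RANGE[1])
    birthweight_g: Optional[int] = Field(
        default=None, ge=BIRTHWEIGHT_RANGE[0], le=BIRTHWEIGHT_RANGE[1]
    )
    sex: str = "unknown"
    multiple: Optional[bool] = None
    presentation: str = "unknown"
    maceration: str = "not_applicable"
    conditions: ConditionFlags = Field(default_factory=ConditionFlags)

    def to_row(self) -> dict:
        """Flatten to a registry CSV row (condition flags prefixed)."""
        row = self.model_dump(exclude={"conditions"})
        for name in CONDITION_FLAGS:
            row[CONDITION_PREFIX + name] = getattr(self.conditions, name)
        return row


def registry_json_schema() -> dict:
    """JSON schema documenting record fields and allowed values."""
    schema = PregnancyRecord.model_json_schema()
    schema["x-enum-domains"] = {k: list(v) for k, v in _ENUM_DOMAINS.items()}
    return schema


@dataclass(frozen=True)
class ClassificationThresholds:
    """Thresholds splitting fetal deaths into stillbirths vs miscarriages.

    Gestational age takes precedence when both fields are present; the
    birthweight rule is a fallback for records without a gestational age.
    ``strict_gt_500g`` switches the weight fallback from ``>= 500 g`` to
    ``> 500 g``.
    """

    ga_weeks: int = 20
    birthweight_g: int = 500
    strict_gt_500g: bool = False

    def weight_qualifies(self, birthweight_g: float) -> bool:
        if self.strict_gt_500g:
            return birthweight_g > self.birthweight_g
        return birthweight_g >= self.birthweight_g


DEFAULT_THRESHOLDS = ClassificationThresholds()

EXCLUSION_REASONS = ("miscarriage", "termination", "missing")


@dataclass
class EnrollmentLedger:
    """Fig.-1-style accounting: screened -> enrolled -> included."""

    screened: int
    enrolled: int
    excluded_by_reason: dict
    included: int

    def __post_init__(self) -> None:
        excluded = sum(self.excluded_by_reason.values())
        if self.included + excluded != self.enrolled:
            raise ValueError(
                f"ledger does not balance: included {self.included} + excluded "
                f"{excluded} != enrolled {self.enrolled}"
            )

    @property
    def excluded(self) -> int:
        return sum(self.excluded_by_reason.values())

    @property
    def consent_percent(self) -> float:
        """Percent of screened women enrolled, rounded to one decimal."""
        if self.screened == 0:
            return float("nan")
        return round_half_up(100.0 * self.enrolled / self.screened, 1)

    @property
    def included_percent(self) -> float:
        if self.enrolled == 0:
            return float("nan")
        return round_half_up(100.0 * self.included / self.enrolled, 1)

    def to_dict(self) -> dict:
        return {
            "screened": self.screened,
            "enrolled": self.enrolled,
            "consent_percent": self.consent_percent,
            "excluded_by_reason": dict(self.excluded_by_reason),
            "excluded": self.excluded,
            "included": self.included,
            "included_percent": self.included_percent,
        }


@dataclass
class AnalysisSet:
    """Included records (live births + stillbirths) plus the enrollment ledger."""

    records: pd.DataFrame
    ledger: EnrollmentLedger


# ---------------------------------------------------------------------------
# Loading / validation
# ---------------------------------------------------------------------------

def _parse_bool(series: pd.Series) -> pd.Series:
    s = series.astype("string").str.strip().str.lower()
    out = pd.Series(pd.NA, index=series.index, dtype="boolean")
    out[s == "true"] = True
    out[s == "false"] = False
    return out


def _format_bool(series: pd.Series) -> pd.Series:
    return series.map({True: "true", False: "false"}).astype("string")


def load_registry(
    source: Union[str, Path, IO[str]],
    *,
    return_rejects: bool = False,
):
    """Read and validate a registry CSV.

    Rows violating field invariants (out-of-range gestational age or
    birthweight, negative counts, unknown enum codes, bad year) are rejected
    and logged with their ``record_id`` and reason.

    Returns the validated frame, or ``(frame, rejects)`` when
    ``return_rejects`` is true; ``rejects`` has columns ``record_id``/``reason``.
    """
    raw = pd.read_csv(source, dtype="string", keep_default_na=False)
    missing_cols = [c for c in REGISTRY_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"registry CSV missing required columns: {missing_cols}")
    raw = raw.replace("", pd.NA)

    df = pd.DataFrame(index=raw.index)
    reasons = pd.Series("", index=raw.index, dtype="string")

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask.fillna(False) & (reasons == "")
        reasons[fresh] = reason

    df["record_id"] = raw["record_id"]
    flag(df["record_id"].isna(), "missing record_id")
    df["cluster_id"] = raw["cluster_id"]
    flag(df["cluster_id"].isna(), "missing cluster_id")

    for col in _INT_COLUMNS:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        flag(raw[col].notna() & numeric.isna(), f"non-numeric {col}")
        flag(numeric.notna() & (numeric != numeric.round()), f"non-integer {col}")
        df[col] = numeric.round().astype("Int64")

    flag(df["year"].isna(), "missing year")
    flag(
        (df["year"] < YEAR_RANGE[0]) | (df["year"] > YEAR_RANGE[1]),
        f"year outside {YEAR_RANGE}",
    )
    flag(
        (df["ga_weeks"] < GA_RANGE[0]) | (df["ga_weeks"] > GA_RANGE[1]),
        f"ga_weeks outside {GA_RANGE}",
    )
    flag(
        (df["birthweight_g"] < BIRTHWEIGHT_RANGE[0])
        | (df["birthweight_g"] > BIRTHWEIGHT_RANGE[1]),
        f"birthweight_g outside {BIRTHWEIGHT_RANGE}",
    )
    for col in ("maternal_age", "parity", "anc_visits"):
        flag(df[col] < 0, f"negative {col}")

    for col, domain in _ENUM_DOMAINS.items():
        values = raw[col].str.strip().str.lower()
        bad = values.notna() & ~values.isin(domain)
        flag(bad, f"invalid {col}")
        if col in _REQUIRED_ENUMS:
            flag(values.isna(), f"missing {col}")
        df[col] = values

    df["maceration"] = df["maceration"].fillna("not_applicable")
    df["prior_pregnancy_live"] = df["prior_pregnancy_live"].fillna("unknown")
    df["sex"] = df["sex"].fillna("unknown")
    df["presentation"] = df["presentation"].fillna("unknown")

    for col in _BOOL_COLUMNS:
        values = raw[col].str.strip().str.lower()
        bad = values.notna() & ~values.isin(("true", "false"))
        flag(bad, f"invalid {col}")
        df[col] = _parse_bool(raw[col])

    ok = reasons == ""
    rejects = pd.DataFrame(
        {"record_id": raw.loc[~ok, "record_id"], "reason": reasons[~ok]}
    ).reset_index(drop=True)
    for _, rej in rejects.iterrows():
        log.warning("rejected record %s: %s", rej["record_id"], rej["reason"])

    frame = df[ok].reset_index(drop=True)[list(REGISTRY_COLUMNS)]
    if return_rejects:
        return frame, rejects
    if len(rejects):
        log.warning("%d record(s) rejected at load", len(rejects))
    return frame


def write_registry(df: pd.DataFrame, path: Union[str, Path, IO[str]]) -> None:
    """Write a registry frame back to CSV (missing -> empty, flags -> true/false)."""
    out = df.copy()
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            out[col] = _format_bool(out[col])
    out.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Outcome classification
# ---------------------------------------------------------------------------

def classify_delivery_outcome(
    record: Union[PregnancyRecord, Mapping],
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Classify one record's final delivery outcome.

    Fetal deaths become stillbirths when gestational age is at least
    ``thresholds.ga_weeks`` completed weeks, or — only when gestational age is
    missing — when birthweight meets the weight fallback; all other fetal
    deaths are miscarriages.  Live births, terminations and missing outcomes
    pass through unchanged.
    """
    if isinstance(record, PregnancyRecord):
        status = record.outcome_status
        ga = record.ga_weeks
        bw = record.birthweight_g
        rid = record.record_id
    else:
        status = record.get("outcome_status", "missing")
        ga = record.get("ga_weeks")
        bw = record.get("birthweight_g")
        rid = record.get("record_id", "<unknown>")
    ga = None if ga is None or (isinstance(ga, float) and np.isnan(ga)) or ga is pd.NA else ga
    bw = None if bw is None or (isinstance(bw, float) and np.isnan(bw)) or bw is pd.NA else bw

    for name, value in (("ga_weeks", ga), ("birthweight_g", bw)):
        if value is None:
            continue
        try:
            value = float(value)
        except (TypeError, ValueError):
            log.error("record %s: non-numeric %s %r", rid, name, value)
            raise ValueError(f"record {rid}: non-numeric {name}: {value!r}")
        if value < 0:
            log.error("record %s: negative %s %r", rid, name, value)
            raise ValueError(f"record {rid}: negative {name}: {value!r}")

    if status != "fetal_death":
        return status
    if ga is not None:
        return "stillbirth" if ga >= thresholds.ga_weeks else "miscarriage"
    if bw is not None and thresholds.weight_qualifies(bw):
        return "stillbirth"
    return "miscarriage"


def classify_outcomes(
    df: pd.DataFrame,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> pd.Series:
    """Vectorised :func:`classify_delivery_outcome` over a registry frame."""
    status = df["outcome_status"].astype("string")
    ga = pd.to_numeric(df["ga_weeks"], errors="coerce")
    bw = pd.to_numeric(df["birthweight_g"], errors="coerce")

    out = status.copy()
    fd = status == "fetal_death"
    ga_known = fd & ga.notna()
    weight_ok = (
        bw > thresholds.birthweight_g
        if thresholds.strict_gt_500g
        else bw >= thresholds.birthweight_g
    )
    stillbirth = (ga_known & (ga >= thresholds.ga_weeks)) | (
        fd & ga.isna() & weight_ok.fillna(False)
    )
    out[fd] = "miscarriage"
    out[stillbirth] = "stillbirth"
    return out.rename("outcome")


# ---------------------------------------------------------------------------
# Analysis set
# ---------------------------------------------------------------------------

def build_analysis_set(
    records: pd.DataFrame,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    *,
    n_screened: Optional[int] = None,
) -> AnalysisSet:
    """Apply the analysis filters and return included records plus the ledger.

    Excludes miscarriages (including fetal deaths below the stillbirth
    thresholds), terminations and missing delivery outcomes.  ``n_screened``
    defaults to the number of enrolled records when the screening count is
    not separately known.
    """
    enrolled = len(records)
    if enrolled == 0:
        ledger = EnrollmentLedger(
            screened=n_screened or 0,
            enrolled=0,
            excluded_by_reason={r: 0 for r in EXCLUSION_REASONS},
            included=0,
        )
        empty = records.copy()
        empty["outcome"] = pd.Series([], dtype="string")
        return AnalysisSet(records=empty, ledger=ledger)

    outcome = classify_outcomes(records, thresholds)
    excluded_by_reason = {
        reason: int((outcome == reason).sum()) for reason in EXCLUSION_REASONS
    }
    keep = outcome.isin(("live_birth", "stillbirth"))
    included = records[keep].copy()
    included["outcome"] = outcome[keep]
    included = included.reset_index(drop=True)

    # maceration is defined only for stillbirths
    inconsistent = (
        (included["outcome"] == "live_birth")
        & (included["maceration"].astype("string") != "not_applicable")
        if "maceration" in included.columns
        else pd.Series(False, index=included.index)
    )
    if inconsistent.any():
        log.warning(
            "%d live birth(s) carry a maceration status; expected not_applicable",
            int(inconsistent.sum()),
        )

    ledger = EnrollmentLedger(
        screened=enrolled if n_screened is None else n_screened,
        enrolled=enrolled,
        excluded_by_reason=excluded_by_reason,
        included=len(included),
    )
    return AnalysisSet(records=included, ledger=ledger)


# ---------------------------------------------------------------------------
# Derived covariates
# ---------------------------------------------------------------------------

def _cut_age(age: pd.Series) -> pd.Series:
    out = pd.Series(pd.NA, index=age.index, dtype="string")
    out[age < 20] = "<20"
    out[(age >= 20) & (age <= 35)] = "20-35"
    out[age > 35] = ">35"
    return out


def _cut_parity(parity: pd.Series) -> pd.Series:
    out = pd.Series(pd.NA, index=parity.index, dtype="string")
    out[parity == 0] = "0"
    out[(parity >= 1) & (parity <= 2)] = "1-2"
    out[parity > 2] = ">2"
    return out


def _cut_anc(anc: pd.Series) -> pd.Series:
    out = pd.Series(pd.NA, index=anc.index, dtype="string")
    out[anc == 0] = "0"
    out[(anc >= 1) & (anc <= 2)] = "1-2"
    out[anc >= 3] = ">=3"
    return out


def derive_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Append the report-table covariates to an analysis-set frame.

    Missing source fields propagate to missing covariates; each downstream
    table drops its own missing rows (denominators vary per table).
    """
    df = records.copy()
    ga = pd.to_numeric(df["ga_weeks"], errors="coerce")
    bw = pd.to_numeric(df["birthweight_g"], errors="coerce")

    df["preterm"] = pd.array(ga < PRETERM_GA_LIMIT, dtype="boolean")
    df.loc[ga.isna(), "preterm"] = pd.NA
    df["low_birthweight"] = pd.array(bw < LOW_BIRTHWEIGHT_LIMIT, dtype="boolean")
    df.loc[bw.isna(), "low_birthweight"] = pd.NA

    df["age_group"] = _cut_age(pd.to_numeric(df["maternal_age"], errors="coerce"))
    df["parity_group"] = _cut_parity(pd.to_numeric(df["parity"], errors="coerce"))
    df["anc_group"] = _cut_anc(pd.to_numeric(df["anc_visits"], errors="coerce"))

    prior = df["prior_pregnancy_live"].astype("string")
    prior_loss = pd.Series(pd.NA, index=df.index, dtype="boolean")
    prior_loss[prior == "no"] = True
    prior_loss[prior == "yes"] = False
    df["prior_loss"] = prior_loss

    pres = df["presentation"].astype("string")
    breech = pd.Series(pd.NA, index=df.index, dtype="boolean")
    breech[pres == "breech_transverse"] = True
    breech[pres == "cephalic"] = False
    df["breech"] = breech

    sex = df["sex"].astype("string")
    df.loc[sex == "unknown", "sex"] = pd.NA
    return df


def cluster_key(df: pd.DataFrame) -> pd.Series:
    """Globally unique cluster label (cluster ids are unique within site only)."""
    return (df["site"].astype(str) + "/" + df["cluster_id"].astype(str)).rename("cluster")
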