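"""Hierarchical assignment of one primary cause per stillbirth, and the
cause tabulations (overall/by site, by maceration, by maternal condition).

The hierarchy is evaluated in fixed order and the first satisfied level wins:

1. fetal trauma
2. major (visible) congenital anomaly
3. signs of maternal or fetal infection
4. any maternal/fetal condition associated with intrauterine asphyxia
   (configurable set; by default hypertensive disease/pre-eclampsia/eclampsia,
   antepartum hemorrhage, obstructed or prolonged labor, plus a generic
   other-asphyxia-condition flag)
5. gestational age below 32 completed weeks -> prematurity
6. unknown

Unknown/missing flags count as absent.  A stillbirth with missing gestational
age can never be attributed to prematurity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._round import round_half_up
from .registry_core import CONDITION_FLAGS, CONDITION_PREFIX, ConditionFlags

CAUSES = ("trauma", "congenital_anomaly", "infection", "asphyxia", "prematurity", "unknown")

PREMATURITY_GA_LIMIT = 32  # completed weeks; rule 5 requires ga < 32

DEFAULT_ASPHYXIA_CONDITIONS = frozenset(
    {
        "hypertensive_disease",
        "antepartum_hemorrhage",
        "obstructed_prolonged_labor",
        "other_asphyxia_condition",
    }
)

#: Maternal-condition columns of the condition cross-tabulation.
MATERNAL_CONDITION_COLUMNS = (
    "hypertensive_disease",
    "antepartum_hemorrhage",
    "obstructed_prolonged_labor",
    "breech_transverse",
    "maternal_infection",
)

MACERATION_COLUMNS = ("macerated", "non_macerated", "unknown")


@dataclass(frozen=True)
class CauseAssignment:
    """One cause per stillbirth plus the hierarchy level that fired."""

    cause: str
    rule_fired: int
    inputs_snapshot: dict

    def __post_init__(self) -> None:
        if self.cause != CAUSES[self.rule_fired - 1]:
            raise ValueError(f"rule {self.rule_fired} cannot yield cause {self.cause}")


def _flag_true(flags: Mapping, name: str) -> bool:
    value = flags.get(name)
    if value is pd.NA or value is None:
        return False
    if isinstance(value, str):
        return value.strip().lower() == "true"
    return bool(value)


def assign_cause(
    flags: Union[ConditionFlags, Mapping],
    ga_weeks: Optional[float] = None,
    asphyxia_conditions: Iterable[str] = DEFAULT_ASPHYXIA_CONDITIONS,
) -> CauseAssignment:
    """Assign the primary cause for one stillbirth.

    ``flags`` may be a :class:`ConditionFlags` or any mapping of flag name to
    ``True``/``False``/``None``/``"true"``/``"false"``; unknowns count as false.
    """
    if isinstance(flags, ConditionFlags):
        flags = flags.model_dump()
    asphyxia_conditions = tuple(asphyxia_conditions)
    unknown_cond = set(asphyxia_conditions) - set(CONDITION_FLAGS)
    if unknown_cond:
        raise ValueError(f"unknown asphyxia condition flags: {sorted(unknown_cond)}")

    if ga_weeks is pd.NA or (isinstance(ga_weeks, float) and np.isnan(ga_weeks)):
        ga_weeks = None

    snapshot = {name: flags.get(name) for name in CONDITION_FLAGS}
    snapshot["ga_weeks"] = ga_weeks
    snapshot["asphyxia_conditions"] = asphyxia_conditions

    if _flag_true(flags, "trauma"):
        rule = 1
    elif _flag_true(flags, "major_anomaly"):
        rule = 2
    elif _flag_true(flags, "maternal_infection") or _flag_true(flags, "fetal_infection"):
        rule = 3
    elif any(_flag_true(flags, name) for name in asphyxia_conditions):
        rule = 4
    elif ga_weeks is not None and ga_weeks < PREMATURITY_GA_LIMIT:
        rule = 5
    else:
        rule = 6
    return CauseAssignment(cause=CAUSES[rule - 1], rule_fired=rule, inputs_snapshot=snapshot)


def assign_causes(
    stillbirths: pd.DataFrame,
    asphyxia_conditions: Iterable[str] = DEFAULT_ASPHYXIA_CONDITIONS,
) -> pd.DataFrame:
    """Vectorised classifier over a frame of stillbirth rows.

    Expects the ``cond_*`` flag columns and ``ga_weeks``; returns a frame with
    ``record_id`` (when present), ``cause`` and ``rule_fired`` aligned to the
    input index.
    """
    asphyxia_conditions = tuple(asphyxia_conditions)
    unknown_cond = set(asphyxia_conditions) - set(CONDITION_FLAGS)
    if unknown_cond:
        raise ValueError(f"unknown asphyxia condition flags: {sorted(unknown_cond)}")

    def truthy(col: str) -> np.ndarray:
        series = stillbirths[CONDITION_PREFIX + col]
        if series.dtype == object or pd.api.types.is_string_dtype(series):
            return (series.astype("string").str.lower() == "true").to_numpy()
        return series.fillna(False).to_numpy(dtype=bool)

    ga = pd.to_numeric(stillbirths["ga_weeks"], errors="coerce").to_numpy(dtype=float)

    n = len(stillbirths)
    rule = np.full(n, 6, dtype=int)
    premature = ~np.isnan(ga) & (ga < PREMATURITY_GA_LIMIT)
    rule[premature] = 5
    asph = np.zeros(n, dtype=bool)
    for name in asphyxia_conditions:
        asph |= truthy(name)
    rule[asph] = 4
    rule[truthy("maternal_infection") | truthy("fetal_infection")] = 3
    rule[truthy("major_anomaly")] = 2
    rule[truthy("trauma")] = 1

    out = pd.DataFrame(index=stillbirths.index)
    if "record_id" in stillbirths.columns:
        out["record_id"] = stillbirths["record_id"]
    out["cause"] = pd.Categorical.from_codes(rule - 1, categories=list(CAUSES))
    out["rule_fired"] = rule
    return out


# ---------------------------------------------------------------------------
# Tabulations
# ---------------------------------------------------------------------------

def _cause_counts(causes: pd.Series) -> pd.Series:
    counts = causes.value_counts()
    return pd.Series({c: int(counts.get(c, 0)) for c in CAUSES})


def _pct_column(counts: pd.Series, total: int) -> pd.Series:
    if total == 0:
        return pd.Series(0.0, index=counts.index)
    return counts.map(lambda n: round_half_up(100.0 * n / total, 1))


def tabulate_causes(
    assignments: pd.DataFrame,
    strata: Optional[str] = None,
) -> pd.DataFrame:
    """Tidy cause table: counts and percentages per stratum plus a total column.

    ``assignments`` needs a ``cause`` column and, when ``strata`` is given,
    that stratum column (e.g. ``site``).  Percentages are computed on the
    stratum N and rounded half-up to one decimal.
    """
    if strata is not None and strata not in assignments.columns:
        raise ValueError(f"stratum column {strata!r} not in assignments")

    blocks = []
    if strata is not None:
        for label, group in assignments.groupby(strata, observed=True, sort=True):
            counts = _cause_counts(group["cause"])
            blocks.append((str(label), counts))
    counts_total = _cause_counts(assignments["cause"])
    blocks.append(("total", counts_total))

    rows = []
    for label, counts in blocks:
        total = int(counts.sum())
        pct = _pct_column(counts, total)
        for cause in CAUSES:
            rows.append(
                {
                    "stratum": label,
                    "cause": cause,
                    "n": int(counts[cause]),
                    "pct": float(pct[cause]),
                    "stratum_n": total,
                }
            )
    return pd.DataFrame(rows)


def crosstab_cause(assignments: pd.DataFrame, by: str) -> pd.DataFrame:
    """Cause-by-column contingency table, tidy format.

    ``by="maceration"`` uses the mutually exclusive maceration status columns;
    ``by="maternal_condition"`` uses the (non-exclusive) maternal-condition
    flags — one stillbirth may appear under several condition columns, so
    column Ns may sum above the stillbirth total.
    """
    if by == "maceration":
        column_masks = {
            col: (assignments["maceration"].astype("string") == col)
            for col in MACERATION_COLUMNS
        }
    elif by == "maternal_condition":
        column_masks = {}
        for col in MATERNAL_CONDITION_COLUMNS:
            series = assignments[CONDITION_PREFIX + col]
            if pd.api.types.is_string_dtype(series) or series.dtype == object:
                mask = series.astype("string").str.lower() == "true"
            else:
                mask = series.fillna(False).astype(bool)
            column_masks[col] = mask
    else:
        raise ValueError(f"unsupported cross-tab axis: {by!r}")

    rows = []
    for label, mask in column_masks.items():
        counts = _cause_counts(assignments.loc[mask.fillna(False), "cause"])
        total = int(counts.sum())
        pct = _pct_column(counts, total)
        for cause in CAUSES:
            rows.append(
                {
                    "column": label,
                    "cause": cause,
                    "n": int(counts[cause]),
                    "pct": float(pct[cause]),
                    "column_n": total,
                }
            )
    return pd.DataFrame(rows)


def assignments_from_counts(counts: Mapping[str, int], **extra_columns) -> pd.DataFrame:
    """Expand a cause -> count mapping into per-record assignment rows.

    Convenience for running the tabulations on published table counts.
    """
    causes: list[str] = []
    for cause, n in counts.items():
        if cause not in CAUSES:
            raise ValueError(f"unknown cause {cause!r}")
        causes.extend([cause] * int(n))
    df = pd.DataFrame({"cause": pd.Categorical(causes, categories=list(CAUSES))})
    for name, value in extra_columns.items():
        df[name] = value
    return df
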