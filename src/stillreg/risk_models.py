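"""Relative risks of stillbirth under a log-link binomial model.

Point estimates come from a marginal log-binomial fit (one exposure at a
time, matching the per-row report tables); variances are cluster-robust
sandwich estimates from generalized estimating equations.  When the
log-binomial fit fails to converge the standard fallback is a log-link
Poisson model with the same sandwich variance, flagged in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm
import statsmodels.api as sm

from .registry_core import cluster_key

log = logging.getLogger(__name__)

CLUSTER_UNITS = ("cluster", "site")
WORKING_CORRELATIONS = ("independence", "exchangeable")

#: Reference levels for the standard derived covariates.
DEFAULT_REFERENCES: Mapping[str, str] = {
    "preterm": "false",
    "low_birthweight": "false",
    "sex": "female",
    "multiple": "false",
    "breech": "false",
    "age_group": "20-35",
    "education": "university_plus",
    "parity_group": "1-2",
    "prior_loss": "false",
    "anc_group": ">=3",
    "attendant": "physician",
    "location": "hospital",
    "mode": "vaginal",
}

_Z95 = norm.ppf(0.975)


@dataclass
class RiskEstimate:
    """Relative risk for one exposure level against its reference."""

    exposure: str
    level: str
    reference: str
    rr: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_exposed_cases: int
    n_exposed: int
    n_ref_cases: int
    n_ref: int
    model: str = "crude"
    cluster_unit: Optional[str] = None
    working_correlation: Optional[str] = None
    flags: Tuple[str, ...] = ()

    @property
    def is_reference(self) -> bool:
        return self.level == self.reference

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "level": self.level,
            "reference": self.reference,
            "rr": self.rr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_exposed_cases": self.n_exposed_cases,
            "n_exposed": self.n_exposed,
            "n_ref_cases": self.n_ref_cases,
            "n_ref": self.n_ref,
            "model": self.model,
            "cluster_unit": self.cluster_unit,
            "working_correlation": self.working_correlation,
            "flags": ";".join(self.flags),
        }


def crude_rr(
    a: int,
    b: int,
    c: int,
    d: int,
    *,
    exposure: str = "exposure",
    level: str = "exposed",
    reference: str = "reference",
    continuity_correction: bool = False,
) -> RiskEstimate:
    """Crude relative risk from a 2x2 table.

    ``a``/``b`` are cases/non-cases among the exposed, ``c``/``d`` among the
    reference group: ``rr = (a/(a+b)) / (c/(c+d))`` with a log-scale Wald 95%
    interval.  A zero case count in either arm yields a flagged estimate
    unless the optional 0.5 continuity correction is enabled.
    """
    for name, value in (("a", a), ("b", b), ("c", c), ("d", d)):
        if value < 0:
            raise ValueError(f"cell {name} is negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("both row totals must be positive")

    flags: List[str] = []
    aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    if a == 0 or c == 0:
        if continuity_correction:
            aa, bb, cc, dd = aa + 0.5, bb + 0.5, cc + 0.5, dd + 0.5
            flags.append("continuity_corrected")
        else:
            flags.append("zero_cell")
            rr = float("inf") if c == 0 and a > 0 else 0.0 if a == 0 and c > 0 else float("nan")
            return RiskEstimate(
                exposure=exposure, level=level, reference=reference,
                rr=rr, ci_low=None, ci_high=None,
                n_exposed_cases=a, n_exposed=a + b, n_ref_cases=c, n_ref=c + d,
                model="crude", flags=tuple(flags),
            )

    risk_exposed = aa / (aa + bb)
    risk_ref = cc / (cc + dd)
    rr = risk_exposed / risk_ref
    se = np.sqrt(1.0 / aa - 1.0 / (aa + bb) + 1.0 / cc - 1.0 / (cc + dd))
    ci_low = float(np.exp(np.log(rr) - _Z95 * se))
    ci_high = float(np.exp(np.log(rr) + _Z95 * se))
    return RiskEstimate(
        exposure=exposure, level=level, reference=reference,
        rr=float(rr), ci_low=ci_low, ci_high=ci_high,
        n_exposed_cases=a, n_exposed=a + b, n_ref_cases=c, n_ref=c + d,
        model="crude", flags=tuple(flags),
    )


def _level_labels(series: pd.Series) -> pd.Series:
    """Exposure levels as lowercase strings (booleans -> 'true'/'false')."""
    def label(v):
        if pd.isna(v):
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return "true" if v else "false"
        return str(v).strip().lower() if str(v).strip().lower() in ("true", "false") else str(v)
    return series.map(label).astype("string")


def cluster_rr(
    records: pd.DataFrame,
    exposure: str,
    reference_level: Optional[str] = None,
    cluster_unit: str = "cluster",
    working_correlation: str = "independence",
    outcome_col: str = "outcome",
) -> List[RiskEstimate]:
    """Log-binomial RR per exposure level with a cluster-robust 95% interval.

    Rows with a missing exposure are dropped (table-wise denominators).
    Returns one :class:`RiskEstimate` per level including the reference (RR
    fixed at 1.0, no interval).  Levels with a zero case or non-case margin
    are flagged ``separation`` and receive no estimate.
    """
    if cluster_unit not in CLUSTER_UNITS:
        raise ValueError(f"unknown cluster unit {cluster_unit!r}")
    if working_correlation not in WORKING_CORRELATIONS:
        raise ValueError(f"unknown working correlation {working_correlation!r}")
    if exposure not in records.columns:
        raise ValueError(f"exposure column {exposure!r} not found")

    levels_series = _level_labels(records[exposure])
    keep = levels_series.notna()
    df = records[keep]
    levels_series = levels_series[keep]
    y = (df[outcome_col].astype(str) == "stillbirth").to_numpy(dtype=float)

    levels = sorted(levels_series.unique())
    if len(levels) < 2:
        raise ValueError(f"exposure {exposure!r} is constant ({levels})")

    if reference_level is None:
        reference_level = DEFAULT_REFERENCES.get(exposure)
    if reference_level is None or reference_level not in levels:
        raise ValueError(
            f"reference level for {exposure!r} must be one of {levels}, "
            f"got {reference_level!r}"
        )

    groups = cluster_key(df) if cluster_unit == "cluster" else df["site"].astype(str)
    if groups.nunique() < 2:
        raise ValueError("cluster-robust variance requires >=2 clusters")

    counts = {}
    for lvl in levels:
        mask = (levels_series == lvl).to_numpy()
        counts[lvl] = (int(y[mask].sum()), int(mask.sum()))
    ref_cases, ref_n = counts[reference_level]

    def make_estimate(lvl, rr, lo, hi, model, flags=()):
        cases, n = counts[lvl]
        return RiskEstimate(
            exposure=exposure, level=lvl, reference=reference_level,
            rr=rr, ci_low=lo, ci_high=hi,
            n_exposed_cases=cases, n_exposed=n,
            n_ref_cases=ref_cases, n_ref=ref_n,
            model=model, cluster_unit=cluster_unit,
            working_correlation=working_correlation, flags=tuple(flags),
        )

    flagged = {}
    model_levels = []
    for lvl in levels:
        cases, n = counts[lvl]
        if cases == 0 or cases == n:
            flagged[lvl] = "separation"
        else:
            model_levels.append(lvl)
    if reference_level in flagged:
        # no usable baseline risk: flag every non-reference level
        out = [make_estimate(reference_level, 1.0, None, None, "cluster_gee",
                             ("reference", flagged[reference_level]))]
        for lvl in levels:
            if lvl != reference_level:
                out.append(make_estimate(lvl, float("nan"), None, None,
                                         "cluster_gee", ("separation",)))
        return out

    nonref = [l for l in model_levels if l != reference_level]
    exog_levels = nonref
    X = np.column_stack(
        [np.ones(len(df))]
        + [(levels_series == lvl).to_numpy(dtype=float) for lvl in exog_levels]
    )
    in_model = levels_series.isin(model_levels).to_numpy()

    start = np.empty(1 + len(exog_levels))
    start[0] = np.log(ref_cases / ref_n)
    for i, lvl in enumerate(exog_levels):
        cases, n = counts[lvl]
        start[1 + i] = np.log((cases / n) / (ref_cases / ref_n))

    cov_struct = (
        sm.cov_struct.Independence()
        if working_correlation == "independence"
        else sm.cov_struct.Exchangeable()
    )

    def fit(family):
        import warnings

        from statsmodels.tools.sm_exceptions import DomainWarning

        with warnings.catch_warnings():
            # the log link is a deliberate choice for RR estimation
            warnings.simplefilter("ignore", DomainWarning)
            return _fit_inner(family)

    def _fit_inner(family):
        model = sm.GEE(
            y[in_model],
            X[in_model],
            groups=groups.to_numpy()[in_model],
            family=family,
            cov_struct=(
                sm.cov_struct.Independence()
                if working_correlation == "independence"
                else sm.cov_struct.Exchangeable()
            ),
        )
        return model.fit(start_params=start, maxiter=200, ctol=1e-10)

    fallback = False
    try:
        with np.errstate(all="ignore"):
            result = fit(sm.families.Binomial(link=sm.families.links.Log()))
        if not np.all(np.isfinite(result.params)) or not np.all(
            np.isfinite(result.bse)
        ):
            raise ValueError("non-finite log-binomial estimates")
    except Exception as exc:  # noqa: BLE001 - any fit failure triggers fallback
        log.warning(
            "log-binomial GEE failed for %s (%s); falling back to Poisson",
            exposure, exc,
        )
        fallback = True
        with np.errstate(all="ignore"):
            result = fit(sm.families.Poisson())

    model_name = "cluster_gee_poisson_fallback" if fallback else "cluster_gee"
    flags = ("poisson_fallback",) if fallback else ()

    out = [make_estimate(reference_level, 1.0, None, None, model_name,
                         ("reference",) + flags)]
    for i, lvl in enumerate(exog_levels):
        beta = float(result.params[1 + i])
        se = float(result.bse[1 + i])
        out.append(
            make_estimate(
                lvl,
                float(np.exp(beta)),
                float(np.exp(beta - _Z95 * se)),
                float(np.exp(beta + _Z95 * se)),
                model_name,
                flags,
            )
        )
    for lvl, reason in flagged.items():
        out.append(make_estimate(lvl, float("nan"), None, None, model_name,
                                 (reason,) + flags))
    order = {lvl: i for i, lvl in enumerate(levels)}
    out.sort(key=lambda e: order[e.level])
    return out


def risk_table(
    records: pd.DataFrame,
    exposures: Sequence[str],
    cluster_unit: str = "cluster",
    working_correlation: str = "independence",
) -> pd.DataFrame:
    """Tidy table of cluster-robust RRs over several exposures."""
    rows = []
    for exposure in exposures:
        try:
            for est in cluster_rr(
                records, exposure,
                cluster_unit=cluster_unit,
                working_correlation=working_correlation,
            ):
                rows.append(est.to_dict())
        except ValueError as exc:
            log.warning("skipping exposure %s: %s", exposure, exc)
    return pd.DataFrame(rows)
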