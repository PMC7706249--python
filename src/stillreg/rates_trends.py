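"""Stillbirth rates per 1000 births with confidence intervals, by arbitrary
strata (site, year, cluster), plus the continuing-cluster restriction used
for yearly trend series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from ._round import round_half_up

log = logging.getLogger(__name__)

CI_METHODS = ("wilson", "cluster_robust")


@dataclass
class RateEstimate:
    """Stillbirths per 1000 births for one stratum."""

    n_stillbirths: int
    n_births: int
    stratum: dict = field(default_factory=dict)
    rate_per_1000: float = float("nan")
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_method: Optional[str] = None
    undefined: bool = False

    @property
    def rate_display(self) -> float:
        """Rate rounded half-up to one decimal, as printed in report tables."""
        return round_half_up(self.rate_per_1000, 1)

    def to_dict(self) -> dict:
        out = dict(self.stratum)
        out.update(
            n_stillbirths=self.n_stillbirths,
            n_births=self.n_births,
            rate_per_1000=self.rate_per_1000,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            ci_method=self.ci_method,
            undefined=self.undefined,
        )
        return out


def stillbirth_rate(
    n_stillbirths: int,
    n_births: int,
    stratum: Optional[dict] = None,
) -> RateEstimate:
    """Exact stillbirth rate per 1000 births for one stratum.

    A zero denominator yields an undefined-rate flag rather than an error;
    a numerator exceeding the denominator is rejected.
    """
    n_stillbirths = int(n_stillbirths)
    n_births = int(n_births)
    if n_stillbirths < 0 or n_births < 0:
        raise ValueError("counts must be non-negative")
    if n_stillbirths > n_births:
        raise ValueError(
            f"n_stillbirths ({n_stillbirths}) exceeds n_births ({n_births})"
        )
    est = RateEstimate(
        n_stillbirths=n_stillbirths,
        n_births=n_births,
        stratum=dict(stratum or {}),
    )
    if n_births == 0:
        est.undefined = True
        return est
    est.rate_per_1000 = 1000.0 * n_stillbirths / n_births
    return est


def rate_ci(
    n_stillbirths: int,
    n_births: int,
    method: str = "wilson",
    clusters: Optional[Sequence[Tuple[int, int]]] = None,
    alpha: float = 0.05,
) -> Tuple[float, float]:
    """95% interval for a stillbirth rate, per 1000 births.

    ``wilson`` is the binomial score interval.  ``cluster_robust`` uses the
    between-cluster empirical variance of the ratio estimator (normal
    approximation) and needs per-cluster ``(n_stillbirths, n_births)`` pairs;
    with fewer than two clusters it falls back to Wilson with a warning.
    """
    if method not in CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}")
    if n_births == 0:
        return (float("nan"), float("nan"))
    if n_stillbirths > n_births:
        raise ValueError("n_stillbirths exceeds n_births")

    if method == "cluster_robust":
        if clusters is None or len(clusters) < 2:
            log.warning(
                "cluster_robust CI requires >=2 clusters; falling back to wilson"
            )
            return rate_ci(n_stillbirths, n_births, method="wilson", alpha=alpha)
        s = np.asarray([c[0] for c in clusters], dtype=float)
        b = np.asarray([c[1] for c in clusters], dtype=float)
        if int(s.sum()) != int(n_stillbirths) or int(b.sum()) != int(n_births):
            raise ValueError("cluster counts do not sum to the totals")
        k = len(s)
        rate = s.sum() / b.sum()
        # ratio-estimator variance with the usual k/(k-1) small-sample factor
        var = (k / (k - 1)) * np.sum((s - rate * b) ** 2) / b.sum() ** 2
        z = norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        low = max(0.0, rate - half) * 1000.0
        high = min(1.0, rate + half) * 1000.0
        return (float(low), float(high))

    low, high = proportion_confint(n_stillbirths, n_births, alpha=alpha, method="wilson")
    low = 0.0 if n_stillbirths == 0 else max(0.0, float(low))
    high = 1.0 if n_stillbirths == n_births else min(1.0, float(high))
    return (low * 1000.0, high * 1000.0)


def _with_ci(
    est: RateEstimate,
    ci_method: str,
    clusters: Optional[Sequence[Tuple[int, int]]] = None,
) -> RateEstimate:
    if est.undefined:
        est.ci_method = ci_method
        return est
    est.ci_low, est.ci_high = rate_ci(
        est.n_stillbirths, est.n_births, method=ci_method, clusters=clusters
    )
    est.ci_method = ci_method
    return est


def rate_table(
    records: pd.DataFrame,
    by: Sequence[str],
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """Tidy rate table grouped by ``by`` columns over an analysis set.

    ``records`` must carry an ``outcome`` column (``stillbirth``/``live_birth``).
    For ``cluster_robust`` the per-group cluster counts come from
    ``site``/``cluster_id``.
    """
    rows = []
    for labels, group in records.groupby(list(by), observed=True, sort=True):
        if not isinstance(labels, tuple):
            labels = (labels,)
        stratum = dict(zip(by, (str(l) for l in labels)))
        est = stillbirth_rate(
            int((group["outcome"] == "stillbirth").sum()), len(group), stratum
        )
        clusters = None
        if ci_method == "cluster_robust":
            agg = group.groupby(["site", "cluster_id"], observed=True).agg(
                s=("outcome", lambda o: int((o == "stillbirth").sum())),
                b=("outcome", "size"),
            )
            clusters = list(zip(agg["s"], agg["b"]))
        rows.append(_with_ci(est, ci_method, clusters).to_dict())
    return pd.DataFrame(rows)


def select_continuing_clusters(
    records: pd.DataFrame,
    start_year: int = 2010,
    end_year: int = 2018,
    min_births_per_year: int = 1,
) -> Set[Tuple[str, str]]:
    """Clusters with at least ``min_births_per_year`` included births in every
    calendar year of the span — the restriction for yearly trend series."""
    if len(records) == 0:
        return set()
    years = range(start_year, end_year + 1)
    counts = (
        records.groupby(["site", "cluster_id", "year"], observed=True)
        .size()
        .unstack("year", fill_value=0)
    )
    for y in years:
        if y not in counts.columns:
            return set()
    ok = (counts[list(years)] >= min_births_per_year).all(axis=1)
    return {(str(site), str(cid)) for site, cid in counts.index[ok]}


def yearly_rate_series(
    records: pd.DataFrame,
    continuing_only: bool = False,
    ci_method: str = "wilson",
    start_year: Optional[int] = None,
    end_year: Optional[int] = None,
) -> pd.DataFrame:
    """One rate per (site, year) over the full year span.

    Site-years with zero births are reported with the undefined flag rather
    than dropped.  With ``continuing_only`` the denominator is restricted to
    clusters active in every year of the span.
    """
    df = records
    if len(df) == 0:
        return pd.DataFrame(
            columns=[
                "site", "year", "n_stillbirths", "n_births",
                "rate_per_1000", "ci_low", "ci_high", "ci_method", "undefined",
            ]
        )
    years = pd.to_numeric(df["year"])
    start_year = int(years.min()) if start_year is None else start_year
    end_year = int(years.max()) if end_year is None else end_year

    if continuing_only:
        keep = select_continuing_clusters(df, start_year, end_year)
        mask = [
            (str(s), str(c)) in keep
            for s, c in zip(df["site"], df["cluster_id"])
        ]
        df = df[pd.Series(mask, index=df.index)]

    rows = []
    sites = sorted(records["site"].astype(str).unique())
    for site in sites:
        site_df = df[df["site"].astype(str) == site]
        for year in range(start_year, end_year + 1):
            group = site_df[pd.to_numeric(site_df["year"]) == year]
            est = stillbirth_rate(
                int((group["outcome"] == "stillbirth").sum()),
                len(group),
                {"site": site, "year": year},
            )
            clusters = None
            if ci_method == "cluster_robust" and len(group):
                agg = group.groupby(["site", "cluster_id"], observed=True).agg(
                    s=("outcome", lambda o: int((o == "stillbirth").sum())),
                    b=("outcome", "size"),
                )
                clusters = list(zip(agg["s"], agg["b"]))
            rows.append(_with_ci(est, ci_method, clusters).to_dict())
    return pd.DataFrame(rows)
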