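"""Seeded synthetic registry generator with a known-truth ledger.

Every pipeline stage can be exercised without study data: stillbirth is
sampled from a multiplicative (log-link) risk model combining a per-site
baseline, a yearly trend, a lognormal cluster random effect and per-covariate
relative risks, so the configured RRs are exactly the estimand of
:mod:`stillreg.risk_models` and the configured baselines are the estimand of
:mod:`stillreg.rates_trends`.  Condition flags are sampled conditional on the
outcome, maceration is assigned to stillbirths, and exclusion records
(miscarriage / termination / missing outcome) are injected at configured
probabilities.

Same seed + same config => byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cause_of_death import CAUSES, DEFAULT_ASPHYXIA_CONDITIONS, assign_cause, assign_causes
from .registry_core import (
    CONDITION_FLAGS,
    CONDITION_PREFIX,
    REGISTRY_COLUMNS,
    SITES,
    _INT_COLUMNS,
)

#: Record fields a covariate spec may drive (everything else gets a default).
COVARIATE_FIELDS = (
    "maternal_age",
    "education",
    "parity",
    "prior_pregnancy_live",
    "anc_visits",
    "attendant",
    "location",
    "mode",
    "ga_weeks",
    "sex",
    "multiple",
    "presentation",
)

#: Values used for fields without a covariate spec.
FIELD_DEFAULTS = {
    "maternal_age": 27,
    "education": "primary",
    "parity": 1,
    "prior_pregnancy_live": "yes",
    "anc_visits": 3,
    "attendant": "physician",
    "location": "hospital",
    "mode": "vaginal",
    "ga_weeks": 39,
    "sex": "unknown",
    "multiple": False,
    "presentation": "cephalic",
}

_PROB_TOL = 1e-9


class LevelSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    value: Union[bool, int, float, str]
    prob: float = Field(ge=0.0, le=1.0)
    rr: float = Field(default=1.0, gt=0.0)


class CovariateSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    field_name: str = Field(alias="field")
    levels: List[LevelSpec]

    @model_validator(mode="after")
    def _check(self) -> "CovariateSpec":
        if self.field_name not in COVARIATE_FIELDS:
            raise ValueError(f"unsupported covariate field {self.field_name!r}")
        total = sum(l.prob for l in self.levels)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{self.field_name}: level probabilities sum to {total}")
        if self.field_name == "ga_weeks":
            for lvl in self.levels:
                if not (20 <= float(lvl.value) <= 50):
                    # stillbirths must stay above the miscarriage threshold
                    raise ValueError("ga_weeks covariate levels must lie in [20, 50]")
        return self

    @property
    def mean_rr(self) -> float:
        return sum(l.prob * l.rr for l in self.levels)


class ConditionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    p_stillbirth: float = Field(ge=0.0, le=1.0)
    p_livebirth: float = Field(ge=0.0, le=1.0)
    p_unknown: float = Field(default=0.0, ge=0.0, le=1.0)


class MacerationSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    macerated: float = Field(ge=0.0, le=1.0)
    non_macerated: float = Field(ge=0.0, le=1.0)
    unknown: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "MacerationSpec":
        total = self.macerated + self.non_macerated + self.unknown
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"maceration probabilities sum to {total}")
        return self


class ExclusionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    miscarriage: float = Field(default=0.0, ge=0.0, le=1.0)
    termination: float = Field(default=0.0, ge=0.0, le=1.0)
    missing: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "ExclusionSpec":
        if self.miscarriage + self.termination + self.missing >= 1.0:
            raise ValueError("exclusion probabilities must sum below 1")
        return self


class SiteSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    n_clusters: int = Field(ge=1)
    births_per_cluster_per_year: int = Field(ge=1)
    start_year: int = 2010
    end_year: int = 2018
    baseline_stillbirth_prob: float = Field(gt=0.0, lt=0.5)
    yearly_trend: float = Field(default=1.0, gt=0.0)
    cluster_sd: float = Field(default=0.0, ge=0.0)
    maceration: MacerationSpec = Field(
        default_factory=lambda: MacerationSpec(macerated=0.3, non_macerated=0.65, unknown=0.05)
    )
    cluster_entry_years: Optional[List[int]] = None

    @model_validator(mode="after")
    def _check(self) -> "SiteSpec":
        if self.name not in SITES:
            raise ValueError(f"site name must be one of {SITES}")
        if self.end_year < self.start_year:
            raise ValueError("end_year before start_year")
        if self.cluster_entry_years is not None:
            if len(self.cluster_entry_years) != self.n_clusters:
                raise ValueError("cluster_entry_years length must equal n_clusters")
            for y in self.cluster_entry_years:
                if not (self.start_year <= y <= self.end_year):
                    raise ValueError("cluster entry year outside the site span")
        return self

    def entry_years(self) -> List[int]:
        return list(self.cluster_entry_years or [self.start_year] * self.n_clusters)


class SyntheticConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sites: List[SiteSpec]
    covariates: List[CovariateSpec] = Field(default_factory=list)
    conditions: Dict[str, ConditionSpec] = Field(default_factory=dict)
    exclusions: ExclusionSpec = Field(default_factory=ExclusionSpec)
    seed: Optional[int] = None
    #: None -> reject any record whose implied risk exceeds 1; a float caps
    #: the per-record risk instead (slight, documented bias on expectations).
    risk_cap: Optional[float] = Field(default=None, gt=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        for flag in self.conditions:
            if flag not in CONDITION_FLAGS:
                raise ValueError(f"unknown condition flag {flag!r}")
        seen = set()
        for cov in self.covariates:
            if cov.field_name in seen:
                raise ValueError(f"duplicate covariate {cov.field_name!r}")
            seen.add(cov.field_name)
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise ValueError("duplicate site names")
        inflation = math.prod(c.mean_rr for c in self.covariates)
        for site in self.sites:
            worst_trend = max(
                site.yearly_trend ** (y - site.start_year)
                for y in range(site.start_year, site.end_year + 1)
            )
            implied = (
                site.baseline_stillbirth_prob
                * worst_trend
                * math.exp(site.cluster_sd**2 / 2.0)
                * inflation
            )
            if not (0.0 < implied < 0.5):
                raise ValueError(
                    f"site {site.name}: implied stillbirth risk {implied:.3f} "
                    "outside (0, 0.5)"
                )
        return self

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "SyntheticConfig":
        with open(source, "r", encoding="utf-8") as fh:
            return cls.model_validate(json.load(fh))


def default_config() -> SyntheticConfig:
    """The bundled illustrative multi-site configuration."""
    text = resources.files("stillreg").joinpath("data/gn2018.json").read_text("utf-8")
    return SyntheticConfig.model_validate(json.loads(text))


def default_config_path() -> Path:
    return Path(str(resources.files("stillreg").joinpath("data/gn2018.json")))


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

@dataclass
class TruthLedger:
    """Per-record latents plus config-implied expectations."""

    per_record: pd.DataFrame
    counts: dict
    continuing_clusters: Set[Tuple[str, str]]
    expected: dict

    def summary(self) -> dict:
        return {
            "counts": self.counts,
            "continuing_clusters": sorted(list(c) for c in self.continuing_clusters),
            "expected": self.expected,
        }


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_registry(
    config: SyntheticConfig,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, TruthLedger]:
    """Generate one record per birth plus the truth ledger.

    ``seed`` overrides ``config.seed``; one of the two must be set.  When
    ``config.risk_cap`` is unset, any record whose implied risk exceeds 1 is
    rejected with the offending covariate combination reported.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (argument or config.seed)")
    rng = np.random.default_rng(int(seed))

    frames = []
    truth_frames = []
    for site in config.sites:
        df, truth = _generate_site(site, config, rng)
        frames.append(df)
        truth_frames.append(truth)

    records = pd.concat(frames, ignore_index=True)[list(REGISTRY_COLUMNS)]
    truth = pd.concat(truth_frames, ignore_index=True)

    # intended cause under the default hierarchy, for stillbirth rows
    sb = records[truth["true_outcome"] == "stillbirth"]
    truth["intended_cause"] = pd.Series(pd.NA, index=truth.index, dtype="string")
    if len(sb):
        causes = assign_causes(sb)
        truth.loc[sb.index, "intended_cause"] = causes["cause"].astype("string")

    counts = {
        "enrolled": int(len(truth)),
        "miscarriage": int((truth["status"] == "miscarriage").sum()),
        "termination": int((truth["status"] == "termination").sum()),
        "missing": int((truth["status"] == "missing").sum()),
        "included": int((truth["status"] == "included").sum()),
        "live_births": int((truth["true_outcome"] == "live_birth").sum()),
        "stillbirths": int((truth["true_outcome"] == "stillbirth").sum()),
        "by_site": {
            site: {
                "included": int(
                    ((truth["site"] == site) & (truth["status"] == "included")).sum()
                ),
                "stillbirths": int(
                    (
                        (truth["site"] == site)
                        & (truth["true_outcome"] == "stillbirth")
                    ).sum()
                ),
            }
            for site in (s.name for s in config.sites)
        },
    }

    global_start = min(s.start_year for s in config.sites)
    global_end = max(s.end_year for s in config.sites)
    continuing: Set[Tuple[str, str]] = set()
    for site in config.sites:
        for idx, entry in enumerate(site.entry_years()):
            if (
                site.start_year <= global_start
                and site.end_year >= global_end
                and entry <= global_start
            ):
                continuing.add((site.name, _cluster_id(idx)))

    ledger = TruthLedger(
        per_record=truth,
        counts=counts,
        continuing_clusters=continuing,
        expected=truth_report(config),
    )
    return records, ledger


def _cluster_id(index: int) -> str:
    return f"c{index + 1:02d}"


def _generate_site(
    site: SiteSpec,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    bpcy = site.births_per_cluster_per_year
    cluster_idx_parts = []
    year_parts = []
    for idx, entry in enumerate(site.entry_years()):
        years = np.arange(entry, site.end_year + 1)
        cluster_idx_parts.append(np.full(len(years) * bpcy, idx))
        year_parts.append(np.repeat(years, bpcy))
    cluster_idx = np.concatenate(cluster_idx_parts)
    year = np.concatenate(year_parts)
    n = len(year)

    cluster_effects = rng.normal(0.0, site.cluster_sd, site.n_clusters)

    values: Dict[str, np.ndarray] = {}
    risk = (
        site.baseline_stillbirth_prob
        * site.yearly_trend ** (year - site.start_year)
        * np.exp(cluster_effects[cluster_idx])
    )
    for cov in config.covariates:
        probs = np.array([l.prob for l in cov.levels])
        picks = rng.choice(len(cov.levels), size=n, p=probs / probs.sum())
        values[cov.field_name] = np.array([l.value for l in cov.levels], dtype=object)[picks]
        risk = risk * np.array([l.rr for l in cov.levels])[picks]

    if config.risk_cap is None:
        over = risk > 1.0
        if over.any():
            worst = int(np.argmax(risk))
            combo = {f: values[f][worst] for f in values}
            raise ValueError(
                f"site {site.name}: implied risk {risk[worst]:.3f} > 1 for "
                f"covariate combination {combo}"
            )
    else:
        risk = np.minimum(risk, config.risk_cap)

    u_excl = rng.random(n)
    p_mis = config.exclusions.miscarriage
    p_term = p_mis + config.exclusions.termination
    p_miss = p_term + config.exclusions.missing
    status = np.full(n, "included", dtype=object)
    status[u_excl < p_miss] = "missing"
    status[u_excl < p_term] = "termination"
    status[u_excl < p_mis] = "miscarriage"
    included = status == "included"

    stillbirth = included & (rng.random(n) < risk)

    for fname in COVARIATE_FIELDS:
        if fname not in values:
            values[fname] = np.full(n, FIELD_DEFAULTS[fname], dtype=object)

    ga = values["ga_weeks"].astype(float)
    bw_noise = rng.normal(0.0, 300.0, n)
    bw = np.clip(np.round(3300.0 - 170.0 * (40.0 - ga) + bw_noise), 100, 8000)

    flag_values: Dict[str, np.ndarray] = {}
    for flag in CONDITION_FLAGS:
        spec = config.conditions.get(flag)
        if spec is None:
            flag_values[flag] = np.zeros(n, dtype=bool)
            flag_unknown = np.zeros(n, dtype=bool)
        else:
            p = np.where(stillbirth, spec.p_stillbirth, spec.p_livebirth)
            flag_values[flag] = rng.random(n) < p
            flag_unknown = (
                rng.random(n) < spec.p_unknown
                if spec.p_unknown > 0
                else np.zeros(n, dtype=bool)
            )
        flag_values[flag + "__unknown"] = flag_unknown

    mac_probs = np.array(
        [site.maceration.macerated, site.maceration.non_macerated, site.maceration.unknown]
    )
    mac_pick = rng.choice(3, size=n, p=mac_probs / mac_probs.sum())
    maceration = np.full(n, "not_applicable", dtype=object)
    mac_labels = np.array(["macerated", "non_macerated", "unknown"], dtype=object)
    maceration[stillbirth] = mac_labels[mac_pick[stillbirth]]

    outcome_status = np.where(stillbirth, "fetal_death", "live_birth").astype(object)
    outcome_status[~included] = status[~included]

    record_id = np.array(
        [
            f"{site.name}-{_cluster_id(c)}-{y}-{i:06d}"
            for i, (c, y) in enumerate(zip(cluster_idx, year))
        ],
        dtype=object,
    )

    df = pd.DataFrame(
        {
            "record_id": record_id,
            "site": site.name,
            "cluster_id": [_cluster_id(c) for c in cluster_idx],
            "year": year,
            "outcome_status": outcome_status,
            "maceration": maceration,
        }
    )
    for fname in COVARIATE_FIELDS:
        df[fname] = values[fname]
    df["ga_weeks"] = ga.astype(int)
    df["birthweight_g"] = bw.astype(int)
    for flag in CONDITION_FLAGS:
        col = pd.array(flag_values[flag], dtype="boolean")
        col[flag_values[flag + "__unknown"]] = pd.NA
        df[CONDITION_PREFIX + flag] = col

    excluded = ~included
    for col in ("ga_weeks", "birthweight_g"):
        df[col] = df[col].astype("Int64")
        df.loc[excluded, col] = pd.NA
    for flag in CONDITION_FLAGS:
        df.loc[excluded, CONDITION_PREFIX + flag] = pd.NA
    for col in _INT_COLUMNS:
        df[col] = pd.array(pd.to_numeric(df[col]), dtype="Int64")
    df["multiple"] = pd.array(df["multiple"], dtype="boolean")
    df.loc[excluded, "multiple"] = pd.NA

    truth = pd.DataFrame(
        {
            "record_id": record_id,
            "site": site.name,
            "cluster_id": [_cluster_id(c) for c in cluster_idx],
            "year": year,
            "status": status,
            "true_outcome": np.where(
                included, np.where(stillbirth, "stillbirth", "live_birth"), None
            ),
            "risk": risk,
            "cluster_effect": cluster_effects[cluster_idx],
        }
    )
    return df, truth


# ---------------------------------------------------------------------------
# Analytic expectations
# ---------------------------------------------------------------------------

def expected_site_year_rate(config: SyntheticConfig, site: SiteSpec, year: int) -> float:
    """Expected stillbirths per 1000 births for one site-year (no cap applied)."""
    inflation = math.prod(c.mean_rr for c in config.covariates)
    risk = (
        site.baseline_stillbirth_prob
        * site.yearly_trend ** (year - site.start_year)
        * math.exp(site.cluster_sd**2 / 2.0)
        * inflation
    )
    return 1000.0 * risk


def expected_cause_mix(
    config: SyntheticConfig,
    asphyxia_conditions=DEFAULT_ASPHYXIA_CONDITIONS,
) -> Dict[str, float]:
    """Cause distribution among stillbirths implied by the config.

    Pushes the conditional flag probabilities and the gestational-age
    distribution among stillbirths through the hierarchy by exhaustive
    enumeration of flag combinations.  Under the multiplicative risk model the
    level distribution of a covariate among stillbirths is
    ``prob*rr / sum(prob*rr)``; condition flags are independent given outcome.
    """
    ga_cov = next((c for c in config.covariates if c.field_name == "ga_weeks"), None)
    if ga_cov is None:
        ga_levels = [(float(FIELD_DEFAULTS["ga_weeks"]), 1.0)]
    else:
        weights = [l.prob * l.rr for l in ga_cov.levels]
        total = sum(weights)
        ga_levels = [
            (float(l.value), w / total) for l, w in zip(ga_cov.levels, weights)
        ]

    flag_p = [
        config.conditions[f].p_stillbirth if f in config.conditions else 0.0
        for f in CONDITION_FLAGS
    ]
    # drop always-false flags from the enumeration for speed
    active = [i for i, p in enumerate(flag_p) if p > 0.0]

    mix = {cause: 0.0 for cause in CAUSES}
    for combo in product((False, True), repeat=len(active)):
        p_combo = 1.0
        flags = {f: False for f in CONDITION_FLAGS}
        for i, on in zip(active, combo):
            p_combo *= flag_p[i] if on else 1.0 - flag_p[i]
            flags[CONDITION_FLAGS[i]] = on
        if p_combo == 0.0:
            continue
        for ga, p_ga in ga_levels:
            assignment = assign_cause(flags, ga, asphyxia_conditions)
            mix[assignment.cause] += p_combo * p_ga
    return mix


def truth_report(config: SyntheticConfig) -> dict:
    """Analytic expectations for rates, cause mix, covariate RRs, maceration."""
    rates = {
        site.name: {
            str(year): expected_site_year_rate(config, site, year)
            for year in range(site.start_year, site.end_year + 1)
        }
        for site in config.sites
    }
    overall = {
        site.name: float(np.mean(list(rates[site.name].values())))
        for site in config.sites
    }
    return {
        "rate_per_1000": rates,
        "site_mean_rate_per_1000": overall,
        "cause_mix": expected_cause_mix(config),
        "covariate_rr": {
            cov.field_name: {str(l.value): l.rr for l in cov.levels}
            for cov in config.covariates
        },
        "maceration": {
            site.name: site.maceration.model_dump() for site in config.sites
        },
        "exclusions": config.exclusions.model_dump(),
    }
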