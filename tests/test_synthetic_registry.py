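import io
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

import stillreg as sr
from stillreg.cause_of_death import CAUSES
from stillreg.registry_core import CONDITION_FLAGS
from stillreg.synthetic_registry import (
    SyntheticConfig,
    default_config,
    expected_cause_mix,
    expected_site_year_rate,
)


def simple_config(**overrides):
    spec = {
        "sites": [{
            "name": "pakistan", "n_clusters": 10, "births_per_cluster_per_year": 1000,
            "start_year": 2010, "end_year": 2010,
            "baseline_stillbirth_prob": 0.056,
        }],
        "seed": 7,
    }
    spec.update(overrides)
    return SyntheticConfig.model_validate(spec)


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def _csv_bytes(config, seed):
    records, _ = sr.generate_registry(config, seed=seed)
    buf = io.StringIO()
    sr.write_registry(records, buf)
    return buf.getvalue().encode()


def test_same_seed_same_bytes():
    config = simple_config()
    assert _csv_bytes(config, 7) == _csv_bytes(config, 7)


def test_different_seed_differs():
    config = simple_config()
    assert _csv_bytes(config, 7) != _csv_bytes(config, 8)


def test_seed_required():
    config = simple_config()
    config = config.model_copy(update={"seed": None})
    with pytest.raises(ValueError, match="seed"):
        sr.generate_registry(config)


# ---------------------------------------------------------------------------
# rate recovery
# ---------------------------------------------------------------------------

def test_flat_config_rate_within_3_se():
    # zero heterogeneity, zero trend, no covariate effects
    config = simple_config()
    records, _ = sr.generate_registry(config, seed=21)
    analysis = sr.build_analysis_set(records)
    n = len(analysis.records)
    rate = 1000 * (analysis.records["outcome"] == "stillbirth").sum() / n
    p = 0.056
    se = 1000 * math.sqrt(p * (1 - p) / n)
    assert abs(rate - 1000 * p) < 3 * se


def test_truth_ledger_counts_match_records_exactly():
    config = simple_config(
        exclusions={"miscarriage": 0.03, "termination": 0.01, "missing": 0.02}
    )
    records, ledger = sr.generate_registry(config, seed=5)
    assert ledger.counts["enrolled"] == len(records)
    status = records["outcome_status"]
    assert ledger.counts["miscarriage"] == int((status == "miscarriage").sum())
    assert ledger.counts["termination"] == int((status == "termination").sum())
    assert ledger.counts["missing"] == int((status == "missing").sum())
    assert ledger.counts["stillbirths"] == int((status == "fetal_death").sum())
    assert ledger.counts["included"] == int(status.isin(["fetal_death", "live_birth"]).sum())
    per_rec = ledger.per_record
    assert (per_rec["status"] == "included").sum() == ledger.counts["included"]


def test_truth_ledger_intended_cause_matches_classifier():
    config = simple_config(
        covariates=[{"field": "ga_weeks", "levels": [
            {"value": 29, "prob": 0.3, "rr": 2.0},
            {"value": 38, "prob": 0.7, "rr": 1.0}]}],
        conditions={"trauma": {"p_stillbirth": 0.1, "p_livebirth": 0.0}},
    )
    records, ledger = sr.generate_registry(config, seed=2)
    sb_mask = ledger.per_record["true_outcome"] == "stillbirth"
    vec = sr.assign_causes(records[sb_mask])
    assert list(ledger.per_record.loc[sb_mask, "intended_cause"]) == list(
        vec["cause"].astype(str)
    )


# ---------------------------------------------------------------------------
# risk-overflow handling
# ---------------------------------------------------------------------------

def test_risk_over_one_rejected_with_combo():
    config = simple_config(
        sites=[{
            "name": "pakistan", "n_clusters": 2, "births_per_cluster_per_year": 1000,
            "start_year": 2010, "end_year": 2010,
            "baseline_stillbirth_prob": 0.2,
        }],
        covariates=[{"field": "anc_visits", "levels": [
            {"value": 0, "prob": 0.02, "rr": 6.0},
            {"value": 4, "prob": 0.98, "rr": 1.0}]}],
    )
    with pytest.raises(ValueError, match="implied risk .* > 1"):
        sr.generate_registry(config, seed=1)


def test_risk_cap_avoids_rejection():
    config = simple_config(
        sites=[{
            "name": "pakistan", "n_clusters": 2, "births_per_cluster_per_year": 1000,
            "start_year": 2010, "end_year": 2010,
            "baseline_stillbirth_prob": 0.2,
        }],
        covariates=[{"field": "anc_visits", "levels": [
            {"value": 0, "prob": 0.02, "rr": 6.0},
            {"value": 4, "prob": 0.98, "rr": 1.0}]}],
        risk_cap=0.95,
    )
    records, _ = sr.generate_registry(config, seed=1)
    assert len(records) == 2000


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

def test_bad_level_probs_rejected():
    with pytest.raises(ValidationError, match="sum"):
        simple_config(covariates=[{"field": "sex", "levels": [
            {"value": "male", "prob": 0.6}, {"value": "female", "prob": 0.6}]}])


def test_unknown_condition_flag_rejected():
    with pytest.raises(ValidationError, match="unknown condition flag"):
        simple_config(conditions={"bad_flag": {"p_stillbirth": 0.1, "p_livebirth": 0.0}})


def test_ga_covariate_below_20_rejected():
    with pytest.raises(ValidationError, match="ga_weeks"):
        simple_config(covariates=[{"field": "ga_weeks", "levels": [
            {"value": 18, "prob": 0.5}, {"value": 39, "prob": 0.5}]}])


def test_implied_risk_above_half_rejected():
    with pytest.raises(ValidationError, match="implied stillbirth risk"):
        simple_config(sites=[{
            "name": "pakistan", "n_clusters": 2, "births_per_cluster_per_year": 10,
            "baseline_stillbirth_prob": 0.3,
        }], covariates=[{"field": "anc_visits", "levels": [
            {"value": 0, "prob": 0.5, "rr": 3.0},
            {"value": 4, "prob": 0.5, "rr": 1.0}]}])


def test_cluster_entry_years_length_checked():
    with pytest.raises(ValidationError, match="cluster_entry_years"):
        simple_config(sites=[{
            "name": "kenya", "n_clusters": 3, "births_per_cluster_per_year": 10,
            "baseline_stillbirth_prob": 0.02,
            "cluster_entry_years": [2010, 2010],
        }])


def test_duplicate_covariate_rejected():
    with pytest.raises(ValidationError, match="duplicate covariate"):
        simple_config(covariates=[
            {"field": "sex", "levels": [{"value": "male", "prob": 1.0}]},
            {"field": "sex", "levels": [{"value": "female", "prob": 1.0}]},
        ])


# ---------------------------------------------------------------------------
# truth_report
# ---------------------------------------------------------------------------

def closed_form_cause_mix(p, ga_lt32):
    """Independent closed-form oracle for the expected cause distribution."""
    def off(*names):
        return math.prod(1 - p.get(n, 0.0) for n in names)

    asph_set = ("hypertensive_disease", "antepartum_hemorrhage",
                "obstructed_prolonged_labor", "other_asphyxia_condition")
    p_trauma = p.get("trauma", 0.0)
    p_anom = off("trauma") * p.get("major_anomaly", 0.0)
    p_inf = off("trauma", "major_anomaly") * (
        1 - off("maternal_infection", "fetal_infection")
    )
    pre3 = off("trauma", "major_anomaly", "maternal_infection", "fetal_infection")
    p_asph = pre3 * (1 - off(*asph_set))
    rest = pre3 * off(*asph_set)
    return {
        "trauma": p_trauma,
        "congenital_anomaly": p_anom,
        "infection": p_inf,
        "asphyxia": p_asph,
        "prematurity": rest * ga_lt32,
        "unknown": rest * (1 - ga_lt32),
    }


def test_expected_cause_mix_matches_closed_form():
    p = {
        "trauma": 0.01, "major_anomaly": 0.08, "maternal_infection": 0.15,
        "fetal_infection": 0.05, "hypertensive_disease": 0.1,
        "antepartum_hemorrhage": 0.1, "obstructed_prolonged_labor": 0.2,
        "breech_transverse": 0.12, "other_asphyxia_condition": 0.07,
    }
    config = simple_config(
        covariates=[{"field": "ga_weeks", "levels": [
            {"value": 28, "prob": 0.1, "rr": 3.0},
            {"value": 39, "prob": 0.9, "rr": 1.0}]}],
        conditions={k: {"p_stillbirth": v, "p_livebirth": 0.0} for k, v in p.items()},
    )
    # GA distribution among stillbirths under the multiplicative model
    ga_lt32 = (0.1 * 3.0) / (0.1 * 3.0 + 0.9 * 1.0)
    oracle = closed_form_cause_mix(p, ga_lt32)
    mix = expected_cause_mix(config)
    assert sum(mix.values()) == pytest.approx(1.0, abs=1e-12)
    for cause in CAUSES:
        assert mix[cause] == pytest.approx(oracle[cause], abs=1e-12), cause


def test_zero_flags_concentrate_on_prematurity_and_unknown():
    config = simple_config(
        covariates=[{"field": "ga_weeks", "levels": [
            {"value": 28, "prob": 0.25, "rr": 1.0},
            {"value": 39, "prob": 0.75, "rr": 1.0}]}],
    )
    mix = expected_cause_mix(config)
    assert mix["prematurity"] == pytest.approx(0.25)
    assert mix["unknown"] == pytest.approx(0.75)
    assert mix["asphyxia"] == 0.0


def test_empirical_cause_mix_tracks_expectation():
    config = simple_config(
        sites=[{
            "name": "drc", "n_clusters": 10, "births_per_cluster_per_year": 3000,
            "start_year": 2014, "end_year": 2014, "baseline_stillbirth_prob": 0.05,
        }],
        conditions={
            "maternal_infection": {"p_stillbirth": 0.3, "p_livebirth": 0.01},
            "obstructed_prolonged_labor": {"p_stillbirth": 0.25, "p_livebirth": 0.02},
        },
    )
    records, ledger = sr.generate_registry(config, seed=17)
    analysis = sr.build_analysis_set(records)
    sb = analysis.records[analysis.records["outcome"] == "stillbirth"]
    causes = sr.assign_causes(sb)
    observed = causes["cause"].value_counts(normalize=True)
    expected = ledger.expected["cause_mix"]
    n = len(sb)
    for cause in ("infection", "asphyxia", "unknown"):
        se = math.sqrt(expected[cause] * (1 - expected[cause]) / n)
        assert abs(observed.get(cause, 0.0) - expected[cause]) < 4 * se, cause


def test_constant_trend_expected_rates_constant():
    config = simple_config(sites=[{
        "name": "pakistan", "n_clusters": 2, "births_per_cluster_per_year": 10,
        "start_year": 2010, "end_year": 2014,
        "baseline_stillbirth_prob": 0.03, "yearly_trend": 1.0,
    }])
    report = sr.truth_report(config)
    rates = list(report["rate_per_1000"]["pakistan"].values())
    assert all(r == pytest.approx(rates[0]) for r in rates)
    assert rates[0] == pytest.approx(30.0)


def test_trend_and_cluster_sd_enter_expected_rate():
    config = simple_config(sites=[{
        "name": "pakistan", "n_clusters": 2, "births_per_cluster_per_year": 10,
        "start_year": 2010, "end_year": 2012,
        "baseline_stillbirth_prob": 0.03, "yearly_trend": 0.9, "cluster_sd": 0.2,
    }])
    site = config.sites[0]
    expected_2012 = 1000 * 0.03 * 0.9**2 * math.exp(0.2**2 / 2)
    assert expected_site_year_rate(config, site, 2012) == pytest.approx(expected_2012)


def test_maceration_distribution_tracks_config():
    config = simple_config(sites=[{
        "name": "pakistan", "n_clusters": 10, "births_per_cluster_per_year": 2000,
        "start_year": 2010, "end_year": 2010, "baseline_stillbirth_prob": 0.05,
        "maceration": {"macerated": 0.3, "non_macerated": 0.6, "unknown": 0.1},
    }])
    records, _ = sr.generate_registry(config, seed=3)
    sb = records[records["outcome_status"] == "fetal_death"]
    live = records[records["outcome_status"] == "live_birth"]
    assert (live["maceration"] == "not_applicable").all()
    frac_mac = (sb["maceration"] == "macerated").mean()
    se = math.sqrt(0.3 * 0.7 / len(sb))
    assert abs(frac_mac - 0.3) < 4 * se


def test_bundled_default_config_loads_and_generates():
    config = default_config()
    assert len(config.sites) == 7
    assert {s.name for s in config.sites} == {
        "guatemala", "drc", "zambia", "kenya", "belagavi", "nagpur", "pakistan"
    }
    for site in config.sites:
        assert 10 <= site.n_clusters <= 24
    records, ledger = sr.generate_registry(config, seed=1)
    assert ledger.counts["enrolled"] == len(records)
    # kenya has two late-entry clusters in the bundled config
    kenya_continuing = {c for s, c in ledger.continuing_clusters if s == "kenya"}
    assert len(kenya_continuing) == 14
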