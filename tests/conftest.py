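import io

import pandas as pd
import pytest

from stillreg.registry_core import CONDITION_COLUMNS, REGISTRY_COLUMNS, load_registry

_ROW_DEFAULTS = {
    "record_id": "",
    "site": "pakistan",
    "cluster_id": "c01",
    "year": "2012",
    "maternal_age": "27",
    "education": "primary",
    "parity": "1",
    "prior_pregnancy_live": "yes",
    "anc_visits": "3",
    "attendant": "physician",
    "location": "hospital",
    "mode": "vaginal",
    "outcome_status": "live_birth",
    "ga_weeks": "39",
    "birthweight_g": "3100",
    "sex": "female",
    "multiple": "false",
    "presentation": "cephalic",
    "maceration": "",
}
_ROW_DEFAULTS.update({c: "false" for c in CONDITION_COLUMNS})


def record_row(**overrides) -> dict:
    """One registry CSV row as strings, with sensible defaults."""
    row = dict(_ROW_DEFAULTS)
    for key, value in overrides.items():
        if key not in REGISTRY_COLUMNS:
            raise KeyError(key)
        row[key] = "" if value is None else str(value)
    return row


def registry_frame(rows) -> pd.DataFrame:
    """Run rows through the CSV loader so dtypes match production input."""
    rows = list(rows)
    for i, row in enumerate(rows):
        if not row["record_id"]:
            row["record_id"] = f"r{i:04d}"
    csv = io.StringIO()
    pd.DataFrame(rows, columns=list(REGISTRY_COLUMNS)).to_csv(csv, index=False)
    csv.seek(0)
    return load_registry(csv)


@pytest.fixture
def make_registry():
    return registry_frame


@pytest.fixture
def ten_records():
    """7 live births, 1 stillbirth, 1 miscarriage, 1 missing outcome."""
    rows = [record_row() for _ in range(7)]
    rows.append(record_row(outcome_status="fetal_death", ga_weeks=30, birthweight_g=1400))
    rows.append(record_row(outcome_status="miscarriage", ga_weeks="", birthweight_g=""))
    rows.append(record_row(outcome_status="missing", ga_weeks="", birthweight_g=""))
    return registry_frame(rows)
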