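import numpy as np
import pandas as pd
import pytest

from linkenhance.records import LinkedDataset
from linkenhance.synthetic import GeneratorConfig, simulate


def make_records(
    person_id="P1",
    flags=(),
    collections=None,
    dates=None,
    facilities=None,
    sampled=None,
):
    """One person's record frame from compact per-record tuples.

    ``flags`` uses codes 'a' (aboriginal), 'n' (non_aboriginal),
    'm' (missing).  Defaults: all APDC, consecutive dates, one facility.
    """
    k = len(flags)
    code = {"a": "aboriginal", "n": "non_aboriginal", "m": "missing"}
    collections = list(collections) if collections is not None else ["APDC"] * k
    if dates is None:
        dates = [f"2014-01-{i + 1:02d}" for i in range(k)]
    if facilities is None:
        facilities = [
            "F001" if c in ("APDC", "EDDC") else None for c in collections
        ]
    if sampled is None:
        sampled = [False] * k
    return pd.DataFrame({
        "person_id": [person_id] * k,
        "collection": collections,
        "event_date": pd.to_datetime(list(dates)),
        "facility_id": facilities,
        "flag": [code[f] for f in flags],
        "is_sampled": list(sampled),
    })


def make_dataset(person_specs):
    """Build a LinkedDataset from {person_id: (reference_status, age_group,
    records_frame)} specs; records_frame may be None (zero linked records)."""
    persons = pd.DataFrame({
        "person_id": list(person_specs),
        "reference_status": [s[0] for s in person_specs.values()],
        "age_group": [s[1] for s in person_specs.values()],
        "sex": [None] * len(person_specs),
        "remoteness": [None] * len(person_specs),
    })
    frames = [s[2] for s in person_specs.values() if s[2] is not None and len(s[2])]
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = make_records(flags=()).iloc[:0]
    return LinkedDataset(persons=persons, records=records)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-person simulated cohort shared across fast tests."""
    cfg = GeneratorConfig(n_persons=2000, seed=42)
    ds, truth = simulate(cfg)
    return cfg, ds, truth
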