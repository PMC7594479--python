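"""Domain types and I/O for linked administrative health records.

The analysis operates on two tables:

* a **records** table — one row per administrative record (hospital
  admission, emergency presentation, perinatal, birth-registration or
  death record), each carrying the Indigenous-status flag reported at
  that encounter; and
* a **reference** table — one row per person, carrying the self-reported
  reference status (the survey-based gold standard) and stratification
  attributes.

Both are held as pandas DataFrames inside a :class:`LinkedDataset`, which
validates the schema and referential integrity on construction.  CSV is
the interchange format; dates are ISO-8601 so chronological rules
("most recent", "index record") are unambiguous.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IndigenousFlag",
    "Collection",
    "Method",
    "AGE_GROUPS",
    "SEXES",
    "REMOTENESS",
    "CORE_METHODS",
    "ALL_METHODS",
    "HOSPITAL_COLLECTIONS",
    "LinkedDataset",
    "SchemaError",
    "read_dataset",
    "write_dataset",
    "summarise_dataset",
]


class IndigenousFlag(str, enum.Enum):
    """Indigenous status as recorded on a single administrative record."""

    ABORIGINAL = "aboriginal"
    NON_ABORIGINAL = "non_aboriginal"
    MISSING = "missing"


class Collection(str, enum.Enum):
    """The five source data collections contributing linked records.

    APDC and EDDC are the admitted-patient and emergency-department
    collections (the two evaluated sources); PDC (perinatal), RBDM
    (birth registrations) and CODURF (cause of death) contribute
    additional evidence records only.
    """

    APDC = "APDC"
    EDDC = "EDDC"
    PDC = "PDC"
    RBDM = "RBDM"
    CODURF = "CODURF"


#: Collections whose records carry a facility identifier.
HOSPITAL_COLLECTIONS = (Collection.APDC, Collection.EDDC)

#: Tie-break priority for same-date records (most-recent / index rules).
COLLECTION_PRIORITY = {c.value: i for i, c in enumerate(Collection)}


class Method(str, enum.Enum):
    """Status-derivation methods: as-recorded baseline plus eight
    linked-record enhancement approaches."""

    AS_RECORDED = "as_recorded"
    MOST_RECENT = "most_recent"
    EVER_REPORTED = "ever_reported"
    ALWAYS_REPORTED = "always_reported"
    INDEX_RECORD = "index_record"
    MAJORITY = "majority"
    TWO_HOSPITALS = "two_hospitals"
    ERA = "era"
    MSM = "msm"


#: The baseline plus the four enhancement approaches studied in depth.
CORE_METHODS = (
    Method.AS_RECORDED,
    Method.MOST_RECENT,
    Method.ERA,
    Method.MSM,
    Method.EVER_REPORTED,
)

ALL_METHODS = tuple(Method)

AGE_GROUPS = ("0-19", "20-39", "40-64", "65plus")
SEXES = ("male", "female")
REMOTENESS = ("major_cities", "inner_regional", "outer_regional", "remote")

RECORD_COLUMNS = [
    "person_id",
    "collection",
    "event_date",
    "facility_id",
    "flag",
    "is_sampled",
]
REFERENCE_COLUMNS = ["person_id", "reference_status", "age_group", "sex", "remoteness"]

_FLAG_CODES = {f.value for f in IndigenousFlag}
_COLLECTION_CODES = {c.value for c in Collection}
_STATUS_CODES = {IndigenousFlag.ABORIGINAL.value, IndigenousFlag.NON_ABORIGINAL.value}


class SchemaError(ValueError):
    """A table violates the expected schema; carries row/column context."""


def _bad_rows(msg: str, column: str, mask: pd.Series) -> SchemaError:
    rows = list(mask[mask].index[:10])
    return SchemaError(f"{msg} (column {column!r}, row(s) {rows})")


@dataclass
class LinkedDataset:
    """A validated pair of (reference persons, linked records) tables.

    ``persons`` columns: person_id, reference_status, age_group,
    sex (optional, may be NA), remoteness (optional, may be NA).
    ``records`` columns: person_id, collection, event_date (datetime64),
    facility_id (NA for non-hospital collections), flag, is_sampled (bool).
    """

    persons: pd.DataFrame
    records: pd.DataFrame
    validate_on_init: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.persons = self.persons.reset_index(drop=True)
        self.records = self.records.reset_index(drop=True)
        if self.validate_on_init:
            self.validate()

    # -- validation -------------------------------------------------

    def validate(self) -> None:
        p, r = self.persons, self.records
        for col in ("person_id", "reference_status", "age_group"):
            if col not in p.columns:
                raise SchemaError(f"reference table missing column {col!r}")
        for col in RECORD_COLUMNS:
            if col not in r.columns:
                raise SchemaError(f"records table missing column {col!r}")

        if p["person_id"].duplicated().any():
            raise _bad_rows("duplicate person_id", "person_id", p["person_id"].duplicated())
        bad = ~p["reference_status"].isin(_STATUS_CODES)
        if bad.any():
            raise _bad_rows("reference_status must be aboriginal/non_aboriginal",
                            "reference_status", bad)
        bad = ~p["age_group"].isin(AGE_GROUPS)
        if bad.any():
            raise _bad_rows("unknown age_group code", "age_group", bad)

        bad = ~r["collection"].isin(_COLLECTION_CODES)
        if bad.any():
            raise _bad_rows("unknown collection code", "collection", bad)
        bad = ~r["flag"].isin(_FLAG_CODES)
        if bad.any():
            raise _bad_rows("unknown flag code", "flag", bad)
        if not pd.api.types.is_datetime64_any_dtype(r["event_date"]):
            raise SchemaError("event_date must be a parsed date column")
        if r["event_date"].isna().any():
            raise _bad_rows("unparseable event_date", "event_date", r["event_date"].isna())

        orphans = ~r["person_id"].isin(p["person_id"])
        if orphans.any():
            ids = sorted(r.loc[orphans, "person_id"].unique()[:10])
            raise SchemaError(
                f"orphan record(s): person_id(s) {ids} absent from reference table"
            )

        hosp = r["collection"].isin([c.value for c in HOSPITAL_COLLECTIONS])
        bad = r["facility_id"].notna() & ~hosp
        if bad.any():
            raise _bad_rows("facility_id present on non-hospital record", "facility_id", bad)

        sampled = r[r["is_sampled"].astype(bool)]
        if sampled["person_id"].duplicated().any():
            raise _bad_rows("multiple sampled records for one person", "is_sampled",
                            sampled["person_id"].duplicated())
        bad = ~sampled["collection"].isin([c.value for c in HOSPITAL_COLLECTIONS])
        if bad.any():
            raise SchemaError(
                "sampled record outside APDC/EDDC for person(s) "
                f"{sorted(sampled.loc[bad, 'person_id'].unique()[:10])}"
            )

    # -- convenience ------------------------------------------------

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def records_of(self, person_id: str) -> pd.DataFrame:
        return self.records[self.records["person_id"] == person_id]

    def equals(self, other: "LinkedDataset") -> bool:
        try:
            pd.testing.assert_frame_equal(
                _canonical_persons(self.persons), _canonical_persons(other.persons)
            )
            pd.testing.assert_frame_equal(
                _canonical_records(self.records), _canonical_records(other.records)
            )
        except AssertionError:
            return False
        return True


def _canonical_persons(p: pd.DataFrame) -> pd.DataFrame:
    out = p.copy()
    for col in ("sex", "remoteness"):
        if col not in out.columns:
            out[col] = pd.Series([pd.NA] * len(out), dtype="object")
        else:
            out[col] = out[col].astype("object").where(out[col].notna(), pd.NA)
    out = out[REFERENCE_COLUMNS]
    return out.sort_values("person_id", kind="stable").reset_index(drop=True).astype(
        {"person_id": str}
    )


def _canonical_records(r: pd.DataFrame) -> pd.DataFrame:
    out = r.copy()
    out["facility_id"] = out["facility_id"].astype("object").where(
        out["facility_id"].notna(), pd.NA
    )
    out["is_sampled"] = out["is_sampled"].astype(bool)
    out["event_date"] = out["event_date"].astype("datetime64[ns]")
    out = out[RECORD_COLUMNS]
    # file order within person is meaningful (tie-breaks) -> stable sort
    return out.sort_values("person_id", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------- I/O


def read_dataset(records_path, reference_path) -> LinkedDataset:
    """Read and validate the two CSV tables into a :class:`LinkedDataset`.

    Flag/status/sex/remoteness codes are case-insensitive on read.
    Raises :class:`SchemaError` with row and column context on any
    malformed row, and on records whose person is absent from the
    reference table.
    """
    persons = pd.read_csv(reference_path, dtype=str, keep_default_na=False)
    records = pd.read_csv(records_path, dtype=str, keep_default_na=False)
    logger.info("read %d reference rows from %s", len(persons), reference_path)
    logger.info("read %d record rows from %s", len(records), records_path)

    for col in ("sex", "remoteness"):
        if col in persons.columns:
            persons[col] = persons[col].str.lower().replace("", pd.NA)
        else:
            persons[col] = pd.Series([pd.NA] * len(persons), dtype="object")
    for col in ("reference_status", "age_group"):
        if col in persons.columns:
            persons[col] = persons[col].str.lower()

    if "flag" in records.columns:
        records["flag"] = records["flag"].str.lower()
    if "collection" in records.columns:
        records["collection"] = records["collection"].str.upper()
    if "facility_id" in records.columns:
        records["facility_id"] = records["facility_id"].replace("", pd.NA)
    if "is_sampled" in records.columns:
        bad = ~records["is_sampled"].isin(["0", "1"])
        if bad.any():
            raise _bad_rows("is_sampled must be 0 or 1", "is_sampled", bad)
        records["is_sampled"] = records["is_sampled"] == "1"
    if "event_date" in records.columns:
        parsed = pd.to_datetime(records["event_date"], format="%Y-%m-%d", errors="coerce")
        if parsed.isna().any():
            raise _bad_rows("unparseable event_date (expect YYYY-MM-DD)",
                            "event_date", parsed.isna())
        records["event_date"] = parsed

    ds = LinkedDataset(persons=persons, records=records)
    logger.info("dataset validated: %d persons, %d records", ds.n_persons, ds.n_records)
    return ds


def write_dataset(ds: LinkedDataset, records_path, reference_path) -> None:
    """Write the dataset as the two CSV tables (lossless round-trip)."""
    persons = _canonical_persons(ds.persons).copy()
    persons = persons.fillna("")
    persons.to_csv(reference_path, index=False)

    records = ds.records.copy()
    records["event_date"] = records["event_date"].dt.strftime("%Y-%m-%d")
    records["is_sampled"] = records["is_sampled"].astype(bool).astype(int)
    records["facility_id"] = records["facility_id"].astype("object").where(
        records["facility_id"].notna(), ""
    )
    records[RECORD_COLUMNS].to_csv(records_path, index=False)
    logger.info("wrote %d persons to %s, %d records to %s",
                len(persons), reference_path, len(records), records_path)


# ------------------------------------------------------- summarisation


def summarise_dataset(ds: LinkedDataset) -> dict[str, pd.DataFrame]:
    """Per-reference-status structural summary of a linked dataset.

    Returns a dict of tables:

    ``persons``
        per status: person count, record count, persons by linked-record
        count (0 / 1 / 2 / 3+) and the count and fraction of persons with
        zero Aboriginal-flagged records (for reference-Aboriginal persons
        this is the *never identified* fraction — the hard ceiling on any
        linkage-based enhancement).
    ``collections``
        record count and share per source collection and status.
    """
    p = ds.persons.set_index("person_id")
    r = ds.records

    counts = r.groupby("person_id").size().reindex(p.index, fill_value=0)
    abor_flags = (
        r[r["flag"] == IndigenousFlag.ABORIGINAL.value]
        .groupby("person_id").size().reindex(p.index, fill_value=0)
    )
    bucket = pd.cut(counts, [-1, 0, 1, 2, np.inf], labels=["0", "1", "2", "3+"])

    rows = []
    for status, grp in p.groupby("reference_status", sort=True):
        idx = grp.index
        n = len(idx)
        by_bucket = bucket.loc[idx].value_counts().reindex(["0", "1", "2", "3+"], fill_value=0)
        zero_abor = int((abor_flags.loc[idx] == 0).sum())
        rows.append({
            "reference_status": status,
            "n_persons": n,
            "n_records": int(counts.loc[idx].sum()),
            "persons_0_records": int(by_bucket["0"]),
            "persons_1_record": int(by_bucket["1"]),
            "persons_2_records": int(by_bucket["2"]),
            "persons_3plus_records": int(by_bucket["3+"]),
            "persons_zero_aboriginal_flags": zero_abor,
            "frac_zero_aboriginal_flags": zero_abor / n if n else np.nan,
        })
    persons_tbl = pd.DataFrame(rows)

    coll = (
        r.merge(ds.persons[["person_id", "reference_status"]], on="person_id")
        .groupby(["reference_status", "collection"]).size().rename("n_records")
        .reset_index()
    )
    total = coll.groupby("reference_status")["n_records"].transform("sum")
    coll["share"] = coll["n_records"] / total

    return {"persons": persons_tbl, "collections": coll}
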