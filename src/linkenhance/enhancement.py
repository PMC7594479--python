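"""Derivation of a person-level Indigenous status from linked records.

Implements the as-recorded baseline plus eight linked-record
enhancement approaches:

``ever_reported``
    one Aboriginal-flagged linked record from any collection suffices.
``always_reported``
    every (non-missing) linked record must be Aboriginal-flagged.
``index_record`` / ``most_recent``
    the flag of the first / last record in the chronological series.
``two_hospitals``
    Aboriginal-flagged at two or more distinct hospital facilities
    (APDC/EDDC records only).
``majority``
    Aboriginal-flagged on at least 50% of public hospital (APDC) records.
``era``
    the weight-of-evidence rule: with three or more units of
    information, at least two must indicate Aboriginal; with one or two
    units, one suffices.  A unit of information is one linked record
    with a non-missing flag.
``msm``
    the multi-stage rule: apply the ``era`` rule within each data
    collection, then apply it again across the per-collection results
    (one unit per collection with evidence).  This guards against a
    single record-rich collection dominating the weight of evidence.
``as_recorded``
    the flag on the one APDC/EDDC record originally sampled for the
    reference survey (the unenhanced baseline).

Missing flags carry no evidence for any method.  A person with no
usable evidence derives NON_ABORIGINAL (logged), mirroring the binary
record-level evaluation downstream.

Per-person functions (``derive_era`` etc.) operate on one person's
records and are the readable reference implementations;
:func:`derive_all` computes the same statuses for a whole dataset with
vectorised pandas/numpy group operations.
"""

from __future__ import annotations

import logging
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    COLLECTION_PRIORITY,
    HOSPITAL_COLLECTIONS,
    IndigenousFlag,
    LinkedDataset,
    Method,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DerivedStatus",
    "era_rule",
    "derive_era",
    "derive_msm",
    "derive_ever_reported",
    "derive_always_reported",
    "derive_most_recent",
    "derive_index_record",
    "derive_majority",
    "derive_two_hospitals",
    "derive_as_recorded",
    "derive_all",
]

_A = IndigenousFlag.ABORIGINAL.value
_N = IndigenousFlag.NON_ABORIGINAL.value
_M = IndigenousFlag.MISSING.value
_HOSP = [c.value for c in HOSPITAL_COLLECTIONS]


class DerivedStatus(NamedTuple):
    """Per-person output of one derivation method."""

    person_id: str
    method: Method
    status: str  # "aboriginal" | "non_aboriginal"
    n_units: int
    n_aboriginal_units: int


class NoSampledRecordError(ValueError):
    """as_recorded requires exactly one sampled record with a usable flag."""


# ------------------------------------------------------------- rules


def era_rule(n_units: int, n_aboriginal: int) -> str:
    """Weight-of-evidence status from unit counts.

    ABORIGINAL iff (>=3 units and >=2 Aboriginal-indicating) or
    (1-2 units and >=1 Aboriginal-indicating); NON_ABORIGINAL otherwise,
    including the zero-evidence case.
    """
    if n_aboriginal > n_units:
        raise ValueError(
            f"n_aboriginal ({n_aboriginal}) exceeds n_units ({n_units})"
        )
    if n_units < 0:
        raise ValueError("n_units must be non-negative")
    if n_units >= 3:
        return _A if n_aboriginal >= 2 else _N
    if n_units >= 1:
        return _A if n_aboriginal >= 1 else _N
    return _N


def _units(records: pd.DataFrame) -> pd.DataFrame:
    """Records carrying evidence: non-missing flag."""
    return records[records["flag"] != _M]


def _assert_one_person(records: pd.DataFrame) -> None:
    if records["person_id"].nunique() > 1:
        raise ValueError("records belong to more than one person")


def _pid(records: pd.DataFrame) -> str:
    return str(records["person_id"].iloc[0]) if len(records) else ""


def derive_era(records: pd.DataFrame) -> DerivedStatus:
    """Weight-of-evidence status over all of one person's linked records."""
    _assert_one_person(records)
    ev = _units(records)
    n, na = len(ev), int((ev["flag"] == _A).sum())
    return DerivedStatus(_pid(records), Method.ERA, era_rule(n, na), n, na)


def derive_msm(records: pd.DataFrame) -> DerivedStatus:
    """Two-stage weight of evidence: within each collection, then across."""
    _assert_one_person(records)
    ev = _units(records)
    statuses = []
    for _, grp in ev.groupby("collection"):
        statuses.append(era_rule(len(grp), int((grp["flag"] == _A).sum())))
    n, na = len(statuses), sum(s == _A for s in statuses)
    return DerivedStatus(_pid(records), Method.MSM, era_rule(n, na), n, na)


def derive_ever_reported(records: pd.DataFrame) -> DerivedStatus:
    _assert_one_person(records)
    ev = _units(records)
    n, na = len(ev), int((ev["flag"] == _A).sum())
    return DerivedStatus(
        _pid(records), Method.EVER_REPORTED, _A if na >= 1 else _N, n, na
    )


def derive_always_reported(records: pd.DataFrame) -> DerivedStatus:
    _assert_one_person(records)
    ev = _units(records)
    n, na = len(ev), int((ev["flag"] == _A).sum())
    status = _A if (n >= 1 and na == n) else _N
    return DerivedStatus(_pid(records), Method.ALWAYS_REPORTED, status, n, na)


def _chronological_pick(records: pd.DataFrame, latest: bool) -> Optional[pd.Series]:
    """The record the most-recent / index rules use.

    Same-date ties break by collection priority (APDC > EDDC > PDC >
    RBDM > CODURF), then Aboriginal flag first, then original row order.
    """
    ev = _units(records)
    if ev.empty:
        return None
    key = pd.DataFrame({
        "date": ev["event_date"],
        "prio": ev["collection"].map(COLLECTION_PRIORITY),
        "not_a": (ev["flag"] != _A).astype(int),
        "order": np.arange(len(ev)),
    }, index=ev.index)
    key = key.sort_values(["prio", "not_a", "order"], kind="stable")
    key = key.sort_values("date", kind="stable", ascending=not latest)
    return ev.loc[key.index[0]]


def derive_most_recent(records: pd.DataFrame) -> DerivedStatus:
    """Status as flagged on the latest-dated usable record."""
    _assert_one_person(records)
    rec = _chronological_pick(records, latest=True)
    if rec is None:
        return DerivedStatus(_pid(records), Method.MOST_RECENT, _N, 0, 0)
    na = int(rec["flag"] == _A)
    return DerivedStatus(_pid(records), Method.MOST_RECENT, rec["flag"], 1, na)


def derive_index_record(records: pd.DataFrame) -> DerivedStatus:
    """Status as flagged on the earliest-dated usable record."""
    _assert_one_person(records)
    rec = _chronological_pick(records, latest=False)
    if rec is None:
        return DerivedStatus(_pid(records), Method.INDEX_RECORD, _N, 0, 0)
    na = int(rec["flag"] == _A)
    return DerivedStatus(_pid(records), Method.INDEX_RECORD, rec["flag"], 1, na)


def derive_majority(records: pd.DataFrame) -> DerivedStatus:
    """Aboriginal on at least half of public-hospital (APDC) records."""
    _assert_one_person(records)
    ev = _units(records)
    ev = ev[ev["collection"] == "APDC"]
    n, na = len(ev), int((ev["flag"] == _A).sum())
    status = _A if (n >= 1 and na / n >= 0.5) else _N
    return DerivedStatus(_pid(records), Method.MAJORITY, status, n, na)


def derive_two_hospitals(records: pd.DataFrame) -> DerivedStatus:
    """Aboriginal-flagged at two or more distinct hospital facilities."""
    _assert_one_person(records)
    ev = _units(records)
    hosp = ev[ev["collection"].isin(_HOSP)]
    a_fac = hosp.loc[hosp["flag"] == _A, "facility_id"].dropna().nunique()
    status = _A if a_fac >= 2 else _N
    return DerivedStatus(
        _pid(records), Method.TWO_HOSPITALS, status,
        len(hosp), int((hosp["flag"] == _A).sum()),
    )


def derive_as_recorded(records: pd.DataFrame) -> DerivedStatus:
    """The flag of the one record originally sampled for the survey."""
    _assert_one_person(records)
    sampled = records[records["is_sampled"].astype(bool)]
    if len(sampled) != 1:
        raise NoSampledRecordError(
            f"person {_pid(records)!r} has {len(sampled)} sampled records (need 1)"
        )
    flag = sampled["flag"].iloc[0]
    if flag == _M:
        raise NoSampledRecordError(
            f"person {_pid(records)!r}: sampled record flag is missing"
        )
    return DerivedStatus(
        _pid(records), Method.AS_RECORDED, flag, 1, int(flag == _A)
    )


_PER_PERSON = {
    Method.AS_RECORDED: derive_as_recorded,
    Method.MOST_RECENT: derive_most_recent,
    Method.EVER_REPORTED: derive_ever_reported,
    Method.ALWAYS_REPORTED: derive_always_reported,
    Method.INDEX_RECORD: derive_index_record,
    Method.MAJORITY: derive_majority,
    Method.TWO_HOSPITALS: derive_two_hospitals,
    Method.ERA: derive_era,
    Method.MSM: derive_msm,
}


# ------------------------------------------------------ whole-dataset


def _era_vec(n: np.ndarray, na: np.ndarray) -> np.ndarray:
    abor = ((n >= 3) & (na >= 2)) | ((n >= 1) & (n <= 2) & (na >= 1))
    return np.where(abor, _A, _N)


def derive_all(
    ds: LinkedDataset, methods: Iterable[Method | str] = tuple(Method)
) -> pd.DataFrame:
    """Derive statuses for every person under each requested method.

    Returns a tidy frame with columns ``person_id, method, status,
    n_units, n_aboriginal_units, evaluable``.  Enhancement methods are
    always evaluable (zero-evidence persons derive non_aboriginal);
    ``as_recorded`` is not evaluable for persons lacking a sampled
    record with a usable flag — such rows carry a null status and
    ``evaluable = False``.
    """
    methods = [Method(m) for m in methods]
    persons = ds.persons["person_id"]
    pid_index = pd.Index(persons)
    ev = ds.records[ds.records["flag"] != _M]
    n_all = ev.groupby("person_id").size().reindex(pid_index, fill_value=0).to_numpy()
    na_all = (
        ev[ev["flag"] == _A].groupby("person_id").size()
        .reindex(pid_index, fill_value=0).to_numpy()
    )

    frames = []

    def emit(method, status, n_units, na_units, evaluable=None):
        def arr(x):
            return x.to_numpy() if isinstance(x, pd.Series) else np.asarray(x)

        frames.append(pd.DataFrame({
            "person_id": persons.to_numpy(),
            "method": method.value,
            "status": arr(status),
            "n_units": arr(n_units).astype(np.int64),
            "n_aboriginal_units": arr(na_units).astype(np.int64),
            "evaluable": True if evaluable is None else arr(evaluable),
        }))

    for method in methods:
        if method is Method.ERA:
            emit(method, _era_vec(n_all, na_all), n_all, na_all)
        elif method is Method.EVER_REPORTED:
            emit(method, np.where(na_all >= 1, _A, _N), n_all, na_all)
        elif method is Method.ALWAYS_REPORTED:
            status = np.where((n_all >= 1) & (na_all == n_all), _A, _N)
            emit(method, status, n_all, na_all)
        elif method is Method.MAJORITY:
            apdc = ev[ev["collection"] == "APDC"]
            n = apdc.groupby("person_id").size().reindex(pid_index, fill_value=0).to_numpy()
            na = (
                apdc[apdc["flag"] == _A].groupby("person_id").size()
                .reindex(pid_index, fill_value=0).to_numpy()
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                status = np.where((n >= 1) & (na >= 0.5 * n), _A, _N)
            emit(method, status, n, na)
        elif method is Method.TWO_HOSPITALS:
            hosp = ev[ev["collection"].isin(_HOSP)]
            n = hosp.groupby("person_id").size().reindex(pid_index, fill_value=0).to_numpy()
            na = (
                hosp[hosp["flag"] == _A].groupby("person_id").size()
                .reindex(pid_index, fill_value=0).to_numpy()
            )
            a_hosp = hosp[hosp["flag"] == _A].dropna(subset=["facility_id"])
            n_fac = (
                a_hosp.drop_duplicates(["person_id", "facility_id"])
                .groupby("person_id").size().reindex(pid_index, fill_value=0).to_numpy()
            )
            emit(method, np.where(n_fac >= 2, _A, _N), n, na)
        elif method is Method.MSM:
            n_pc = ev.groupby(["person_id", "collection"]).size()
            na_pc = (
                ev[ev["flag"] == _A].groupby(["person_id", "collection"]).size()
                .reindex(n_pc.index, fill_value=0)
            )
            coll_status = pd.DataFrame({
                "person_id": n_pc.index.get_level_values(0),
                "is_a": _era_vec(n_pc.to_numpy(), na_pc.to_numpy()) == _A,
            })
            by_p = coll_status.groupby("person_id")
            n = by_p.size().reindex(pid_index, fill_value=0).to_numpy()
            na = by_p["is_a"].sum().reindex(pid_index, fill_value=0).to_numpy().astype(np.int64)
            emit(method, _era_vec(n, na), n, na)
        elif method in (Method.MOST_RECENT, Method.INDEX_RECORD):
            latest = method is Method.MOST_RECENT
            key = ev[["person_id", "event_date", "collection", "flag"]].copy()
            key["prio"] = key["collection"].map(COLLECTION_PRIORITY)
            key["not_a"] = (key["flag"] != _A).astype(int)
            key["order"] = np.arange(len(key))
            # sort so the preferred record ends up first per person
            key = key.sort_values(["prio", "not_a", "order"], kind="stable")
            key = key.sort_values("event_date", kind="stable", ascending=not latest)
            picked = key.drop_duplicates("person_id", keep="first").set_index("person_id")
            flag = picked["flag"].reindex(pid_index)
            status = flag.fillna(_N).to_numpy()
            has = flag.notna().to_numpy()
            emit(method, status, has.astype(int), (flag == _A).fillna(False).astype(int))
        elif method is Method.AS_RECORDED:
            sampled = ds.records[ds.records["is_sampled"].astype(bool)]
            sampled = sampled[sampled["flag"] != _M]
            flag = sampled.set_index("person_id")["flag"].reindex(pid_index)
            evaluable = flag.notna().to_numpy()
            n_bad = int((~evaluable).sum())
            if n_bad:
                logger.info("as_recorded not evaluable for %d person(s) "
                            "(no sampled record with usable flag)", n_bad)
            emit(method, flag.to_numpy(), evaluable.astype(int),
                 (flag == _A).fillna(False).astype(int), evaluable)
        else:  # pragma: no cover
            raise ValueError(f"unknown method {method!r}")

    if not frames:
        return pd.DataFrame(columns=[
            "person_id", "method", "status", "n_units",
            "n_aboriginal_units", "evaluable",
        ])
    return pd.concat(frames, ignore_index=True)
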