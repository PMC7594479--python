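"""Synthetic linked-cohort generator.

The real linked survey/administrative data are confidential, so this
module generates :class:`~linkenhance.records.LinkedDataset` objects
with the statistical structure the analysis assumes:

* a reference-Aboriginal prevalence (default 3.9%);
* a *never-identified* stratum — reference-Aboriginal persons none of
  whose administrative records carry an Aboriginal flag (default 16.4%),
  the hard ceiling on linkage-based enhancement;
* per-status linked-record-count distributions over {1, 2, 3+} with a
  left-truncated geometric tail for the 3+ bucket;
* records allocated to the five source collections, with per-collection
  probabilities that an identifiable Aboriginal person's record is
  actually flagged Aboriginal (under-reporting);
* a small fraction of reference-non-Aboriginal persons carrying one or
  more Aboriginal-flagged records (misreporting), with a within-person
  rate that produces both once-only and consistently misreported persons;
* a MISSING-flag overlay, event dates, hospital facility ids and one
  sampled APDC/EDDC record per person (the survey sampling record).

Generation is fully deterministic given ``seed``; each stage draws from
its own child stream of a single :class:`numpy.random.SeedSequence`, so
one integer reproduces the whole cohort.
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import calibration as cal
from .records import (
    AGE_GROUPS,
    Collection,
    HOSPITAL_COLLECTIONS,
    IndigenousFlag,
    LinkedDataset,
)

logger = logging.getLogger(__name__)

__all__ = ["GeneratorConfig", "SimulatedTruth", "simulate", "calibration_report"]

_A = IndigenousFlag.ABORIGINAL.value
_N = IndigenousFlag.NON_ABORIGINAL.value
_M = IndigenousFlag.MISSING.value

_COLLECTIONS = [c.value for c in Collection]

# Default 3+ tail means chosen so simulated per-status record totals match
# the published cohort: Aboriginal 75,041/5,102 records per person and
# non-Aboriginal 1,190,758/125,412, i.e. overall ~9.7 records per person.
_TAIL_MEAN_ABORIGINAL = round(
    (cal.N_RECORDS_ABORIGINAL / cal.N_ABORIGINAL - 0.05 * 1 - 0.09 * 2) / 0.86, 2
)
_TAIL_MEAN_NON_ABORIGINAL = round(
    (cal.N_RECORDS_NON_ABORIGINAL / cal.N_NON_ABORIGINAL - 0.10 * 1 - 0.12 * 2) / 0.78, 2
)


class GeneratorConfig(BaseModel):
    """All parameters of the synthetic linked cohort.

    Defaults reproduce the published cohort structure (prevalence,
    never-identified fraction, record-count distributions, collection
    shares, misreporter fraction) at the published cohort size.
    """

    n_persons: int = Field(default=cal.N_PERSONS, gt=0)
    prevalence: float = Field(default=0.039, ge=0, le=1)
    never_identified_fraction: float = Field(default=0.164, ge=0, le=1)
    #: P(person has 1, 2, 3+ linked records), by reference status
    record_count_dist_aboriginal: tuple[float, float, float] = (0.05, 0.09, 0.86)
    record_count_dist_non_aboriginal: tuple[float, float, float] = (0.10, 0.12, 0.78)
    #: mean record count within the 3+ bucket (left-truncated geometric)
    tail_mean_aboriginal: float = Field(default=_TAIL_MEAN_ABORIGINAL, gt=3)
    tail_mean_non_aboriginal: float = Field(default=_TAIL_MEAN_NON_ABORIGINAL, gt=3)
    #: record shares of APDC, EDDC, PDC, RBDM, CODURF
    collection_shares: tuple[float, float, float, float, float] = (
        0.565, 0.408, 0.011, 0.013, 0.003,
    )
    #: P(record flagged Aboriginal | identifiable Aboriginal person), per collection
    flag_sensitivity_by_collection: dict[str, float] = Field(
        default_factory=lambda: {
            "APDC": 1.00, "EDDC": 0.93, "PDC": 0.95, "RBDM": 0.95, "CODURF": 0.95,
        }
    )
    misreport_person_fraction: float = Field(default=0.005, ge=0, le=1)
    #: P(additional record flagged Aboriginal) within a misreporting person,
    #: beyond the one forced flag
    misreport_within_person_rate: float = Field(default=0.5, ge=0, le=1)
    missing_flag_rate: float = Field(default=0.01, ge=0, le=1)
    n_facilities: int = Field(default=200, gt=0)
    date_start: dt.date = dt.date(2011, 1, 1)
    date_end: dt.date = dt.date(2016, 12, 31)
    seed: int = 0

    @field_validator(
        "record_count_dist_aboriginal", "record_count_dist_non_aboriginal",
        "collection_shares",
    )
    @classmethod
    def _check_simplex(cls, v):
        if any(p < 0 or p > 1 for p in v):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"probability vector must sum to 1, got {sum(v)}")
        return v

    @field_validator("flag_sensitivity_by_collection")
    @classmethod
    def _check_sensitivities(cls, v):
        missing = set(_COLLECTIONS) - set(v)
        if missing:
            raise ValueError(f"flag sensitivity missing for collection(s) {sorted(missing)}")
        if any(not 0 <= s <= 1 for s in v.values()):
            raise ValueError("flag sensitivities must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_dates(self):
        if self.date_end < self.date_start:
            raise ValueError("date_end precedes date_start")
        return self


class SimulatedTruth:
    """Per-person latent attributes of a simulated cohort.

    ``table`` columns: person_id, reference_status, never_identified,
    misreporter, age_group.  ``never_identified`` is true only for
    reference-Aboriginal persons.
    """

    def __init__(self, table: pd.DataFrame):
        bad = table["never_identified"] & (table["reference_status"] != _A)
        if bad.any():
            raise ValueError("never_identified set for a non-Aboriginal person")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


def _draw_categorical(rng: np.random.Generator, n: int, p: Sequence[float]) -> np.ndarray:
    return rng.choice(len(p), size=n, p=np.asarray(p, dtype=float))


def _draw_record_counts(
    rng: np.random.Generator, n: int, dist: Sequence[float], tail_mean: float
) -> np.ndarray:
    """Record counts per person: bucket {1,2,3+}, geometric tail above 3."""
    bucket = _draw_categorical(rng, n, dist)  # 0 -> 1 rec, 1 -> 2 recs, 2 -> 3+
    counts = bucket + 1
    tail = bucket == 2
    if tail.any():
        # N = 3 + G, G ~ Geometric on {0,1,...} with mean tail_mean - 3
        p = 1.0 / (tail_mean - 2.0)  # mean of numpy's geometric on {1,2,..} is 1/p
        counts = counts.astype(np.int64)
        counts[tail] = 2 + rng.geometric(p, size=int(tail.sum()))
    return counts.astype(np.int64)


def simulate(config: GeneratorConfig) -> tuple[LinkedDataset, SimulatedTruth]:
    """Generate a linked cohort with the configured structure.

    Deterministic given ``config.seed``: the same configuration always
    yields byte-identical tables.
    """
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(10)]
    (rng_status, rng_strata, rng_counts, rng_coll, rng_dates,
     rng_fac, rng_flags, rng_misrep, rng_missing, rng_sampled) = rngs

    n = config.n_persons
    person_id = np.array([f"P{i:07d}" for i in range(n)])

    aboriginal = rng_status.random(n) < config.prevalence
    never = aboriginal & (rng_status.random(n) < config.never_identified_fraction)

    age_group = np.empty(n, dtype=object)
    sex = np.empty(n, dtype=object)
    remoteness = np.empty(n, dtype=object)
    for is_abor, age_m, sex_m, rem_m in (
        (True, cal.AGE_MARGINALS_ABORIGINAL, cal.SEX_MARGINALS_ABORIGINAL,
         cal.REMOTENESS_MARGINALS_ABORIGINAL),
        (False, cal.AGE_MARGINALS_NON_ABORIGINAL, cal.SEX_MARGINALS_NON_ABORIGINAL,
         cal.REMOTENESS_MARGINALS_NON_ABORIGINAL),
    ):
        mask = aboriginal == is_abor
        m = int(mask.sum())
        for target, marg, labels in (
            (age_group, age_m, list(age_m)),
            (sex, sex_m, list(sex_m)),
            (remoteness, rem_m, list(rem_m)),
        ):
            p = list(cal._normalised(marg).values())
            target[mask] = np.array(labels, dtype=object)[_draw_categorical(rng_strata, m, p)]

    counts = np.empty(n, dtype=np.int64)
    counts[aboriginal] = _draw_record_counts(
        rng_counts, int(aboriginal.sum()),
        config.record_count_dist_aboriginal, config.tail_mean_aboriginal,
    )
    counts[~aboriginal] = _draw_record_counts(
        rng_counts, int((~aboriginal).sum()),
        config.record_count_dist_non_aboriginal, config.tail_mean_non_aboriginal,
    )

    m = int(counts.sum())
    owner = np.repeat(np.arange(n), counts)

    collection = np.array(_COLLECTIONS, dtype=object)[
        _draw_categorical(rng_coll, m, config.collection_shares)
    ]
    n_days = (config.date_end - config.date_start).days + 1
    event_date = np.datetime64(config.date_start) + rng_dates.integers(0, n_days, size=m)

    hosp = np.isin(collection, [c.value for c in HOSPITAL_COLLECTIONS])
    facility = np.full(m, None, dtype=object)
    facility[hosp] = np.array(
        [f"F{i:04d}" for i in rng_fac.integers(0, config.n_facilities, size=int(hosp.sum()))],
        dtype=object,
    )

    # -- flags ------------------------------------------------------
    flag = np.full(m, _N, dtype=object)
    sens_lookup = {c: config.flag_sensitivity_by_collection[c] for c in _COLLECTIONS}
    rec_sens = np.array([sens_lookup[c] for c in collection])

    identifiable_rec = aboriginal[owner] & ~never[owner]
    flag[identifiable_rec & (rng_flags.random(m) < rec_sens)] = _A

    misreporter = ~aboriginal & (rng_misrep.random(n) < config.misreport_person_fraction)
    forced = np.zeros(m, dtype=bool)
    if misreporter.any():
        extra = (~aboriginal[owner]) & misreporter[owner] & (
            rng_misrep.random(m) < config.misreport_within_person_rate
        )
        flag[extra] = _A
        # force at least one Aboriginal flag per misreporting person
        u = rng_misrep.random(m)
        pick = pd.Series(u).groupby(owner).idxmin()
        forced_idx = pick[misreporter[pick.index.to_numpy()]].to_numpy()
        flag[forced_idx] = _A
        forced[forced_idx] = True

    # MISSING overlay; the forced misreporter flag is exempt so the
    # misreporter stratum keeps >=1 visible Aboriginal flag
    miss = (rng_missing.random(m) < config.missing_flag_rate) & ~forced
    flag[miss] = _M

    # -- sampled record: one APDC/EDDC record per person, if any ----
    is_sampled = np.zeros(m, dtype=bool)
    u = rng_sampled.random(m)
    u[~hosp] = np.inf
    first_hosp = pd.Series(u).groupby(owner).idxmin()
    has_hosp = np.isfinite(u[first_hosp.to_numpy()])
    is_sampled[first_hosp.to_numpy()[has_hosp]] = True
    n_unsampled = int((~has_hosp).sum())
    if n_unsampled:
        logger.info("%d person(s) have no APDC/EDDC record and carry no sampled record",
                    n_unsampled)

    persons = pd.DataFrame({
        "person_id": person_id,
        "reference_status": np.where(aboriginal, _A, _N),
        "age_group": pd.Categorical(age_group, categories=list(AGE_GROUPS)).astype(str),
        "sex": sex,
        "remoteness": remoteness,
    })
    records = pd.DataFrame({
        "person_id": person_id[owner],
        "collection": collection,
        "event_date": pd.to_datetime(event_date),
        "facility_id": facility,
        "flag": flag,
        "is_sampled": is_sampled,
    })
    truth = SimulatedTruth(pd.DataFrame({
        "person_id": person_id,
        "reference_status": persons["reference_status"],
        "never_identified": never,
        "misreporter": misreporter,
        "age_group": persons["age_group"],
    }))
    ds = LinkedDataset(persons=persons, records=records)
    logger.info("simulated %d persons, %d records (seed=%d)", n, m, config.seed)
    return ds, truth


# ------------------------------------------------------- calibration


def _se_prop(p: float, n: int) -> float:
    return float(np.sqrt(max(p * (1 - p), 0.0) / n)) if n > 0 else np.nan


def calibration_report(
    ds: LinkedDataset, config: GeneratorConfig, truth: Optional[SimulatedTruth] = None
) -> pd.DataFrame:
    """Compare realised cohort fractions with the configured targets.

    Returns one row per parameter with the configured value, the
    realised value, a Monte-Carlo standard error for the realised
    proportion and the z-distance between the two.  The realised
    never-identified fraction uses the observable definition (zero
    Aboriginal-flagged records among reference-Aboriginal persons),
    which exceeds the latent fraction slightly whenever some flag
    sensitivities are below one.
    """
    p = ds.persons
    r = ds.records
    abor = p["reference_status"] == _A
    n_abor = int(abor.sum())
    n_non = int((~abor).sum())

    abor_flags = (
        r[r["flag"] == _A].groupby("person_id").size()
        .reindex(p["person_id"], fill_value=0).to_numpy()
    )
    rows = []

    def add(name, configured, realised, n_draws):
        se = _se_prop(configured, n_draws)
        z = (realised - configured) / se if se and se > 0 else np.nan
        rows.append({"parameter": name, "configured": configured,
                     "realised": realised, "mc_se": se, "z": z})

    add("prevalence", config.prevalence, n_abor / len(p), len(p))
    if n_abor:
        add("never_identified_fraction", config.never_identified_fraction,
            float((abor_flags[abor.to_numpy()] == 0).mean()), n_abor)
    if n_non:
        add("misreport_person_fraction", config.misreport_person_fraction,
            float((abor_flags[(~abor).to_numpy()] >= 1).mean()), n_non)

    counts = r.groupby("person_id").size().reindex(p["person_id"], fill_value=0)
    for status_mask, dist, label in (
        (abor, config.record_count_dist_aboriginal, "aboriginal"),
        (~abor, config.record_count_dist_non_aboriginal, "non_aboriginal"),
    ):
        n_grp = int(status_mask.sum())
        if not n_grp:
            continue
        c = counts[status_mask.to_numpy()]
        for k, target in zip((1, 2, 3), dist):
            realised = float((c == k).mean()) if k < 3 else float((c >= 3).mean())
            add(f"record_count_{label}_{k if k < 3 else '3plus'}", target, realised, n_grp)

    shares = r["collection"].value_counts(normalize=True)
    for c_name, target in zip(_COLLECTIONS, config.collection_shares):
        add(f"collection_share_{c_name}", target, float(shares.get(c_name, 0.0)), len(r))

    if truth is not None:
        add("latent_never_identified_fraction", config.never_identified_fraction,
            float(truth.table.loc[truth.table["reference_status"] == _A,
                                  "never_identified"].mean()),
            n_abor)
    return pd.DataFrame(rows)
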