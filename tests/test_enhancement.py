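import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkenhance.enhancement import (
    NoSampledRecordError,
    derive_all,
    derive_always_reported,
    derive_as_recorded,
    derive_era,
    derive_ever_reported,
    derive_index_record,
    derive_majority,
    derive_most_recent,
    derive_msm,
    derive_two_hospitals,
    era_rule,
)
from linkenhance.records import Method
from linkenhance.synthetic import GeneratorConfig, simulate

from conftest import make_dataset, make_records

A, N = "aboriginal", "non_aboriginal"


def era_oracle(units):
    """Literal transliteration of the weight-of-evidence rule over an
    explicit list of per-unit indications (True = Aboriginal)."""
    n = len(units)
    n_a = sum(units)
    if n >= 3:
        return A if n_a >= 2 else N
    if n in (1, 2):
        return A if n_a >= 1 else N
    return N


class TestEraRule:
    def test_matches_enumeration_oracle_up_to_8_units(self):
        for n in range(9):
            for na in range(n + 1):
                units = [True] * na + [False] * (n - na)
                for perm in set(itertools.permutations(units)) if n <= 5 else [units]:
                    assert era_rule(n, na) == era_oracle(list(perm))

    @pytest.mark.parametrize(
        "n,na,expected",
        [(3, 2, A), (1, 1, A), (5, 1, N), (0, 0, N), (2, 1, A), (2, 0, N), (3, 1, N)],
    )
    def test_stated_examples(self, n, na, expected):
        assert era_rule(n, na) == expected

    def test_rejects_inconsistent_counts(self):
        with pytest.raises(ValueError):
            era_rule(2, 3)
        with pytest.raises(ValueError):
            era_rule(-1, 0)

    @given(n=st.integers(0, 20), na=st.integers(0, 20))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_aboriginal_evidence(self, n, na):
        # adding one Aboriginal-indicating unit never flips A -> N
        if na > n:
            return
        if era_rule(n, na) == A:
            assert era_rule(n + 1, na + 1) == A


class TestPerPersonRules:
    def test_era_spec_examples(self):
        assert derive_era(make_records(flags="aann")).status == A
        d = derive_era(make_records(flags="mm"))
        assert d.status == N and d.n_units == 0
        assert derive_era(make_records(flags="an")).status == A

    def test_msm_two_stage_hand_example(self):
        # APDC (A,N,N) -> N within-collection; EDDC (A) -> A; PDC (A) -> A;
        # second stage has 3 collection units, 2 Aboriginal -> A
        recs = make_records(
            flags="annaa",
            collections=["APDC", "APDC", "APDC", "EDDC", "PDC"],
        )
        d = derive_msm(recs)
        assert (d.status, d.n_units, d.n_aboriginal_units) == (A, 3, 2)

    def test_msm_all_negative_collections(self):
        recs = make_records(
            flags="nnnnn",
            collections=["APDC", "EDDC", "PDC", "RBDM", "CODURF"],
        )
        assert derive_msm(recs).status == N

    @pytest.mark.parametrize("flags", ["a", "an", "aan", "aannn", "m", "nnaa"])
    def test_msm_collapses_to_era_in_single_collection(self, flags):
        recs = make_records(flags=flags)
        assert derive_msm(recs).status == derive_era(recs).status

    def test_ever_reported(self):
        assert derive_ever_reported(make_records(flags="nna")).status == A
        assert derive_ever_reported(make_records(flags="nn")).status == N
        assert derive_ever_reported(make_records(flags="m")).status == N

    def test_always_reported(self):
        assert derive_always_reported(make_records(flags="aaa")).status == A
        assert derive_always_reported(make_records(flags="an")).status == N
        # missing flags are not evidence against
        assert derive_always_reported(make_records(flags="am")).status == A
        assert derive_always_reported(make_records(flags="m")).status == N

    def test_most_recent_uses_latest_dated_flag(self):
        recs = make_records(flags="an", dates=["2014-01-01", "2015-06-30"])
        assert derive_most_recent(recs).status == N
        assert derive_most_recent(make_records(flags="a")).status == A

    def test_most_recent_ignores_missing_and_empty(self):
        recs = make_records(flags="am", dates=["2014-01-01", "2015-06-30"])
        assert derive_most_recent(recs).status == A
        d = derive_most_recent(make_records(flags="m"))
        assert d.status == N and d.n_units == 0

    def test_same_date_tie_breaks_by_collection_priority(self):
        recs = make_records(
            flags="an",
            collections=["CODURF", "APDC"],
            dates=["2014-05-05", "2014-05-05"],
        )
        # APDC outranks CODURF regardless of row order or flag
        assert derive_most_recent(recs).status == N
        recs2 = make_records(
            flags="na",
            collections=["CODURF", "APDC"],
            dates=["2014-05-05", "2014-05-05"],
        )
        assert derive_most_recent(recs2).status == A
        assert derive_index_record(recs2).status == A

    def test_same_date_same_collection_prefers_aboriginal_flag(self):
        recs = make_records(flags="na", dates=["2014-05-05", "2014-05-05"])
        assert derive_most_recent(recs).status == A

    def test_index_record_mirrors_most_recent(self):
        recs = make_records(flags="an", dates=["2014-01-01", "2015-06-30"])
        assert derive_index_record(recs).status == A
        assert derive_index_record(make_records(flags="n")).status == N

    def test_majority_at_least_half_of_apdc(self):
        assert derive_majority(make_records(flags="an")).status == A  # exactly 50%
        assert derive_majority(make_records(flags="ann")).status == N
        assert derive_majority(make_records(flags="a", collections=["PDC"])).status == N

    def test_two_hospitals_distinct_facilities(self):
        recs = make_records(flags="aa", facilities=["H1", "H2"])
        assert derive_two_hospitals(recs).status == A
        recs = make_records(flags="aaa", facilities=["H1", "H1", "H1"])
        assert derive_two_hospitals(recs).status == N
        # non-hospital Aboriginal flag does not count towards facilities
        recs = make_records(flags="aa", collections=["APDC", "PDC"],
                            facilities=["H1", None])
        assert derive_two_hospitals(recs).status == N

    def test_as_recorded_uses_only_sampled_record(self):
        recs = make_records(flags="a" + "n" * 10,
                            sampled=[True] + [False] * 10)
        assert derive_as_recorded(recs).status == A
        recs = make_records(flags="na", sampled=[False, True])
        assert derive_as_recorded(recs).status == A
        with pytest.raises(NoSampledRecordError):
            derive_as_recorded(make_records(flags="an"))
        with pytest.raises(NoSampledRecordError):
            derive_as_recorded(make_records(flags="m", sampled=[True]))


class TestDeriveAll:
    def test_row_count_and_layout(self):
        ds = make_dataset({
            "P1": ("aboriginal", "0-19", make_records("P1", "aa")),
            "P2": ("non_aboriginal", "65plus", make_records("P2", "n")),
            "P3": ("non_aboriginal", "40-64", None),
        })
        out = derive_all(ds, [Method.ERA, Method.EVER_REPORTED])
        assert len(out) == 6

    def test_empty_method_set_gives_empty_table(self):
        ds = make_dataset({"P1": ("aboriginal", "0-19", make_records("P1", "a"))})
        out = derive_all(ds, [])
        assert out.empty and "status" in out.columns

    def test_simulated_row_count(self, small_cohort):
        _, ds, _ = small_cohort
        out = derive_all(ds, list(Method))
        assert len(out) == ds.n_persons * len(Method)

    def test_as_recorded_evaluability(self):
        ds = make_dataset({
            "P1": ("aboriginal", "0-19", make_records("P1", "a", sampled=[True])),
            "P2": ("non_aboriginal", "65plus", make_records("P2", "n", ["PDC"])),
        })
        out = derive_all(ds, [Method.AS_RECORDED]).set_index("person_id")
        assert out.loc["P1", "evaluable"] and out.loc["P1", "status"] == A
        assert not out.loc["P2", "evaluable"]
        assert pd.isna(out.loc["P2", "status"])

    def test_agrees_with_per_person_reference_implementations(self, small_cohort):
        """Dual route: vectorised whole-dataset derivation must equal the
        per-person rule functions on a simulated cohort subsample."""
        _, ds, _ = small_cohort
        sample = ds.persons["person_id"].iloc[:150]
        out = derive_all(ds, list(Method))
        out = out[out["person_id"].isin(sample)].set_index(["person_id", "method"])
        per_person = {
            Method.MOST_RECENT: derive_most_recent,
            Method.EVER_REPORTED: derive_ever_reported,
            Method.ALWAYS_REPORTED: derive_always_reported,
            Method.INDEX_RECORD: derive_index_record,
            Method.MAJORITY: derive_majority,
            Method.TWO_HOSPITALS: derive_two_hospitals,
            Method.ERA: derive_era,
            Method.MSM: derive_msm,
        }
        recs = ds.records
        for pid in sample:
            rr = recs[recs["person_id"] == pid]
            for method, fn in per_person.items():
                expect = fn(rr.reset_index(drop=True))
                got = out.loc[(pid, method.value)]
                assert got["status"] == expect.status, (pid, method)
                assert got["n_units"] == expect.n_units, (pid, method)
                assert got["n_aboriginal_units"] == expect.n_aboriginal_units
            row = out.loc[(pid, Method.AS_RECORDED.value)]
            try:
                expect = derive_as_recorded(rr.reset_index(drop=True))
                assert row["evaluable"] and row["status"] == expect.status
            except NoSampledRecordError:
                assert not row["evaluable"]


def _positives(out, method):
    d = out[(out["method"] == method.value) & (out["status"] == A)]
    return set(d["person_id"])


class TestSetProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_inclusions(self, seed):
        ds, _ = simulate(GeneratorConfig(n_persons=800, seed=seed))
        out = derive_all(ds, list(Method))
        always = _positives(out, Method.ALWAYS_REPORTED)
        era = _positives(out, Method.ERA)
        ever = _positives(out, Method.EVER_REPORTED)
        msm = _positives(out, Method.MSM)
        majority = _positives(out, Method.MAJORITY)
        assert always <= era <= ever
        assert majority <= ever
        assert msm <= ever

    def test_monotone_in_added_aboriginal_record(self):
        ds, _ = simulate(GeneratorConfig(n_persons=300, seed=5))
        out0 = derive_all(ds, list(Method))
        extra = pd.DataFrame({
            "person_id": ds.persons["person_id"],
            "collection": "APDC",
            "event_date": pd.Timestamp("2016-12-30"),
            "facility_id": "FX99",
            "flag": A,
            "is_sampled": False,
        })
        ds2 = make_ds_with_extra(ds, extra)
        out1 = derive_all(ds2, list(Method))
        for m in (Method.ERA, Method.MSM, Method.EVER_REPORTED, Method.MAJORITY):
            assert _positives(out0, m) <= _positives(out1, m)

    def test_never_identified_floor(self, small_cohort):
        """Zero Aboriginal-flagged records -> every method says non-Aboriginal."""
        _, ds, _ = small_cohort
        a_count = (
            ds.records[ds.records["flag"] == A].groupby("person_id").size()
            .reindex(ds.persons["person_id"], fill_value=0)
        )
        never_ids = set(a_count[a_count == 0].index)
        out = derive_all(ds, list(Method))
        positives = set(out.loc[out["status"] == A, "person_id"])
        assert not (never_ids & positives)


def make_ds_with_extra(ds, extra):
    from linkenhance.records import LinkedDataset

    records = pd.concat([ds.records, extra], ignore_index=True)
    return LinkedDataset(persons=ds.persons, records=records)
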