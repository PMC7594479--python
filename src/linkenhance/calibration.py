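"""Published benchmark figures from the NSW linked-data validation study.

These are the printed cohort counts and record-level accuracy figures
from the published NSW Patient Survey Program (PSP) validation of
Indigenous-status reporting on linked administrative health data.  They
serve two purposes:

* they calibrate the default :class:`~linkenhance.synthetic.GeneratorConfig`
  (prevalence, record-count distributions, collection shares, the
  never-identified fraction, the misreporter fraction); and
* the published Table-2 (sensitivity, PPV, F) triplets are arithmetic
  fixtures for the F-score operation.

Counts are stored as integers exactly as printed; derived fractions are
computed, not transcribed.
"""

from __future__ import annotations

# ---- cohort structure (published Results counts) --------------------

N_PERSONS = 130_514
N_ABORIGINAL = 5_102            # self-reported Aboriginal on the PSP
N_NON_ABORIGINAL = 125_412
N_RECORDS = 1_265_799
N_RECORDS_ABORIGINAL = 75_041
N_RECORDS_NON_ABORIGINAL = 1_190_758

#: persons by linked-record count {1, 2, 3+}, per reference status
RECORD_COUNT_ABORIGINAL = {1: 272, 2: 448, 3: 4_382}
RECORD_COUNT_NON_ABORIGINAL = {1: 12_458, 2: 15_427, 3: 97_527}

#: reference-Aboriginal persons with no Aboriginal-flagged linked record
N_NEVER_IDENTIFIED = 838
#: non-Aboriginal persons with >=1 Aboriginal-flagged linked record
N_MISREPORTED = 677
#: non-Aboriginal persons consistently flagged Aboriginal on all records
N_CONSISTENTLY_MISREPORTED = 120

#: linked records per source collection
COLLECTION_COUNTS = {
    "APDC": 714_704,
    "EDDC": 515_907,
    "RBDM": 16_387,
    "PDC": 14_377,
    "CODURF": 4_424,
}

#: age-group marginals (%) per reference status, from the published
#: demographic table; used to assign simulated age groups.
AGE_MARGINALS_ABORIGINAL = {"0-19": 17.0, "20-39": 14.6, "40-64": 43.4, "65plus": 25.0}
AGE_MARGINALS_NON_ABORIGINAL = {"0-19": 14.1, "20-39": 14.2, "40-64": 31.1, "65plus": 40.7}

SEX_MARGINALS_ABORIGINAL = {"male": 45.7, "female": 54.3}
SEX_MARGINALS_NON_ABORIGINAL = {"male": 46.2, "female": 53.4}

REMOTENESS_MARGINALS_ABORIGINAL = {
    "major_cities": 42.3, "inner_regional": 42.4, "outer_regional": 13.4, "remote": 1.9,
}
REMOTENESS_MARGINALS_NON_ABORIGINAL = {
    "major_cities": 55.2, "inner_regional": 34.5, "outer_regional": 9.8, "remote": 0.5,
}

# ---- published record-level validity (Table 2 Total rows) ------------
# method -> (sensitivity %, specificity %, PPV %, NPV %, F)

TABLE2_TOTAL_APDC = {
    "as_recorded": (84.4, 99.7, 95.3, 99.0, 0.90),
    "most_recent": (83.2, 99.7, 94.4, 99.0, 0.88),
    "era": (90.9, 99.3, 88.3, 99.4, 0.90),
    "msm": (90.7, 99.3, 89.5, 99.4, 0.90),
    "ever_reported": (92.0, 99.1, 86.4, 99.5, 0.89),
}

TABLE2_TOTAL_EDDC = {
    "as_recorded": (77.4, 99.7, 94.7, 98.5, 0.85),
    "most_recent": (80.4, 99.7, 94.5, 98.7, 0.87),
    "era": (88.0, 99.3, 89.8, 99.2, 0.89),
    "msm": (87.7, 99.4, 90.4, 99.2, 0.89),
    "ever_reported": (89.3, 99.1, 87.4, 99.3, 0.88),
}

#: all (sensitivity, PPV, F) cells of the published Table 2, including
#: the age-stratified rows, keyed by (source, age stratum, method).
TABLE2_SENS_PPV_F = {
    ("APDC", "0-19", "as_recorded"): (75.1, 93.6, 0.83),
    ("APDC", "0-19", "most_recent"): (79.9, 94.4, 0.87),
    ("APDC", "0-19", "era"): (83.0, 88.9, 0.86),
    ("APDC", "0-19", "msm"): (82.3, 89.6, 0.86),
    ("APDC", "0-19", "ever_reported"): (87.8, 85.2, 0.87),
    ("APDC", "20-39", "as_recorded"): (72.5, 91.7, 0.81),
    ("APDC", "20-39", "most_recent"): (68.5, 91.0, 0.78),
    ("APDC", "20-39", "era"): (83.4, 89.0, 0.86),
    ("APDC", "20-39", "msm"): (82.9, 89.9, 0.86),
    ("APDC", "20-39", "ever_reported"): (85.0, 86.4, 0.86),
    ("APDC", "40-64", "as_recorded"): (88.0, 97.5, 0.93),
    ("APDC", "40-64", "most_recent"): (88.4, 97.8, 0.93),
    ("APDC", "40-64", "era"): (93.9, 92.2, 0.93),
    ("APDC", "40-64", "msm"): (93.9, 94.6, 0.94),
    ("APDC", "40-64", "ever_reported"): (94.6, 91.1, 0.93),
    ("APDC", "65plus", "as_recorded"): (83.6, 93.8, 0.88),
    ("APDC", "65plus", "most_recent"): (80.9, 91.3, 0.86),
    ("APDC", "65plus", "era"): (89.9, 84.2, 0.87),
    ("APDC", "65plus", "msm"): (89.7, 84.5, 0.87),
    ("APDC", "65plus", "ever_reported"): (90.9, 81.9, 0.86),
    ("APDC", "total", "as_recorded"): (84.4, 95.3, 0.90),
    ("APDC", "total", "most_recent"): (83.2, 94.4, 0.88),
    ("APDC", "total", "era"): (90.9, 88.3, 0.90),
    ("APDC", "total", "msm"): (90.7, 89.5, 0.90),
    ("APDC", "total", "ever_reported"): (92.0, 86.4, 0.89),
    ("EDDC", "0-19", "as_recorded"): (72.2, 93.5, 0.81),
    ("EDDC", "0-19", "most_recent"): (80.1, 93.4, 0.86),
    ("EDDC", "0-19", "era"): (82.5, 88.5, 0.85),
    ("EDDC", "0-19", "msm"): (81.7, 89.1, 0.85),
    ("EDDC", "0-19", "ever_reported"): (85.3, 85.0, 0.85),
    ("EDDC", "20-39", "as_recorded"): (75.8, 92.3, 0.83),
    ("EDDC", "20-39", "most_recent"): (81.3, 90.3, 0.86),
    ("EDDC", "20-39", "era"): (89.7, 87.4, 0.89),
    ("EDDC", "20-39", "msm"): (89.2, 88.2, 0.89),
    ("EDDC", "20-39", "ever_reported"): (91.5, 85.6, 0.88),
    ("EDDC", "40-64", "as_recorded"): (81.0, 96.5, 0.88),
    ("EDDC", "40-64", "most_recent"): (82.3, 96.3, 0.89),
    ("EDDC", "40-64", "era"): (91.2, 92.7, 0.92),
    ("EDDC", "40-64", "msm"): (91.3, 92.9, 0.92),
    ("EDDC", "40-64", "ever_reported"): (92.4, 91.4, 0.92),
    ("EDDC", "65plus", "as_recorded"): (75.1, 93.4, 0.83),
    ("EDDC", "65plus", "most_recent"): (77.0, 94.6, 0.85),
    ("EDDC", "65plus", "era"): (84.7, 87.1, 0.86),
    ("EDDC", "65plus", "msm"): (84.4, 88.1, 0.86),
    ("EDDC", "65plus", "ever_reported"): (85.4, 83.5, 0.84),
    ("EDDC", "total", "as_recorded"): (77.4, 94.7, 0.85),
    ("EDDC", "total", "most_recent"): (80.4, 94.5, 0.87),
    ("EDDC", "total", "era"): (88.0, 89.8, 0.89),
    ("EDDC", "total", "msm"): (87.7, 90.4, 0.89),
    ("EDDC", "total", "ever_reported"): (89.3, 87.4, 0.88),
}


def _normalised(marginals: dict[str, float]) -> dict[str, float]:
    total = sum(marginals.values())
    return {k: v / total for k, v in marginals.items()}
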