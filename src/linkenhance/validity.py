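"""Record-level diagnostic validity of derived Indigenous status.

Each administrative record of the evaluated source (APDC or EDDC) with
a usable flag is one unit in the confusion matrix.  The record's
predicted label is the person's derived status under the method being
evaluated (for the as-recorded baseline in ``all_records`` mode, the
record's own flag); the truth is the person's self-reported reference
status.  Measures are sensitivity, specificity, PPV, NPV (percent) and
the F score — the harmonic mean of sensitivity and PPV on the unit
scale, balancing sensitivity gains against PPV losses.

Zero-denominator measures are undefined and propagate as NaN, never as
0 or 100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .records import AGE_GROUPS, IndigenousFlag, LinkedDataset, Method

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "ValidityMeasures",
    "build_confusion",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "f_score",
    "measures",
    "evaluate_table",
    "format_table2",
    "record_sensitivity_cluster_se",
]

_A = IndigenousFlag.ABORIGINAL.value
_M = IndigenousFlag.MISSING.value

EVAL_SOURCES = ("APDC", "EDDC")
STRATA = AGE_GROUPS + ("total",)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass(frozen=True)
class ValidityMeasures:
    """The five accuracy measures; rates in percent, F on the unit scale."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f_score: float

    def rounded(self) -> "ValidityMeasures":
        """Display precision: rates to 1 decimal, F to 2 decimals."""
        r = lambda x, d: round(x, d) if not math.isnan(x) else x
        return ValidityMeasures(
            r(self.sensitivity, 1), r(self.specificity, 1),
            r(self.ppv, 1), r(self.npv, 1), r(self.f_score, 2),
        )


def _rate(num: int, den: int) -> float:
    if den == 0:
        return math.nan
    return 100.0 * num / den


def sensitivity(cm: ConfusionMatrix) -> float:
    return _rate(cm.tp, cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    return _rate(cm.tn, cm.tn + cm.fp)


def ppv(cm: ConfusionMatrix) -> float:
    return _rate(cm.tp, cm.tp + cm.fp)


def npv(cm: ConfusionMatrix) -> float:
    return _rate(cm.tn, cm.tn + cm.fn)


def f_score(sensitivity_pct: float, ppv_pct: float) -> float:
    """Harmonic mean of sensitivity and PPV, on the unit scale.

    Inputs are percentages; the result lives in [0, 1].  Undefined
    (NaN) when both inputs are zero or either is NaN.
    """
    s, p = sensitivity_pct / 100.0, ppv_pct / 100.0
    if math.isnan(s) or math.isnan(p) or (s + p) == 0:
        return math.nan
    return 2.0 * s * p / (s + p)


def measures(cm: ConfusionMatrix) -> ValidityMeasures:
    sens, spec = sensitivity(cm), specificity(cm)
    p, n = ppv(cm), npv(cm)
    return ValidityMeasures(sens, spec, p, n, f_score(sens, p))


# ------------------------------------------------------------ builder


def _predicted(
    recs: pd.DataFrame, derived: pd.DataFrame, method: Method
) -> pd.Series:
    """Predicted record label (True = Aboriginal) for each record row."""
    if method is Method.AS_RECORDED:
        return recs["flag"] == _A
    d = derived[(derived["method"] == method.value) & derived["evaluable"]]
    status = d.set_index("person_id")["status"]
    mapped = recs["person_id"].map(status)
    if mapped.isna().any():
        raise ValueError(
            f"derived table lacks {method.value} status for "
            f"{int(mapped.isna().sum())} record owner(s)"
        )
    return mapped == _A


def _eval_records(
    ds: LinkedDataset, source: str, mode: str
) -> pd.DataFrame:
    if source not in EVAL_SOURCES:
        raise ValueError(f"evaluation source must be one of {EVAL_SOURCES}, got {source!r}")
    if mode not in ("all_records", "sampled_only"):
        raise ValueError(f"unknown mode {mode!r}")
    recs = ds.records
    recs = recs[(recs["collection"] == source) & (recs["flag"] != _M)]
    if mode == "sampled_only":
        recs = recs[recs["is_sampled"].astype(bool)]
    ref = ds.persons.set_index("person_id")
    out = recs.copy()
    out["truth"] = out["person_id"].map(ref["reference_status"]) == _A
    out["age_group"] = out["person_id"].map(ref["age_group"])
    return out


def build_confusion(
    ds: LinkedDataset,
    derived: pd.DataFrame,
    method: Method | str,
    source: str,
    stratum: str = "total",
    mode: str = "all_records",
) -> ConfusionMatrix:
    """Record-level confusion matrix for one method / source / stratum.

    ``stratum`` is an age-group code or ``"total"``; ``mode`` selects
    all usable records of the source or only the originally sampled
    record of each person.  An empty cell yields the zero matrix.
    """
    method = Method(method)
    recs = _eval_records(ds, source, mode)
    if stratum != "total":
        if stratum not in AGE_GROUPS:
            raise ValueError(f"unknown age stratum {stratum!r}")
        recs = recs[recs["age_group"] == stratum]
    if recs.empty:
        logger.info("empty cell: %s/%s/%s (%s)", method.value, source, stratum, mode)
        return ConfusionMatrix()
    pred = _predicted(recs, derived, method)
    truth = recs["truth"]
    return ConfusionMatrix(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


def evaluate_table(
    ds: LinkedDataset,
    derived: pd.DataFrame,
    methods: Iterable[Method | str],
    mode: str = "all_records",
) -> pd.DataFrame:
    """Full validity table: one row per (age stratum + total) x method.

    Columns carry the five measures plus the confusion counts for each
    evaluated source, e.g. ``APDC_sensitivity`` ... ``EDDC_f_score``.
    Measures are at full precision; see :func:`format_table2` for the
    display rounding.
    """
    methods = [Method(m) for m in methods]
    rows = {}
    for source in EVAL_SOURCES:
        recs = _eval_records(ds, source, mode)
        for method in methods:
            pred = _predicted(recs, derived, method) if not recs.empty else pd.Series(dtype=bool)
            for stratum in STRATA:
                mask = slice(None) if stratum == "total" else (recs["age_group"] == stratum)
                sub_pred = pred if stratum == "total" else pred[mask]
                sub_truth = recs["truth"] if stratum == "total" else recs.loc[mask, "truth"]
                cm = ConfusionMatrix(
                    tp=int((sub_pred & sub_truth).sum()),
                    fp=int((sub_pred & ~sub_truth).sum()),
                    tn=int((~sub_pred & ~sub_truth).sum()),
                    fn=int((~sub_pred & sub_truth).sum()),
                )
                mv = measures(cm)
                row = rows.setdefault((stratum, method.value), {})
                row.update({
                    f"{source}_tp": cm.tp, f"{source}_fp": cm.fp,
                    f"{source}_tn": cm.tn, f"{source}_fn": cm.fn,
                    f"{source}_sensitivity": mv.sensitivity,
                    f"{source}_specificity": mv.specificity,
                    f"{source}_ppv": mv.ppv,
                    f"{source}_npv": mv.npv,
                    f"{source}_f_score": mv.f_score,
                })
    out = pd.DataFrame(
        [{"age_group": k[0], "method": k[1], **v} for k, v in rows.items()]
    )
    order_age = {s: i for i, s in enumerate(STRATA)}
    order_m = {m.value: i for i, m in enumerate(methods)}
    out = out.sort_values(
        ["age_group", "method"],
        key=lambda s: s.map(order_age if s.name == "age_group" else order_m),
        kind="stable",
    ).reset_index(drop=True)
    return out


def format_table2(table: pd.DataFrame) -> str:
    """Render the evaluation table in the published layout: age strata
    by method rows, APDC and EDDC measure columns, display rounding."""
    cols = ["age_group", "method"]
    for src in EVAL_SOURCES:
        cols += [f"{src}_{m}" for m in
                 ("sensitivity", "specificity", "ppv", "npv", "f_score")]
    disp = table[[c for c in cols if c in table.columns]].copy()
    for c in disp.columns:
        if c.endswith("f_score"):
            disp[c] = disp[c].round(2)
        elif c not in ("age_group", "method"):
            disp[c] = disp[c].round(1)
    return disp.to_string(index=False)


# ------------------------------------------------- uncertainty helper


def record_sensitivity_cluster_se(
    ds: LinkedDataset,
    derived: pd.DataFrame,
    method: Method | str,
    source: str,
    mode: str = "all_records",
) -> tuple[float, float, int]:
    """Record-level sensitivity with a person-clustered standard error.

    Records of one person share that person's latent attributes, so the
    Monte-Carlo error of a record-level proportion is wider than the
    iid binomial one; the cluster-robust estimate
    ``sqrt(sum_i (a_i - p n_i)^2) / N`` (a_i Aboriginal-predicted
    records and n_i evaluated records of person i, N total records)
    accounts for that.  Returns (sensitivity %, SE %, N records).
    """
    method = Method(method)
    recs = _eval_records(ds, source, mode)
    recs = recs[recs["truth"]]
    if recs.empty:
        return math.nan, math.nan, 0
    pred = _predicted(recs, derived, method)
    grp = pd.DataFrame({"person_id": recs["person_id"].to_numpy(),
                        "pred": pred.to_numpy()}).groupby("person_id")
    a_i = grp["pred"].sum().to_numpy(dtype=float)
    n_i = grp["pred"].size().to_numpy(dtype=float)
    n_total = float(n_i.sum())
    p = float(a_i.sum() / n_total)
    se = float(np.sqrt(np.sum((a_i - p * n_i) ** 2)) / n_total)
    return 100.0 * p, 100.0 * se, int(n_total)
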