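"""Cohort construction: inclusion rules, outcome labels, counting process.

The analysis cohort keeps adult registrants with more than one waitlist
record, drops exception-point and Status-1 registrants and unknown status
codes, and restricts to active-status rows.  Outcomes are coded as a
competing-risks pair: *dropout* (died / too sick / medically unsuitable),
*transplant*, or censoring at the last record.  For model fitting each
registrant is expanded into half-open ``(start, stop]`` intervals whose
covariates are those observed at the interval start — the standard
counting-process representation for time-varying covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DROPOUT_CODES, TERMINAL_CODES

__all__ = [
    "CohortSpec",
    "OutcomeLabel",
    "filter_cohort",
    "label_outcome",
    "to_counting_process",
    "cohort_counting_process",
]

KNOWN_STATUS = {"active", "inactive"}

#: feature columns carried into counting-process rows by default
DEFAULT_COVARIATES = [
    "meld_capped", "meld_uncapped", "serum_sodium", "age_years",
    "ethnicity", "diagnosis",
    "delta_meld_30", "n_meas_30", "ind_ge5", "ind_ge10", "ind_ge30pct",
]


@dataclass(frozen=True)
class CohortSpec:
    """Inclusion/exclusion rules for the analysis cohort."""

    min_age_years: float = 18.0
    require_multiple_records: bool = True
    active_only: bool = True
    exclude_exception: bool = True
    exclude_status_1: bool = True
    window_start: float | None = None  # bounds on listing (first-record) date
    window_end: float | None = None

    def __post_init__(self):
        if (self.window_start is not None and self.window_end is not None
                and not self.window_start < self.window_end):
            raise ValueError("window_start must precede window_end")


@dataclass(frozen=True)
class OutcomeLabel:
    """Single outcome per registrant, on the time-on-list scale."""

    kind: str  # dropout | transplant | censored
    event_date: float  # days since the registrant's first retained record

    def __post_init__(self):
        if self.kind not in {"dropout", "transplant", "censored"}:
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.event_date < 0:
            raise ValueError("event_date precedes first record")


def _check_sorted(records: pd.DataFrame) -> None:
    ids = records["registrant_id"].to_numpy()
    dates = records["record_date"].to_numpy()
    same = ids[1:] == ids[:-1]
    if np.any(same & (np.diff(dates) <= 0)):
        raise ValueError("records must be sorted by (registrant_id, record_date) "
                         "with strictly increasing dates")


def filter_cohort(records: pd.DataFrame, spec: CohortSpec | None = None):
    """Apply inclusion rules; returns ``(filtered records, exclusion tally)``.

    Rules are applied registrant-wise in a fixed order so the tally is
    reproducible: listing window → age → exception/Status-1 → unknown
    status → single entry → inactive-row removal → single entry (re-applied,
    since dropping inactive rows can leave a lone record).  The tally keys
    count *registrants* removed by each rule; ``retained`` counts survivors.
    """
    spec = spec or CohortSpec()
    if records.empty:
        raise ValueError("empty registry")
    _check_sorted(records)

    df = records.copy()
    tally = {k: 0 for k in ("window", "age", "exception_status",
                            "unknown_status", "single_entry",
                            "single_entry_post")}

    grp = df.groupby("registrant_id", sort=False)
    first_date = grp["record_date"].first()
    age = grp["age_years"].first()
    nrec = grp.size()

    keep = pd.Series(True, index=nrec.index)
    if spec.window_start is not None:
        bad = first_date < spec.window_start
        if spec.window_end is not None:
            bad |= first_date >= spec.window_end
        tally["window"] = int((keep & bad).sum())
        keep &= ~bad
    elif spec.window_end is not None:
        bad = first_date >= spec.window_end
        tally["window"] = int(bad.sum())
        keep &= ~bad

    bad = age < spec.min_age_years
    tally["age"] = int((keep & bad).sum())
    keep &= ~bad

    flagged = grp[["exception_case", "status_1"]].max()
    bad = pd.Series(False, index=keep.index)
    if spec.exclude_exception:
        bad |= flagged["exception_case"].astype(bool)
    if spec.exclude_status_1:
        bad |= flagged["status_1"].astype(bool)
    tally["exception_status"] = int((keep & bad).sum())
    keep &= ~bad

    unknown = (~df["status"].isin(KNOWN_STATUS)
               | ~df["terminal_code"].isin(TERMINAL_CODES))
    if unknown.any():
        warnings.warn("records with unknown status/terminal codes removed")
    bad = unknown.groupby(df["registrant_id"], sort=False).any()
    tally["unknown_status"] = int((keep & bad).sum())
    keep &= ~bad

    if spec.require_multiple_records:
        bad = nrec < 2
        tally["single_entry"] = int((keep & bad).sum())
        keep &= ~bad

    df = df[df["registrant_id"].map(keep)]

    if spec.active_only:
        df = df[df["status"] == "active"]
        if spec.require_multiple_records:
            nrec2 = df.groupby("registrant_id", sort=False).size()
            bad2 = nrec2[nrec2 < 2].index
            tally["single_entry_post"] = len(bad2)
            df = df[~df["registrant_id"].isin(bad2)]

    tally["retained"] = df["registrant_id"].nunique()
    tally["input"] = records["registrant_id"].nunique()
    return df.reset_index(drop=True), tally


def label_outcome(registrant_records: pd.DataFrame) -> OutcomeLabel:
    """Outcome for one registrant's (date-sorted) records.

    Death, clinical deterioration, or medical unsuitability on the final
    record → dropout; transplantation → transplant; anything else
    (including removal for improvement) → censored at the last record.
    """
    if registrant_records.empty:
        raise ValueError("no records for registrant")
    codes = registrant_records["terminal_code"].to_numpy()
    if (codes[:-1] != "none").any():
        raise ValueError("terminal code on a non-final record")
    dates = registrant_records["record_date"].to_numpy()
    origin = dates[0]
    last = codes[-1]
    when = float(dates[-1] - origin)
    if last in DROPOUT_CODES:
        return OutcomeLabel("dropout", when)
    if last == "transplanted":
        return OutcomeLabel("transplant", when)
    return OutcomeLabel("censored", when)


def to_counting_process(
    feature_rows: pd.DataFrame,
    outcome: OutcomeLabel,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Expand one registrant's feature rows into ``(start, stop]`` intervals.

    Interval covariates are those of the record opening the interval; the
    cause-specific event indicators are set only on the final interval.
    A competing event is a censoring for the other cause by construction
    (its indicator simply stays 0).  Zero-length intervals are dropped.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    dates = feature_rows["record_date"].to_numpy(dtype=float)
    if np.any(np.diff(dates) <= 0):
        raise ValueError("feature rows must be strictly date-increasing")
    rel = dates - dates[0]
    if outcome.event_date < rel[-1]:
        raise ValueError("event_date precedes the last record")

    bounds = list(rel)
    if outcome.event_date > rel[-1]:
        bounds.append(outcome.event_date)
    starts = np.array(bounds[:-1])
    stops = np.array(bounds[1:])
    if len(starts) == 0:
        warnings.warn("registrant with a single record and same-day outcome "
                      "yields no intervals")
        cols = ["registrant_id", "start", "stop", "event_dropout",
                "event_transplant"] + list(covariates)
        return pd.DataFrame(columns=cols)

    cov = feature_rows.iloc[: len(starts)][covariates].reset_index(drop=True)
    out = pd.DataFrame({
        "registrant_id": feature_rows["registrant_id"].iloc[0],
        "start": starts,
        "stop": stops,
        "event_dropout": 0,
        "event_transplant": 0,
    })
    out = pd.concat([out, cov], axis=1)
    if outcome.kind == "dropout":
        out.loc[out.index[-1], "event_dropout"] = 1
    elif outcome.kind == "transplant":
        out.loc[out.index[-1], "event_transplant"] = 1
    return out


def cohort_counting_process(
    feature_rows: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Label outcomes and stack counting-process rows for a whole cohort.

    Vectorised equivalent of :func:`label_outcome` +
    :func:`to_counting_process` applied per registrant: the outcome sits on
    each registrant's final record, so the intervals are exactly the
    consecutive record pairs.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    ids = feature_rows["registrant_id"].to_numpy()
    dates = feature_rows["record_date"].to_numpy(dtype=float)
    codes = feature_rows["terminal_code"].to_numpy()
    n = len(ids)
    is_last = np.r_[ids[1:] != ids[:-1], True]
    is_first = np.r_[True, ids[1:] != ids[:-1]]
    if np.any((codes != "none") & ~is_last):
        raise ValueError("terminal code on a non-final record")

    # covariate source rows: every row except each registrant's last
    src = ~is_last
    if not src.any():
        raise ValueError("cohort produced no usable intervals")
    origin = dates[is_first]
    origin_per_row = np.repeat(origin, np.diff(np.r_[np.flatnonzero(is_first), n]))
    start = dates[src] - origin_per_row[src]
    stop = dates[np.flatnonzero(src) + 1] - origin_per_row[src]

    closes = np.flatnonzero(src) + 1  # row each interval ends on
    final_code = codes[closes]
    is_final = is_last[closes]
    out = feature_rows.iloc[np.flatnonzero(src)][covariates].reset_index(drop=True)
    out.insert(0, "registrant_id", ids[src])
    out.insert(1, "start", start)
    out.insert(2, "stop", stop)
    out.insert(3, "event_dropout",
               (is_final & np.isin(final_code, DROPOUT_CODES)).astype(int))
    out.insert(4, "event_transplant",
               (is_final & (final_code == "transplanted")).astype(int))
    return out
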