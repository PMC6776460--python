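"""30-day delta-MELD (ΔMELD₃₀) feature engineering.

The ΔMELD₃₀ statistic captures short-term deterioration of a liver-transplant
waitlist registrant.  For a record at day ``t`` with uncapped MELD ``m``:

* let ``W`` be the prior records dated in ``[t - 30, t)``;
* if the immediately preceding record falls in ``W`` (gap ≤ 30 days), the
  delta is ``m`` minus the maximum MELD over ``W`` — a rise above the recent
  window maximum;
* if the preceding record is more than 30 days old, the raw change since that
  record is scaled per 30-day interval: ``(m - m_prev) / ceil(gap / 30)``;
* the first record of every registrant has delta 0.

Deltas are computed on *uncapped* MELD so that changes above the allocation
cap of 40 are visible.  Alongside the delta we record ``n_meas_30`` (records
in the trailing 30-day window, current record included), threshold indicators
at +5 and +10 points, and a 30 %-relative-rise indicator.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_COLUMNS",
    "compute_delta_meld",
    "brute_force_delta",
    "delta_features_single",
]

#: columns appended by :func:`compute_delta_meld`
FEATURE_COLUMNS = [
    "delta_meld_30",
    "n_meas_30",
    "ind_ge5",
    "ind_ge10",
    "ind_ge30pct",
    "days_since_prev",
]

WINDOW_DAYS = 30
REL_THRESHOLD = 0.30


def delta_features_single(dates, melds, i):
    """Delta features for row ``i`` of one registrant, by explicit scan.

    Parameters
    ----------
    dates, melds
        Strictly increasing record days and the matching *uncapped* MELD
        scores for a single registrant.
    i
        Row index to evaluate.

    Returns
    -------
    dict with keys ``delta``, ``n_meas``, ``ind_ge5``, ``ind_ge10``,
    ``ind_ge30pct`` and ``days_since_prev``.

    Notes
    -----
    This routine keeps no incremental state: every call re-scans all prior
    rows.  It is the reference implementation against which the vectorised
    :func:`compute_delta_meld` is checked.
    """
    if i < 0 or i >= len(dates):
        raise IndexError(f"row index {i} out of range for {len(dates)} records")
    t = dates[i]
    m = melds[i]
    if i == 0:
        return dict(delta=0.0, n_meas=1, ind_ge5=0, ind_ge10=0,
                    ind_ge30pct=0, days_since_prev=math.nan)

    window = [j for j in range(i) if t - WINDOW_DAYS <= dates[j] < t]
    gap = t - dates[i - 1]
    if gap <= WINDOW_DAYS:
        wmax = max(melds[j] for j in window)
        delta = float(m - wmax)
        n_meas = len(window) + 1
        rel = (m - wmax) / wmax if wmax > 0 else -math.inf
    else:
        k = math.ceil(gap / WINDOW_DAYS)
        m_prev = melds[i - 1]
        delta = (m - m_prev) / k
        n_meas = 1
        rel = delta / m_prev if m_prev > 0 else -math.inf
    return dict(
        delta=delta,
        n_meas=n_meas,
        ind_ge5=int(delta >= 5),
        ind_ge10=int(delta >= 10),
        ind_ge30pct=int(rel >= REL_THRESHOLD),
        days_since_prev=float(gap),
    )


def brute_force_delta(dates, melds, i):
    """ΔMELD₃₀ for one row by explicit scan over all prior rows (oracle)."""
    return delta_features_single(dates, melds, i)["delta"]


def _features_one_registrant(dates: np.ndarray, melds: np.ndarray):
    """Vectorised-per-row feature pass for one registrant's sorted records."""
    n = len(dates)
    delta = np.zeros(n)
    n_meas = np.ones(n, dtype=int)
    ind5 = np.zeros(n, dtype=int)
    ind10 = np.zeros(n, dtype=int)
    ind30 = np.zeros(n, dtype=int)
    gap = np.full(n, np.nan)
    if n == 1:
        return delta, n_meas, ind5, ind10, ind30, gap

    gaps = np.diff(dates).astype(float)
    gap[1:] = gaps
    # left[i]: first index with date >= dates[i] - 30
    left = np.searchsorted(dates, dates - WINDOW_DAYS, side="left")
    for i in range(1, n):
        m = melds[i]
        if gaps[i - 1] <= WINDOW_DAYS:
            lo = left[i]
            wmax = melds[lo:i].max()
            d = float(m - wmax)
            n_meas[i] = i - lo + 1
            rel = (m - wmax) / wmax if wmax > 0 else -np.inf
        else:
            k = math.ceil(gaps[i - 1] / WINDOW_DAYS)
            m_prev = melds[i - 1]
            d = (m - m_prev) / k
            rel = d / m_prev if m_prev > 0 else -np.inf
        delta[i] = d
        ind5[i] = d >= 5
        ind10[i] = d >= 10
        ind30[i] = rel >= REL_THRESHOLD
    return delta, n_meas, ind5, ind10, ind30, gap


def compute_delta_meld(
    records: pd.DataFrame,
    id_col: str = "registrant_id",
    date_col: str = "record_date",
    meld_col: str = "meld_uncapped",
) -> pd.DataFrame:
    """Append ΔMELD₃₀ feature columns to a registry frame.

    ``records`` must be sorted by ``(id_col, date_col)`` with strictly
    increasing dates within each registrant; duplicate dates raise.
    Non-integer MELD values are used as-is with a warning.
    """
    if records.empty:
        out = records.copy()
        for c in FEATURE_COLUMNS:
            out[c] = pd.Series(dtype=float)
        return out

    melds_all = records[meld_col].to_numpy()
    if not np.allclose(melds_all, np.round(melds_all)):
        warnings.warn("non-integer MELD values encountered; used as-is")

    out = records.copy()
    n = len(out)
    delta = np.zeros(n)
    n_meas = np.ones(n, dtype=int)
    ind5 = np.zeros(n, dtype=int)
    ind10 = np.zeros(n, dtype=int)
    ind30 = np.zeros(n, dtype=int)
    gap = np.full(n, np.nan)

    dates_all = records[date_col].to_numpy()
    ids = records[id_col].to_numpy()
    # group boundaries without a groupby sort (input already ordered)
    boundaries = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1], True])
    for b, e in zip(boundaries[:-1], boundaries[1:]):
        d = dates_all[b:e]
        if np.any(np.diff(d) < 0):
            raise ValueError(f"records for {ids[b]!r} are not date-sorted")
        if np.any(np.diff(d) == 0):
            raise ValueError(f"duplicate record dates for registrant {ids[b]!r}")
        res = _features_one_registrant(d, melds_all[b:e])
        delta[b:e], n_meas[b:e], ind5[b:e], ind10[b:e], ind30[b:e], gap[b:e] = res

    out["delta_meld_30"] = delta
    out["n_meas_30"] = n_meas
    out["ind_ge5"] = ind5
    out["ind_ge10"] = ind10
    out["ind_ge30pct"] = ind30
    out["days_since_prev"] = gap
    return out
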