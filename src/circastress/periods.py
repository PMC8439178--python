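"""Chronological *period* construction for irregular weekly surveys.

A period ties one weekly survey to the span of days it covers, so that
daily survey records and the community case-count series can be summarised
on the same footing as the weekly psychometrics.  The windowing rule:

* if a survey falls fewer than 7 days after the previous one, the window
  starts the day after the previous survey date;
* if it falls 7 or more days after, the window starts 6 days before the
  survey date (capping look-back at one week).

Both endpoints are inclusive, so windows span at most 7 calendar days and
the windows of one participant never overlap.  The first period of a
participant, which has no predecessor, starts at
``max(survey_date - 6 days, enrollment_date)``.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Period",
    "assign_periods",
    "assign_periods_table",
    "summarize_daily_by_period",
    "summarize_case_counts",
    "flag_post_diagnosis",
    "build_period_table",
]


def _as_date(x):
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return pd.Timestamp(x).date()


@dataclass(frozen=True)
class Period:
    """One participant-specific survey window (inclusive endpoints)."""

    participant_id: str
    index: int
    window_start: dt.date
    survey_date: dt.date

    def __post_init__(self):
        if self.window_start > self.survey_date:
            raise ValueError("window_start must not be after survey_date")

    @property
    def n_days(self) -> int:
        return (self.survey_date - self.window_start).days + 1

    def contains(self, day) -> bool:
        day = _as_date(day)
        return self.window_start <= day <= self.survey_date


def assign_periods(survey_dates, participant_id="", enrollment_date=None):
    """Assign the chronological period windows for one participant.

    Parameters
    ----------
    survey_dates : sequence of dates
        Weekly survey completion dates, strictly increasing.
    participant_id : str
        Carried onto the returned :class:`Period` records.
    enrollment_date : date, optional
        Lower bound for the first period's window start.

    Returns
    -------
    list of Period
    """
    dates = [_as_date(d) for d in survey_dates]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("survey dates must be strictly increasing and unique")
    if not dates:
        return []
    periods = []
    first_start = dates[0] - dt.timedelta(days=6)
    if enrollment_date is not None:
        first_start = max(first_start, _as_date(enrollment_date))
    periods.append(Period(participant_id, 1, first_start, dates[0]))
    for k in range(1, len(dates)):
        gap = (dates[k] - dates[k - 1]).days
        if gap < 7:
            start = dates[k - 1] + dt.timedelta(days=1)
        else:
            start = dates[k] - dt.timedelta(days=6)
        periods.append(Period(participant_id, k + 1, start, dates[k]))
    return periods


def assign_periods_table(weekly, enrollment=None, participant_col="participant_id",
                         date_col="date"):
    """Vector version over a weekly-survey table.

    ``enrollment`` may be a mapping of participant id to enrollment date.
    Returns a DataFrame with columns participant_id, period, window_start,
    survey_date.
    """
    rows = []
    for pid, grp in weekly.groupby(participant_col, sort=True):
        enr = None if enrollment is None else enrollment.get(pid)
        dates = sorted(pd.to_datetime(grp[date_col]).dt.date)
        for per in assign_periods(dates, participant_id=pid, enrollment_date=enr):
            rows.append(
                {
                    "participant_id": pid,
                    "period": per.index,
                    "window_start": per.window_start,
                    "survey_date": per.survey_date,
                }
            )
    return pd.DataFrame(rows)


def _locate(periods_df, pid, day):
    """Index of the period of ``pid`` containing ``day`` or None."""
    sub = periods_df[periods_df.participant_id == pid]
    hit = sub[(sub.window_start <= day) & (day <= sub.survey_date)]
    if len(hit) == 0:
        return None
    return hit.index[0]


def summarize_daily_by_period(daily, periods_df, participant_col="participant_id",
                              date_col="date"):
    """Summarise daily survey metrics over each period window.

    Every daily row contributes to the (unique) period whose window contains
    its date, or to none.  Summaries are arithmetic means over the days that
    actually have data; a period with no daily rows yields missing values,
    never zeros.

    Returns a DataFrame keyed by (participant_id, period) with one
    ``mean_<metric>`` column per numeric/boolean daily metric and an
    ``n_days_observed`` count.
    """
    metric_cols = [
        c
        for c in daily.columns
        if c not in (participant_col, date_col)
        and (pd.api.types.is_numeric_dtype(daily[c]) or pd.api.types.is_bool_dtype(daily[c]))
    ]
    days = pd.to_datetime(daily[date_col]).dt.date.to_numpy()
    out_rows = []
    dropped = 0
    for pid, per_grp in periods_df.groupby(participant_col, sort=True):
        sub_mask = daily[participant_col].to_numpy() == pid
        sub = daily[sub_mask]
        sub_days = days[sub_mask]
        # first window whose survey_date >= day, then check window_start
        ends = per_grp.survey_date.to_numpy()
        starts = per_grp.window_start.to_numpy()
        pos = np.searchsorted(ends, sub_days)
        in_any = np.zeros(len(sub), dtype=bool)
        which = np.full(len(sub), -1)
        ok = pos < len(ends)
        which[ok] = pos[ok]
        for j in np.flatnonzero(ok):
            k = which[j]
            if starts[k] <= sub_days[j] <= ends[k]:
                in_any[j] = True
        dropped += int((~in_any).sum())
        for k, (_, per) in enumerate(per_grp.iterrows()):
            rows_k = sub[in_any & (which == k)]
            rec = {
                participant_col: pid,
                "period": per.period,
                "n_days_observed": len(rows_k),
            }
            for c in metric_cols:
                vals = pd.to_numeric(rows_k[c], errors="coerce")
                rec[f"mean_{c}"] = float(vals.mean()) if len(rows_k) else np.nan
            out_rows.append(rec)
    if dropped:
        logger.info("%d daily rows fell outside every period window", dropped)
    return pd.DataFrame(out_rows)


def summarize_case_counts(case_series, periods_df, date_col="date",
                          cases_col="cases"):
    """Mean community case count per day over each period window.

    Raises ``ValueError`` listing the missing dates when the series does not
    cover a window.
    """
    s = case_series.copy()
    s[date_col] = pd.to_datetime(s[date_col]).dt.date
    lookup = dict(zip(s[date_col], s[cases_col]))
    means = []
    for _, per in periods_df.iterrows():
        window = [
            per.window_start + dt.timedelta(days=d)
            for d in range((per.survey_date - per.window_start).days + 1)
        ]
        missing = [d for d in window if d not in lookup]
        if missing:
            raise ValueError(
                "case series missing dates: " + ", ".join(str(d) for d in missing)
            )
        means.append(float(np.mean([lookup[d] for d in window])))
    out = periods_df[["participant_id", "period"]].copy()
    out["mean_case_count"] = means
    return out


def flag_post_diagnosis(periods_df, pcr_positive_date=None,
                        antibody_positive_date=None):
    """Post-diagnosis window flags for one participant's periods.

    A period counts as within k weeks of diagnosis when its survey date lies
    in ``(diagnosis, diagnosis + 7k days]``; ``*_any`` flags every later
    period.  Missing diagnosis dates yield all-false flags.
    """
    out = periods_df[["participant_id", "period"]].copy()
    surv = pd.to_datetime(periods_df["survey_date"]).dt.date
    for name, date in (("pcr", pcr_positive_date), ("ab", antibody_positive_date)):
        if date is None or pd.isna(date):
            out[f"post_{name}_2wk"] = False
            out[f"post_{name}_4wk"] = False
            out[f"post_{name}_any"] = False
            continue
        date = _as_date(date)
        delta = surv.map(lambda d: (d - date).days)
        out[f"post_{name}_2wk"] = ((delta > 0) & (delta <= 14)).to_numpy()
        out[f"post_{name}_4wk"] = ((delta > 0) & (delta <= 28)).to_numpy()
        out[f"post_{name}_any"] = (delta > 0).to_numpy()
    return out


def build_period_table(weekly, daily, case_series, baseline,
                       participant_col="participant_id"):
    """Assemble the per-period long table for the longitudinal stress model.

    Joins the weekly psychometrics with the period-summarised daily metrics,
    the mean community case count, and the post-diagnosis flags.
    """
    enrollment = None
    if "enrollment_date" in baseline.columns:
        enrollment = dict(
            zip(
                baseline[participant_col],
                pd.to_datetime(baseline["enrollment_date"]).dt.date,
            )
        )
    periods_df = assign_periods_table(weekly, enrollment=enrollment)
    tab = periods_df.merge(
        weekly.assign(survey_date=pd.to_datetime(weekly["date"]).dt.date).drop(
            columns=["date"]
        ),
        on=[participant_col, "survey_date"],
        how="left",
    )
    if daily is not None and len(daily):
        tab = tab.merge(
            summarize_daily_by_period(daily, periods_df),
            on=[participant_col, "period"],
            how="left",
        )
    if case_series is not None and len(case_series):
        tab = tab.merge(
            summarize_case_counts(case_series, periods_df),
            on=[participant_col, "period"],
            how="left",
        )
    flags = []
    pcr_dates = {}
    ab_dates = {}
    if "covid_pcr_positive_date" in baseline.columns:
        pcr_dates = dict(zip(baseline[participant_col], baseline["covid_pcr_positive_date"]))
    if "covid_antibody_positive_date" in baseline.columns:
        ab_dates = dict(zip(baseline[participant_col], baseline["covid_antibody_positive_date"]))
    for pid, grp in periods_df.groupby(participant_col, sort=True):
        flags.append(
            flag_post_diagnosis(grp, pcr_dates.get(pid), ab_dates.get(pid))
        )
    if flags:
        tab = tab.merge(pd.concat(flags, ignore_index=True),
                        on=[participant_col, "period"], how="left")
    base_cols = [
        c
        for c in baseline.columns
        if c
        not in (
            "covid_pcr_positive_date",
            "covid_antibody_positive_date",
            "enrollment_date",
        )
    ]
    tab = tab.merge(baseline[base_cols], on=participant_col, how="left",
                    suffixes=("", "_baseline"))
    return tab
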