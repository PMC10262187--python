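"""MCTQ-style scoring of sleep-timing questionnaires.

Derives, per participant, the standard circadian variables:

* ``SD_w`` / ``SD_f`` — sleep duration on workdays / free days (h),
* ``MSW`` / ``MSF`` — mid-sleep phase on workdays / free days (h),
* ``SD_week`` — workday-weighted weekly mean sleep duration,
* ``MSF_sc`` — chronotype: mid-sleep on free days corrected for sleep debt
  accumulated over the workweek (``MSF - (SD_f - SD_week)/2`` when free-day
  sleep exceeds workday sleep),
* ``SJL`` — social jetlag, the circular absolute difference ``|MSF - MSW|``,
* ``Bamid`` — midpoint of the self-reported best-alertness interval.

Participants who use an alarm clock on free days cannot express their
unconstrained sleep phase, so their ``MSF_sc`` is flagged invalid (social
jetlag is still computed); this strictness is configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .clock import circular_abs_diff, parse_clock_time, sleep_interval

logger = logging.getLogger(__name__)

#: Exclusion reasons, in priority order.
EXCLUSION_REASONS = ("none", "missing", "irregular", "alarm_free", "outlier")

#: Variables the 5-sigma outlier filter is applied to, independently.
SIGMA_FILTER_COLUMNS = ("MSF_sc", "SJL", "SD_week")


@dataclass
class MctqResponse:
    """One participant's raw sleep-timing answers (decimal hours or None)."""

    participant_id: object
    sleep_onset_work: float | None = None
    sleep_end_work: float | None = None
    sleep_onset_free: float | None = None
    sleep_end_free: float | None = None
    alarm_free: bool = False
    workdays_per_week: int | None = None
    alertness_start: float | None = None
    alertness_end: float | None = None
    age: float | None = None
    sex: str | None = None


@dataclass
class CircadianProfile:
    """Derived circadian variables with validity flags."""

    participant_id: object
    SD_w: float = math.nan
    SD_f: float = math.nan
    SD_week: float = math.nan
    MSW: float = math.nan
    MSF: float = math.nan
    MSF_sc: float = math.nan
    SJL: float = math.nan
    Bamid: float = math.nan
    valid_sjl: bool = False
    valid_msfsc: bool = False
    exclusion_reason: str = "none"

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _pair(onset, end) -> bool:
    return onset is not None and end is not None and np.isfinite(onset) and np.isfinite(end)


def score_mctq(r: MctqResponse, strict_alarm: bool = True) -> CircadianProfile:
    """Score one response into a :class:`CircadianProfile`.

    Missing day-type pairs yield ``exclusion_reason='missing'``; degenerate
    (zero-length) sleep intervals yield ``'irregular'``.  A free-day alarm
    invalidates ``MSF_sc`` (``'alarm_free'``) when ``strict_alarm`` is true
    but never invalidates social jetlag.
    """
    p = CircadianProfile(participant_id=r.participant_id)

    has_work = _pair(r.sleep_onset_work, r.sleep_end_work)
    has_free = _pair(r.sleep_onset_free, r.sleep_end_free)
    if not (has_work and has_free):
        p.exclusion_reason = "missing"
        return p

    try:
        p.SD_w, p.MSW = sleep_interval(r.sleep_onset_work, r.sleep_end_work)
        p.SD_f, p.MSF = sleep_interval(r.sleep_onset_free, r.sleep_end_free)
    except ValueError:
        p.exclusion_reason = "irregular"
        return p

    wd = r.workdays_per_week
    if wd is None or (isinstance(wd, float) and not np.isfinite(wd)):
        logger.warning(
            "participant %r: workdays_per_week missing, defaulting to 5", r.participant_id
        )
        wd = 5
    wd = int(wd)
    if not 0 <= wd <= 7:
        p.exclusion_reason = "irregular"
        return p

    p.SD_week = (wd * p.SD_w + (7 - wd) * p.SD_f) / 7.0
    if p.SD_f > p.SD_w:
        p.MSF_sc = p.MSF - (p.SD_f - p.SD_week) / 2.0
    else:
        p.MSF_sc = p.MSF
    p.SJL = circular_abs_diff(p.MSF, p.MSW)
    p.valid_sjl = True
    p.valid_msfsc = True

    if _pair(r.alertness_start, r.alertness_end):
        try:
            _, p.Bamid = sleep_interval(r.alertness_start, r.alertness_end)
        except ValueError:
            p.Bamid = math.nan

    if strict_alarm and r.alarm_free:
        p.valid_msfsc = False
        p.MSF_sc = math.nan
        p.exclusion_reason = "alarm_free"
    return p


# ---------------------------------------------------------------------------
# Outlier filtering

def sigma_filter(values, k: float = 5.0) -> np.ndarray:
    """Single-pass mean +/- k*SD filter; returns a boolean keep-mask.

    Mean and SD are computed on all finite values before any exclusion.
    With SD = 0 (or fewer than two finite values) nothing is excluded.
    Non-finite entries are never flagged here (missingness is handled by
    validity flags upstream).
    """
    x = np.asarray(values, dtype=float)
    keep = np.ones(x.shape, dtype=bool)
    finite = np.isfinite(x)
    if finite.sum() < 2 or not np.isfinite(k):
        return keep
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0.0:
        return keep
    keep[finite] = np.abs(x[finite] - mu) <= k * sd
    return keep


# ---------------------------------------------------------------------------
# Frame-level API

#: Input columns holding clock times (parsed with parse_clock_time when str).
TIME_COLUMNS = (
    "sleep_onset_work",
    "sleep_end_work",
    "sleep_onset_free",
    "sleep_end_free",
    "alertness_start",
    "alertness_end",
)


def _coerce_time(value, field_name: str) -> float | None:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return None
    if isinstance(value, str):
        if value.strip() == "":
            return None
        return parse_clock_time(value, field=field_name)
    return float(value)


def response_from_row(row: pd.Series) -> MctqResponse:
    """Build an :class:`MctqResponse` from one table row.

    Clock-time columns may hold either ``"HH:MM"`` strings or decimal hours.
    """
    kwargs = {"participant_id": row.get("participant_id")}
    for col in TIME_COLUMNS:
        kwargs[col] = _coerce_time(row.get(col), col)
    alarm = row.get("alarm_free", False)
    kwargs["alarm_free"] = bool(alarm) if pd.notna(alarm) else False
    wd = row.get("workdays_per_week")
    kwargs["workdays_per_week"] = None if pd.isna(wd) else int(wd)
    for col in ("age",):
        v = row.get(col)
        kwargs[col] = None if pd.isna(v) else float(v)
    sex = row.get("sex")
    kwargs["sex"] = None if pd.isna(sex) else str(sex)
    return MctqResponse(**kwargs)


def score_frame(df: pd.DataFrame, strict_alarm: bool = True) -> pd.DataFrame:
    """Score every row of a response table; returns the derived columns.

    The result is indexed like ``df`` and can be joined back onto it.
    """
    if "participant_id" not in df.columns:
        raise KeyError("score_frame requires a 'participant_id' column")
    records = [
        score_mctq(response_from_row(row), strict_alarm=strict_alarm).as_dict()
        for _, row in df.iterrows()
    ]
    return pd.DataFrame.from_records(records, index=df.index)


def apply_sigma_filter(
    scored: pd.DataFrame, k: float = 5.0, columns=SIGMA_FILTER_COLUMNS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the k-sigma filter independently to each of ``columns``.

    Returns ``(filtered, exclusion_log)``. Filtered rows get
    ``exclusion_reason='outlier'`` and both validity flags cleared; the log
    has one row per (participant, variable) exclusion.
    """
    out = scored.copy()
    log_rows = []
    outlier = np.zeros(len(out), dtype=bool)
    for col in columns:
        if col not in out.columns:
            continue
        keep = sigma_filter(out[col].to_numpy(), k=k)
        for pid in out.loc[~keep, "participant_id"]:
            log_rows.append({"participant_id": pid, "variable": col, "reason": "outlier"})
        outlier |= ~keep
    out.loc[outlier, ["valid_sjl", "valid_msfsc"]] = False
    out.loc[outlier, "exclusion_reason"] = "outlier"
    log = pd.DataFrame(log_rows, columns=["participant_id", "variable", "reason"])
    return out, log
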