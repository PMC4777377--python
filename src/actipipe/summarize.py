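"""Per-day and per-participant estimates under the valid-day rule.

Daily summaries report full-day wear-time minutes plus minutes and percent
of in-window wear time spent in each intensity class between 5:00 AM and
end of day. Percent denominators use in-window wear minutes — classes are
only scored inside the window, so this is the denominator under which the
percentages sum to 100 (the choice is documented; total-wear or 24-h
denominators can be derived from the reported minutes).

A day is valid when its wear time *at 60-s epochs* is at least 360 minutes;
validity is decided once per wear-time algorithm and the same day set is
kept at every epoch length, so epoch comparisons always average over the
same days.
"""

from __future__ import annotations

import warnings
from datetime import timedelta

import numpy as np
import pandas as pd

from .intensity import LPA, MPA, SB, SBLPA, VPA, IntensityLabels
from .weartime import WearMask, wear_minutes_per_day

__all__ = [
    "MIN_VALID_WT_MINUTES",
    "daily_summaries",
    "apply_valid_day_rule",
    "participant_means",
]

#: minimum 60-s-epoch wear minutes for a day to enter the analysis
MIN_VALID_WT_MINUTES = 360.0

CLASS_MINUTE_COLUMNS = ("sb_min", "lpa_min", "sblpa_min", "mpa_min", "vpa_min", "mvpa_min")
CLASS_PCT_COLUMNS = ("sb_pct", "lpa_pct", "sblpa_pct", "mpa_pct", "vpa_pct", "mvpa_pct")

_N_LABELS = 7  # label codes 0..6


def daily_summaries(
    labels: IntensityLabels,
    mask: WearMask,
    start_time,
    subject_id: str = "",
) -> pd.DataFrame:
    """One row per calendar day: wear-time and intensity-class minutes.

    Sets without a SB/LPA split populate ``sblpa_min``/``sblpa_pct`` and
    leave ``sb_*``/``lpa_*`` as NaN; all other sets do the reverse. Days
    with zero in-window wear report NaN percentages.
    """
    if labels.n_epochs != mask.n_epochs or labels.epoch_length != mask.epoch_length:
        raise ValueError("labels and mask must come from the same series")
    epoch = labels.epoch_length
    n = labels.n_epochs
    offset = start_time.hour * 3600 + start_time.minute * 60 + start_time.second
    day = (offset + np.arange(n, dtype=np.int64) * epoch) // 86400
    nd = int(day[-1]) + 1 if n else 0
    per_min = epoch / 60.0

    # per-day label tallies in one bincount pass (hot path of the grid)
    key = day * _N_LABELS + labels.labels
    cnt = np.bincount(key, minlength=nd * _N_LABELS).reshape(nd, _N_LABELS) * per_min

    wt = np.bincount(day[mask.flags], minlength=nd) * per_min
    start_date = pd.Timestamp(start_time).normalize().date()
    frame = pd.DataFrame(
        {
            "subject_id": subject_id,
            "day": [start_date + timedelta(days=d) for d in range(nd)],
            "wt_min": wt,
        }
    )
    mpa, vpa = cnt[:, MPA], cnt[:, VPA]
    if labels.cutpoints.has_sb_lpa_split:
        sb, lpa = cnt[:, SB], cnt[:, LPA]
        in_window_wear = sb + lpa + mpa + vpa
        frame["sb_min"] = sb
        frame["lpa_min"] = lpa
        frame["sblpa_min"] = np.nan
    else:
        sblpa = cnt[:, SBLPA]
        in_window_wear = sblpa + mpa + vpa
        frame["sb_min"] = np.nan
        frame["lpa_min"] = np.nan
        frame["sblpa_min"] = sblpa
    frame["mpa_min"] = mpa
    frame["vpa_min"] = vpa
    frame["mvpa_min"] = mpa + vpa
    frame["in_window_wear_min"] = in_window_wear

    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(in_window_wear > 0, in_window_wear, np.nan)
        for min_col, pct_col in zip(CLASS_MINUTE_COLUMNS, CLASS_PCT_COLUMNS):
            frame[pct_col] = 100.0 * frame[min_col].to_numpy() / denom
    return frame


def apply_valid_day_rule(
    summaries_by_epoch: dict,
    wt60: pd.DataFrame,
    min_wt_minutes: float = MIN_VALID_WT_MINUTES,
) -> dict:
    """Keep, at every epoch length, exactly the days valid at 60-s epochs.

    ``wt60`` must hold columns ``subject_id``, ``day``, ``wear_min`` computed
    at 60-s epochs with the same wear-time algorithm as the summaries.
    Returns new tables with a ``valid`` column, filtered to valid days.
    """
    ref = wt60.set_index(["subject_id", "day"])["wear_min"]
    valid_days = set(ref[ref >= min_wt_minutes].index)
    out = {}
    for epoch, table in summaries_by_epoch.items():
        keys = list(zip(table["subject_id"], table["day"]))
        missing = [k for k in keys if k not in ref.index]
        if missing:
            raise ValueError(
                f"no 60-s wear-time reference for subject-days {missing[:3]}"
                f"{'...' if len(missing) > 3 else ''}"
            )
        is_valid = np.array([k in valid_days for k in keys], dtype=bool)
        kept = table.loc[is_valid].copy()
        kept["valid"] = True
        out[epoch] = kept.reset_index(drop=True)
    return out


def participant_means(summaries: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-subject mean over valid days of every measure.

    Subjects with no valid days are dropped with a warning. If a ``valid``
    column is present, only valid days contribute.
    """
    if summaries.empty:
        return summaries.head(0).drop(columns=["day"], errors="ignore")
    df = summaries
    if "valid" in df.columns:
        dropped = sorted(set(df["subject_id"]) - set(df.loc[df["valid"], "subject_id"]))
        if dropped:
            warnings.warn(f"subjects with no valid days dropped: {dropped}")
        df = df[df["valid"]]
    value_cols = [
        c
        for c in df.columns
        if c not in ("subject_id", "day", "valid") and pd.api.types.is_numeric_dtype(df[c])
    ]
    return df.groupby("subject_id", as_index=False)[value_cols].mean()
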