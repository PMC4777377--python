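"""Non-wear detection: 20-min consecutive-zero, NHANES, and Choi algorithms.

All three algorithms classify each epoch of a count series as wear or
non-wear from the vertical-axis counts (configurable):

* **ZERO20** — every maximal run of consecutive zero-count epochs spanning at
  least 20 minutes is non-wear. No allowance.
* **NHANES** — candidate non-wear intervals are runs of zero-count epochs
  permitted to absorb nonzero epochs whose count lies in the allowance band,
  each absorbed epoch consuming its duration in seconds from a cumulative
  2-minute (120 s) budget per interval. An epoch above the band, or a nonzero
  epoch arriving once the budget cannot cover it, terminates the candidate;
  candidates spanning >= 60 minutes are flagged non-wear. The band is
  0 < c <= 100 counts *per 60-s epoch*; by default it is scaled to the epoch
  being processed (100 * epoch/60), which is how the algorithm is converted
  to non-validated epoch lengths in practice and what makes wear-time
  estimates rise as the epoch shrinks. Set ``scale_allowance_band=False`` to
  apply the 0-100 band to raw epoch counts regardless of epoch length.
* **Choi** — the series is first collapsed internally to 60-s epochs; the
  scan then runs at minute resolution: maximal windows of zero minutes
  spanning >= 90 minutes are non-wear, permitting embedded nonzero spells of
  <= 2 consecutive minutes only when the 30 minutes immediately upstream and
  downstream of the spell are all zero (truncated at recording edges, the
  available flank must still be all zero). The per-minute mask is broadcast
  back to the source epoch length, so the output stays at the input epoch.

Masks carry the detected intervals with the allowance seconds each consumed,
which is what the epoch-length sensitivity of the NHANES algorithm turns on:
a burst of counts confined to one fine epoch consumes only that epoch's
seconds, but consumes a full minute once reintegrated to 60-s epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .io_actigraph import CountSeries
from .reintegrate import reintegrate

__all__ = [
    "WearAlgorithmParams",
    "WearMask",
    "ALGORITHMS",
    "detect_nonwear",
    "detect_nonwear_zero20",
    "detect_nonwear_nhanes",
    "detect_nonwear_choi",
    "wear_minutes_per_day",
    "detection_accuracy",
]

ALGORITHMS = ("zero20", "nhanes", "choi")


@dataclass(frozen=True)
class WearAlgorithmParams:
    """Tunable windows and allowances of the three detectors (minutes)."""

    algorithm: str = "choi"
    zero_run_min: int = 20
    nhanes_window_min: int = 60
    nhanes_allowance_min: int = 2
    nhanes_allowance_counts: float = 100.0  # band upper bound at a 60-s epoch
    scale_allowance_band: bool = True
    choi_window1_min: int = 90
    choi_allowance_min: int = 2
    choi_window2_min: int = 30
    axis_used: str = "vertical"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        for name in (
            "zero_run_min",
            "nhanes_window_min",
            "nhanes_allowance_min",
            "choi_window1_min",
            "choi_allowance_min",
            "choi_window2_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nhanes_allowance_min >= self.nhanes_window_min:
            raise ValueError("allowance must be shorter than the main window")
        if self.choi_allowance_min >= self.choi_window1_min:
            raise ValueError("allowance must be shorter than window 1")


@dataclass
class WearMask:
    """Per-epoch wear flags plus the non-wear intervals that produced them.

    ``flags[i]`` is True when epoch ``i`` is wear. ``nonwear_intervals`` is a
    list of ``(start, end, allowance_seconds)`` with ``end`` exclusive, in
    epoch indices at ``epoch_length``; their union is exactly the epochs
    flagged non-wear.
    """

    epoch_length: int
    flags: np.ndarray
    nonwear_intervals: list = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.flags)

    def wear_seconds(self) -> int:
        return int(self.flags.sum()) * self.epoch_length

    def nonwear_seconds(self) -> int:
        return int((~self.flags).sum()) * self.epoch_length


def _zero_runs(mask: np.ndarray):
    """(start, end) pairs (end exclusive) of maximal True runs in ``mask``."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_nonwear_zero20(
    series: CountSeries, params: WearAlgorithmParams | None = None
) -> WearMask:
    """Flag maximal zero-count runs spanning >= ``zero_run_min`` minutes."""
    params = params or WearAlgorithmParams(algorithm="zero20")
    counts = series.axis(params.axis_used)
    flags = np.ones(series.n_epochs, dtype=bool)
    intervals = []
    min_seconds = params.zero_run_min * 60
    for s, e in _zero_runs(counts == 0):
        if (e - s) * series.epoch_length >= min_seconds:
            flags[s:e] = False
            intervals.append((int(s), int(e), 0))
    return WearMask(series.epoch_length, flags, intervals)


def detect_nonwear_nhanes(
    series: CountSeries, params: WearAlgorithmParams | None = None
) -> WearMask:
    """NHANES scan with a cumulative per-interval allowance budget.

    Every epoch belongs to exactly one candidate; a candidate closes at a
    terminating epoch (count above the band, or a nonzero epoch the budget
    cannot absorb) and qualifies as non-wear when it spans >= 60 minutes.
    The run preceding a terminator keeps its flag (no retroactive unflag).
    """
    params = params or WearAlgorithmParams(algorithm="nhanes")
    counts = series.axis(params.axis_used)
    epoch = series.epoch_length
    n = series.n_epochs
    band_hi = params.nhanes_allowance_counts
    if params.scale_allowance_band:
        band_hi = band_hi * epoch / 60.0
    budget = params.nhanes_allowance_min * 60
    min_seconds = params.nhanes_window_min * 60

    flags = np.ones(n, dtype=bool)
    intervals = []
    cand_start = 0
    consumed = 0
    # only nonzero epochs can change detector state; zeros extend candidates
    for p in np.flatnonzero(counts):
        c = counts[p]
        if c <= band_hi and consumed + epoch <= budget:
            consumed += epoch
            continue
        # terminating epoch: close the candidate just before it
        if (p - cand_start) * epoch >= min_seconds:
            flags[cand_start:p] = False
            intervals.append((int(cand_start), int(p), int(consumed)))
        cand_start = p + 1
        consumed = 0
    if (n - cand_start) * epoch >= min_seconds:
        flags[cand_start:n] = False
        intervals.append((int(cand_start), int(n), int(consumed)))
    return WearMask(epoch, flags, intervals)


def detect_nonwear_choi(
    series: CountSeries, params: WearAlgorithmParams | None = None
) -> WearMask:
    """Choi scan at minute resolution after an internal collapse to 60-s.

    The output mask is broadcast back to the input epoch length, so wear
    minutes per day are identical whatever the epoch of the input series.
    Epochs past the last complete minute are left as wear.
    """
    params = params or WearAlgorithmParams(algorithm="choi")
    if series.epoch_length == 60:
        minute_counts = series.axis(params.axis_used)
    else:
        minute_counts = reintegrate(series, 60).axis(params.axis_used)
    m = len(minute_counts)
    zero = minute_counts == 0
    eligible = zero.copy()
    spell_minutes = np.zeros(m, dtype=bool)
    w2 = params.choi_window2_min
    for s, e in _zero_runs(~zero):  # maximal nonzero spells
        if e - s > params.choi_allowance_min:
            continue
        if zero[max(0, s - w2) : s].all() and zero[e : min(m, e + w2)].all():
            eligible[s:e] = True
            spell_minutes[s:e] = True

    minute_flags = np.ones(m, dtype=bool)
    minute_intervals = []
    for s, e in _zero_runs(eligible):
        if e - s >= params.choi_window1_min:
            minute_flags[s:e] = False
            allowance = int(spell_minutes[s:e].sum()) * 60
            minute_intervals.append((s, e, allowance))

    k = 60 // series.epoch_length
    n = series.n_epochs
    flags = np.ones(n, dtype=bool)
    flags[: m * k] = np.repeat(minute_flags, k)
    intervals = [(int(s * k), int(e * k), a) for s, e, a in minute_intervals]
    return WearMask(series.epoch_length, flags, intervals)


_DETECTORS = {
    "zero20": detect_nonwear_zero20,
    "nhanes": detect_nonwear_nhanes,
    "choi": detect_nonwear_choi,
}


def detect_nonwear(
    series: CountSeries,
    algorithm: str = "choi",
    params: WearAlgorithmParams | None = None,
) -> WearMask:
    """Dispatch to a detector by name ('zero20', 'nhanes' or 'choi')."""
    if algorithm not in _DETECTORS:
        raise ValueError(f"unknown wear-time algorithm {algorithm!r}")
    if params is None:
        params = WearAlgorithmParams(algorithm=algorithm)
    return _DETECTORS[algorithm](series, params)


def wear_minutes_per_day(mask: WearMask, start_time: datetime) -> pd.DataFrame:
    """Wear minutes per midnight-to-midnight calendar day.

    The full 24-h day is the denominator; wear time is not restricted to the
    daytime scoring window used for intensity classes.
    """
    n = mask.n_epochs
    offset = start_time.hour * 3600 + start_time.minute * 60 + start_time.second
    day = (offset + np.arange(n, dtype=np.int64) * mask.epoch_length) // 86400
    nd = int(day[-1]) + 1 if n else 0
    minutes = np.bincount(day[mask.flags], minlength=nd) * mask.epoch_length / 60.0
    dates = [
        (pd.Timestamp(start_time).normalize() + pd.Timedelta(days=d)).date()
        for d in range(nd)
    ]
    return pd.DataFrame({"day": dates, "wear_min": minutes})


def detection_accuracy(mask: WearMask, truth_wear: np.ndarray):
    """(sensitivity, specificity) of non-wear detection against ground truth.

    ``truth_wear`` is the per-second true wear flag. The mask is broadcast to
    1-s resolution; any trailing seconds not covered by the mask (dropped
    partial blocks) are excluded. Sensitivity is the fraction of true
    non-wear seconds detected as non-wear; specificity the fraction of true
    wear seconds kept as wear. With no true non-wear seconds the sensitivity
    is NaN (with a warning); likewise specificity with no true wear.

    ``truth_wear`` may be a bare per-second boolean array or any object with
    a ``wear`` attribute (the simulator's ground truth).
    """
    truth_wear = getattr(truth_wear, "wear", truth_wear)
    truth_wear = np.asarray(truth_wear, dtype=bool)
    detected_wear = np.repeat(mask.flags, mask.epoch_length)
    n = min(len(detected_wear), len(truth_wear))
    detected_wear = detected_wear[:n]
    truth = truth_wear[:n]

    true_nonwear = ~truth
    true_wear = truth
    if true_nonwear.sum() == 0:
        warnings.warn("no true non-wear seconds; sensitivity undefined")
        sens = float("nan")
    else:
        sens = float((~detected_wear & true_nonwear).sum() / true_nonwear.sum())
    if true_wear.sum() == 0:
        warnings.warn("no true wear seconds; specificity undefined")
        spec = float("nan")
    else:
        spec = float((detected_wear & true_wear).sum() / true_wear.sum())
    return sens, spec
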