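"""Activity-intensity cut-points and per-epoch classification.

Houses five published child cut-point sets, each a row of band upper bounds
in counts per its validated epoch:

========== ================ ============== ======================
set         axis             validated      SB / LPA / MPA uppers
========== ================ ============== ======================
Evenson     vertical         15 s           25, 573, 1002
Treuth      vertical         30 s           50, 1499, 2600
Puyau       vertical         60 s           799, 3199, 8199
Mattocks    vertical         60 s           3580, 6129 (no SB/LPA split)
Romanzini   vector magnitude 15 s           180, 756, 1111
========== ================ ============== ======================

Conversion to another epoch multiplies every bound by ``target/validated``
and keeps it real-valued (e.g. the sedentary bound 100 counts/60-s becomes
25 counts/15-s, and Puyau's 799 becomes 199.75); classification compares
counts to the scaled bound with <=, which reproduces the printed 100-25-50
equivalences exactly and avoids integer-rounding gaps.

Wear epochs are scored only inside the daily window starting at 5:00 AM;
membership is decided by the epoch's *start* time, and "11:59 PM" is read as
end-of-day so the last 60-s epoch scored starts at 23:59:00.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import time

import numpy as np

from .io_actigraph import CountSeries
from .weartime import WearMask

__all__ = [
    "CutPointSet",
    "BUILTIN_CUTPOINTS",
    "CUTPOINT_NAMES",
    "get_cutpoints",
    "convert_cutpoints",
    "classify_epochs",
    "IntensityLabels",
    "NONWEAR",
    "OUT_OF_WINDOW",
    "SB",
    "LPA",
    "MPA",
    "VPA",
    "SBLPA",
]

# label codes (ints, so label arrays stay compact)
NONWEAR = 0
OUT_OF_WINDOW = 1
SB = 2
LPA = 3
MPA = 4
VPA = 5
SBLPA = 6  # combined band for sets without a SB/LPA split

LABEL_NAMES = {
    NONWEAR: "NONWEAR",
    OUT_OF_WINDOW: "OUT_OF_WINDOW",
    SB: "SB",
    LPA: "LPA",
    MPA: "MPA",
    VPA: "VPA",
    SBLPA: "SBLPA_COMBINED",
}

#: default daily scoring window start (5:00 AM; window runs to end of day)
WINDOW_START = time(5, 0, 0)


@dataclass(frozen=True)
class CutPointSet:
    """Band upper bounds of one cut-point set at one epoch length.

    ``bounds`` are the inclusive upper bounds for (SB, LPA, MPA), or for
    (SB+LPA combined, MPA) when ``has_sb_lpa_split`` is False; VPA is open
    above the last bound. ``source_epoch`` records the epoch the set was
    originally validated at, whatever epoch the bounds are expressed at now.
    """

    name: str
    axis: str  # 'vertical' or 'vm'
    epoch_length: int
    bounds: tuple
    has_sb_lpa_split: bool = True
    source_epoch: int | None = None

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.bounds, self.bounds[1:])):
            raise ValueError("band upper bounds must be strictly increasing")
        if self.epoch_length <= 0:
            raise ValueError("epoch length must be positive")
        if self.source_epoch is None:
            object.__setattr__(self, "source_epoch", self.epoch_length)

    @property
    def validated_epoch(self) -> int:
        return self.source_epoch

    @property
    def band_labels(self) -> tuple:
        if self.has_sb_lpa_split:
            return (SB, LPA, MPA, VPA)
        return (SBLPA, MPA, VPA)


BUILTIN_CUTPOINTS = {
    "evenson": CutPointSet("evenson", "vertical", 15, (25, 573, 1002)),
    "treuth": CutPointSet("treuth", "vertical", 30, (50, 1499, 2600)),
    "puyau": CutPointSet("puyau", "vertical", 60, (799, 3199, 8199)),
    "mattocks": CutPointSet(
        "mattocks", "vertical", 60, (3580, 6129), has_sb_lpa_split=False
    ),
    "romanzini": CutPointSet("romanzini", "vm", 15, (180, 756, 1111)),
}

CUTPOINT_NAMES = tuple(BUILTIN_CUTPOINTS)


def get_cutpoints(name: str) -> CutPointSet:
    try:
        return BUILTIN_CUTPOINTS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown cut-point set {name!r}; built-ins: {CUTPOINT_NAMES}"
        ) from None


def convert_cutpoints(cps: CutPointSet, target_epoch: int) -> CutPointSet:
    """Linearly rescale band bounds to ``target_epoch`` (real-valued)."""
    if target_epoch <= 0:
        raise ValueError("target epoch must be positive")
    ratio = target_epoch / cps.epoch_length
    return replace(
        cps,
        epoch_length=target_epoch,
        bounds=tuple(b * ratio for b in cps.bounds),
        source_epoch=cps.source_epoch,
    )


@dataclass
class IntensityLabels:
    """Per-epoch intensity label codes paired with a count series."""

    epoch_length: int
    labels: np.ndarray
    cutpoints: CutPointSet

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    def label_names(self) -> list:
        return [LABEL_NAMES[code] for code in self.labels]


def classify_epochs(
    series: CountSeries,
    mask: WearMask,
    cps: CutPointSet,
    window_start: time = WINDOW_START,
) -> IntensityLabels:
    """Label each epoch SB/LPA/MPA/VPA, NONWEAR or OUT_OF_WINDOW.

    The cut-point set must already be expressed at the series' epoch length
    (call :func:`convert_cutpoints` first); a mismatch raises so conversion
    is always explicit. Counts are compared with <= against the band upper
    bounds on the set's axis (vertical -> axis1, vector magnitude -> vm).
    """
    if cps.epoch_length != series.epoch_length:
        raise ValueError(
            f"cut-point set at {cps.epoch_length}-s epochs cannot score a "
            f"{series.epoch_length}-s series; convert_cutpoints first"
        )
    if mask.n_epochs != series.n_epochs or mask.epoch_length != series.epoch_length:
        raise ValueError("wear mask does not pair with the series")
    counts = series.axis(cps.axis)
    bounds = np.asarray(cps.bounds, dtype=np.float64)
    band = np.searchsorted(bounds, counts, side="left")  # count <= bound -> band
    band_codes = np.asarray(cps.band_labels, dtype=np.int8)
    labels = band_codes[band]

    window_s = window_start.hour * 3600 + window_start.minute * 60 + window_start.second
    in_window = series.seconds_of_day() >= window_s
    labels = np.where(in_window, labels, OUT_OF_WINDOW).astype(np.int8)
    labels[~mask.flags] = NONWEAR
    return IntensityLabels(series.epoch_length, labels, cps)
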