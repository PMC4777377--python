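"""Seeded synthetic child cohort: 1-s count recordings with ground truth.

The generator emulates the statistical structure of week-long hip-worn
recordings from children: activity unfolds as a renewal (semi-Markov)
sequence over the behavioral states SB, LPA, MPA and VPA, with
exponential-like dwell times — long sedentary spans, brief intermittent
MPA/VPA bursts of a few seconds — and per-second vertical counts drawn from
a zero-inflated lognormal distribution per state (children's count streams
are right-skewed with many zero seconds even while active). The default
count distributions are calibrated by closed-form moment calculations so
that within-state 15-s sums fall inside the corresponding Evenson band.

Devices are worn around the clock (the protocol asks children to sleep with
the monitor); a configurable midday true non-wear episode exercises the
detectors, and rare spurious single-second counts during non-wear (magnitude
1-100) reproduce the artifact that makes NHANES wear-time estimates depend
on epoch length. Lateral axes are Poisson-thinned copies of the vertical
axis so the vector magnitude stays proportional to vertical counts.

Every recording is reproducible: per-subject generators are derived from
the master seed with ``numpy.random.SeedSequence`` spawning, so subjects are
independent, collision-free and order-independent.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from datetime import datetime, time

import numpy as np
import pandas as pd

from .io_actigraph import CountSeries, compute_vm, write_counts_csv

__all__ = [
    "StateCounts",
    "NonWearEpisode",
    "SpuriousCounts",
    "SimulationConfig",
    "GroundTruth",
    "simulate_recording",
    "simulate_cohort",
    "STATES",
    "STATE_NONWEAR",
]

# ground-truth state codes (per second)
STATE_NONWEAR = 0
STATE_SB = 1
STATE_LPA = 2
STATE_MPA = 3
STATE_VPA = 4
STATES = ("SB", "LPA", "MPA", "VPA")
STATE_CODES = {"NONWEAR": 0, "SB": 1, "LPA": 2, "MPA": 3, "VPA": 4}


@dataclass(frozen=True)
class StateCounts:
    """Zero-inflated lognormal per-second count model for one state.

    With probability ``1 - zero_prob`` the second's vertical count is
    ``rint(Lognormal(ln(median), sigma))``, else zero.
    """

    zero_prob: float
    median: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_prob <= 1.0:
            raise ValueError("zero_prob must be in [0, 1]")
        if self.median <= 0 or self.sigma <= 0:
            raise ValueError("median and sigma must be positive")

    @property
    def mean_per_second(self) -> float:
        return (1.0 - self.zero_prob) * self.median * np.exp(self.sigma**2 / 2)


@dataclass(frozen=True)
class NonWearEpisode:
    """A daily true non-wear episode at a fixed clock time."""

    start: time = time(15, 0)
    duration_min: float = 150.0
    probability: float = 0.8

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


@dataclass(frozen=True)
class SpuriousCounts:
    """Artifactual counts during true non-wear.

    Single seconds fire at ``rate_per_hour`` with integer magnitudes drawn
    uniformly from ``magnitude`` (inclusive). The default 1-100 range sits
    inside the NHANES allowance band at a 60-s epoch but above the scaled
    band at fine epochs, the mechanism behind the epoch-length effect on
    NHANES wear time.
    """

    rate_per_hour: float = 1.0
    magnitude: tuple = (1, 100)

    def __post_init__(self) -> None:
        if self.rate_per_hour < 0:
            raise ValueError("rate must be non-negative")
        lo, hi = self.magnitude
        if not (0 < lo <= hi):
            raise ValueError("magnitude range must satisfy 0 < lo <= hi")


# Defaults calibrated so within-state 15-s vertical sums sit inside the
# Evenson bands (0-25 / 26-573 / 574-1002 / >=1003): per-second means are
# about 0.49, 19.8, 53.9 and 94.3 counts, i.e. 15-s sums near 7, 297, 809
# and 1415, each >2.7 within-window SDs from the nearest band edge.
DEFAULT_STATE_COUNTS = {
    "SB": StateCounts(zero_prob=0.85, median=3.0, sigma=0.4),
    "LPA": StateCounts(zero_prob=0.50, median=35.0, sigma=0.5),
    "MPA": StateCounts(zero_prob=0.05, median=55.0, sigma=0.25),
    "VPA": StateCounts(zero_prob=0.02, median=92.0, sigma=0.3),
}

DEFAULT_STATE_DWELL = {"SB": 120.0, "LPA": 25.0, "MPA": 10.0, "VPA": 6.0}
DEFAULT_STATE_FRACTIONS = {"SB": 0.65, "LPA": 0.25, "MPA": 0.07, "VPA": 0.03}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings (defaults are the stated world)."""

    n_subjects: int = 50
    n_days: int = 7
    seed: int = 0
    start_time: datetime = datetime(2014, 1, 6, 0, 0, 0)
    state_dwell: dict = field(default_factory=lambda: dict(DEFAULT_STATE_DWELL))
    state_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_STATE_FRACTIONS)
    )
    state_counts: dict = field(default_factory=lambda: dict(DEFAULT_STATE_COUNTS))
    wear_schedule: tuple = (NonWearEpisode(),)
    spurious_nonwear: SpuriousCounts = SpuriousCounts()
    lateral_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_days <= 0:
            raise ValueError("n_subjects and n_days must be positive")
        states = [s for s in STATES if self.state_fractions.get(s, 0.0) > 0.0]
        if not states:
            raise ValueError("at least one behavioral state must be enabled")
        for s in states:
            if s not in self.state_dwell or self.state_dwell[s] <= 0:
                raise ValueError(f"state {s} needs a positive mean dwell")
            if s not in self.state_counts:
                raise ValueError(f"state {s} needs a count distribution")
        if self.lateral_ratio < 0:
            raise ValueError("lateral_ratio must be non-negative")

    def entry_probabilities(self) -> dict:
        """Segment-entry probabilities giving the target time occupancy.

        For a renewal sequence with iid state draws, long-run occupancy is
        ``q_s * m_s / sum(q * m)``; inverting, ``q_s ∝ f_s / m_s``.
        """
        states = [s for s in STATES if self.state_fractions.get(s, 0.0) > 0.0]
        w = np.array([self.state_fractions[s] / self.state_dwell[s] for s in states])
        w = w / w.sum()
        return dict(zip(states, w))


@dataclass
class GroundTruth:
    """Per-second true behavioral state and wear status."""

    states: np.ndarray  # int8 codes, STATE_NONWEAR..STATE_VPA
    wear: np.ndarray  # bool; False exactly where states == STATE_NONWEAR

    def __post_init__(self) -> None:
        if len(self.states) != len(self.wear):
            raise ValueError("states and wear must have equal length")

    @property
    def n_seconds(self) -> int:
        return len(self.states)

    def occupancy(self) -> dict:
        """Fraction of wear seconds spent in each behavioral state."""
        wear_states = self.states[self.wear]
        total = len(wear_states)
        return {
            s: float((wear_states == STATE_CODES[s]).sum() / total) if total else 0.0
            for s in STATES
        }


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, subject_index]))


def _draw_state_sequence(
    config: SimulationConfig, rng: np.random.Generator, n_seconds: int
) -> np.ndarray:
    entry = config.entry_probabilities()
    states = list(entry)
    probs = np.array([entry[s] for s in states])
    mean_dwell = np.array([config.state_dwell[s] for s in states])
    codes = np.array([STATE_CODES[s] for s in states], dtype=np.int8)
    mean_seg = float(probs @ mean_dwell)
    out = np.empty(0, dtype=np.int8)
    while out.size < n_seconds:
        m = max(64, int(1.5 * (n_seconds - out.size) / mean_seg) + 16)
        idx = rng.choice(len(states), size=m, p=probs)
        dwells = np.maximum(1, np.rint(rng.exponential(mean_dwell[idx]))).astype(
            np.int64
        )
        out = np.concatenate([out, np.repeat(codes[idx], dwells)])
    return out[:n_seconds]


def _draw_counts(
    config: SimulationConfig, rng: np.random.Generator, states: np.ndarray
) -> np.ndarray:
    counts = np.zeros(len(states), dtype=np.int64)
    for s in STATES:
        m = states == STATE_CODES[s]
        k = int(m.sum())
        if k == 0:
            continue
        dist = config.state_counts[s]
        nonzero = rng.random(k) >= dist.zero_prob
        vals = np.zeros(k, dtype=np.int64)
        nnz = int(nonzero.sum())
        if nnz:
            draws = rng.lognormal(np.log(dist.median), dist.sigma, size=nnz)
            vals[nonzero] = np.maximum(1, np.rint(draws)).astype(np.int64)
        counts[m] = vals
    return counts


def simulate_recording(
    config: SimulationConfig, subject_index: int
) -> tuple[CountSeries, GroundTruth]:
    """Generate one subject's 1-s recording and its ground truth.

    Deterministic in ``(config, subject_index)``: repeated calls return
    identical series and truth.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError(
            f"subject_index {subject_index} outside [0, {config.n_subjects})"
        )
    rng = _subject_rng(config.seed, subject_index)
    n_seconds = config.n_days * 86400

    states = _draw_state_sequence(config, rng, n_seconds)
    axis1 = _draw_counts(config, rng, states)

    # overwrite scheduled non-wear episodes
    wear = np.ones(n_seconds, dtype=bool)
    for episode in config.wear_schedule:
        ep_start = (
            episode.start.hour * 3600 + episode.start.minute * 60 + episode.start.second
        )
        dur = int(round(episode.duration_min * 60))
        for day in range(config.n_days):
            if rng.random() >= episode.probability:
                continue
            s = day * 86400 + ep_start
            e = min(s + dur, n_seconds)
            wear[s:e] = False
    states[~wear] = STATE_NONWEAR
    axis1[~wear] = 0

    # spurious artifact counts during true non-wear
    sp = config.spurious_nonwear
    nonwear_idx = np.flatnonzero(~wear)
    if sp.rate_per_hour > 0 and nonwear_idx.size:
        fire = rng.random(nonwear_idx.size) < sp.rate_per_hour / 3600.0
        hit = nonwear_idx[fire]
        lo, hi = sp.magnitude
        axis1[hit] = rng.integers(lo, hi + 1, size=hit.size)

    ratio = config.lateral_ratio
    axis2 = rng.poisson(ratio * axis1).astype(np.int64)
    axis3 = rng.poisson(ratio * axis1).astype(np.int64)

    series = CountSeries(
        start_time=config.start_time,
        epoch_length=1,
        axis1=axis1,
        axis2=axis2,
        axis3=axis3,
        vm=compute_vm(axis1, axis2, axis3),
        subject_id=f"S{subject_index:03d}",
    )
    truth = GroundTruth(states=states, wear=wear)
    return series, truth


def write_truth_csv(truth: GroundTruth, path) -> None:
    names = {v: k for k, v in STATE_CODES.items()}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("second,state,wear\n")
        for i, (s, w) in enumerate(zip(truth.states, truth.wear)):
            fh.write(f"{i},{names[int(s)]},{int(w)}\n")


def read_truth_csv(path) -> GroundTruth:
    df = pd.read_csv(path)
    states = df["state"].map(STATE_CODES).to_numpy(dtype=np.int8)
    wear = df["wear"].to_numpy(dtype=bool)
    return GroundTruth(states=states, wear=wear)


def simulate_cohort(
    config: SimulationConfig, out_dir, overwrite: bool = False
) -> pd.DataFrame:
    """Write one counts CSV and one truth CSV per subject, plus a manifest.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set. Returns the manifest table (also saved as
    ``manifest.csv``).
    """
    os.makedirs(out_dir, exist_ok=True)
    if os.listdir(out_dir) and not overwrite:
        raise FileExistsError(
            f"{out_dir} is not empty; pass overwrite=True to replace it"
        )
    rows = []
    for i in range(config.n_subjects):
        series, truth = simulate_recording(config, i)
        counts_path = os.path.join(out_dir, f"counts_{i:03d}.csv")
        truth_path = os.path.join(out_dir, f"truth_{i:03d}.csv")
        write_counts_csv(series, counts_path)
        write_truth_csv(truth, truth_path)
        rows.append(
            {
                "subject_id": series.subject_id,
                "subject_index": i,
                "seed": config.seed,
                "counts_file": os.path.basename(counts_path),
                "truth_file": os.path.basename(truth_path),
                "n_epochs": series.n_epochs,
                "total_axis1": int(series.axis1.sum()),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
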