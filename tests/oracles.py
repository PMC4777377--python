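"""Independent brute-force reference implementations for cross-checks.

These re-implement each operation directly from its plain-language
definition — per-epoch state walks, explicit window scans, explicit
sums-of-squares — without sharing code with the package. They are
deliberately slow and simple.
"""

from __future__ import annotations

import numpy as np


def zero20_oracle(counts, epoch_length, zero_run_min=20):
    """Wear flags: non-wear = maximal zero runs spanning >= 20 minutes."""
    counts = list(counts)
    n = len(counts)
    wear = [True] * n
    i = 0
    while i < n:
        if counts[i] == 0:
            j = i
            while j < n and counts[j] == 0:
                j += 1
            if (j - i) * epoch_length >= zero_run_min * 60:
                for k in range(i, j):
                    wear[k] = False
            i = j
        else:
            i += 1
    return np.array(wear)


def nhanes_oracle(
    counts,
    epoch_length,
    window_min=60,
    allowance_min=2,
    band_hi_60s=100.0,
    scale_band=True,
):
    """Wear flags + intervals from a plain per-epoch NHANES state walk."""
    band_hi = band_hi_60s * epoch_length / 60.0 if scale_band else band_hi_60s
    budget = allowance_min * 60
    counts = list(counts)
    n = len(counts)
    wear = [True] * n
    intervals = []

    def close(start, end, consumed):
        if (end - start) * epoch_length >= window_min * 60:
            for k in range(start, end):
                wear[k] = False
            intervals.append((start, end, consumed))

    start, consumed = 0, 0
    for i, c in enumerate(counts):
        if c == 0:
            continue
        if 0 < c <= band_hi and consumed + epoch_length <= budget:
            consumed += epoch_length
        else:
            close(start, i, consumed)
            start, consumed = i + 1, 0
    close(start, n, consumed)
    return np.array(wear), intervals


def choi_oracle(
    counts,
    epoch_length,
    window1_min=90,
    allowance_min=2,
    window2_min=30,
):
    """Wear flags from a direct evaluation of the two-window definition.

    Collapses to minutes by explicit summation, inspects every nonzero
    minute spell with explicit flank scans, then marks eligible runs of at
    least window-1 length.
    """
    counts = list(counts)
    k = 60 // epoch_length
    m = len(counts) // k
    minutes = [sum(counts[i * k : (i + 1) * k]) for i in range(m)]
    zero = [v == 0 for v in minutes]

    eligible = list(zero)
    i = 0
    while i < m:
        if not zero[i]:
            j = i
            while j < m and not zero[j]:
                j += 1
            spell_ok = (j - i) <= allowance_min
            if spell_ok:
                for u in range(max(0, i - window2_min), i):
                    if not zero[u]:
                        spell_ok = False
                for d in range(j, min(m, j + window2_min)):
                    if not zero[d]:
                        spell_ok = False
            if spell_ok:
                for t in range(i, j):
                    eligible[t] = True
            i = j
        else:
            i += 1

    minute_wear = [True] * m
    i = 0
    while i < m:
        if eligible[i]:
            j = i
            while j < m and eligible[j]:
                j += 1
            if j - i >= window1_min:
                for t in range(i, j):
                    minute_wear[t] = False
            i = j
        else:
            i += 1

    wear = [True] * len(counts)
    for t in range(m):
        for u in range(t * k, (t + 1) * k):
            wear[u] = minute_wear[t]
    return np.array(wear)


def anova_f_oracle(groups):
    """One-way ANOVA F from explicit between/within sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    if ss_within == 0:
        return 0.0 if ss_between == 0 else float("inf")
    return (ss_between / df1) / (ss_within / df2)


def random_sparse_stream(rng, epoch_length, n_epochs):
    """A zero-dominated count stream with bursts, low counts and spikes.

    Built to exercise detector candidates: long zero runs broken by short
    activity bursts whose counts straddle the allowance bands.
    """
    counts = np.zeros(n_epochs, dtype=np.int64)
    i = 0
    while i < n_epochs:
        gap = int(rng.exponential(45 * 60 / epoch_length)) + 1
        i += gap
        if i >= n_epochs:
            break
        burst_len = 1 + int(rng.exponential(2))
        kind = rng.random()
        if kind < 0.4:  # low counts, allowance-band scale
            vals = rng.integers(1, 100, size=burst_len)
        elif kind < 0.8:  # activity-scale counts
            vals = rng.integers(100, 4000, size=burst_len)
        else:  # single tiny blip
            burst_len, vals = 1, np.array([rng.integers(1, 8)])
        j = min(n_epochs, i + burst_len)
        counts[i:j] = vals[: j - i]
        i = j
    return counts
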