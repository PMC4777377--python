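"""Factorial comparison of epoch lengths, wear-time algorithms, cut-points.

Reproduces the study design around the pipeline: per-subject mean estimates
of wear time and intensity classes are compared

* **by epoch length** (1, 5, 10, 15, 30, 60 s) within each wear-time
  algorithm and cut-point set, with a one-way ANOVA F test per measure and
  Bonferroni significance at alpha = 0.05/11 (one WT measure plus five
  classes in minutes and percent), and paired post-hoc contrasts of every
  epoch against the validated epoch;
* **by cut-point set** at each set's validated epoch within each wear-time
  algorithm, at alpha = 0.05/10, excluding the Mattocks set from SB and LPA
  comparisons (it has no SB/LPA split).

The ANOVA is a one-way fixed-factor F test on per-subject means (subjects
contribute one value per level); a repeated-measures variant over subjects
is available via ``anova_one_factor(..., repeated=True)``. Post-hoc
contrasts are paired t tests on per-subject differences, reported raw and
judged against the family Bonferroni alpha.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intensity import CUTPOINT_NAMES, classify_epochs, convert_cutpoints, get_cutpoints
from .io_actigraph import VALID_EPOCHS, CountSeries, read_counts_csv, write_table_csv
from .reintegrate import reintegrate
from .summarize import apply_valid_day_rule, daily_summaries, participant_means
from .weartime import (
    ALGORITHMS,
    WearAlgorithmParams,
    detect_nonwear,
    wear_minutes_per_day,
)

__all__ = [
    "anova_one_factor",
    "bonferroni_alpha",
    "posthoc_pairwise",
    "process_recording",
    "process_cohort",
    "compare_by_epoch",
    "compare_by_cutpoint",
    "run_comparison_grid",
    "GridSpec",
]

#: measures per family: WT plus five classes in minutes and percent -> 11
BY_EPOCH_N_TESTS = 11
#: five classes in minutes and percent -> 10
BY_CUTPOINT_N_TESTS = 10

#: reference ("derived") epoch per wear-time algorithm for WT post-hoc
#: contrasts; the 20-min zero-run algorithm has no derived epoch and uses
#: the 60-s convention of the other two
WT_REFERENCE_EPOCH = {"zero20": 60, "nhanes": 60, "choi": 60}

CLASS_MEASURES_SPLIT = [
    "sb_min", "lpa_min", "mpa_min", "vpa_min", "mvpa_min",
    "sb_pct", "lpa_pct", "mpa_pct", "vpa_pct", "mvpa_pct",
]
CLASS_MEASURES_COMBINED = [
    "sblpa_min", "mpa_min", "vpa_min", "mvpa_min",
    "sblpa_pct", "mpa_pct", "vpa_pct", "mvpa_pct",
]


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test significance threshold ``family_alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return family_alpha / n_tests


def anova_one_factor(table: pd.DataFrame, repeated: bool = False):
    """One-way ANOVA across factor levels on per-subject values.

    ``table`` needs columns ``level`` and ``value`` (and ``subject_id`` for
    the repeated-measures variant). Returns ``(F, p)``. Degenerate input in
    which every value is identical returns ``(0.0, 1.0)`` rather than a
    division blow-up.
    """
    groups = [g["value"].to_numpy(dtype=float) for _, g in table.groupby("level")]
    if len(groups) < 2:
        raise ValueError("need at least two factor levels")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least two observations per level")
    allvals = np.concatenate(groups)
    if np.allclose(allvals, allvals[0], rtol=0, atol=0):
        return 0.0, 1.0
    if repeated:
        wide = table.pivot(index="subject_id", columns="level", values="value").dropna()
        data = wide.to_numpy(dtype=float)
        n, k = data.shape
        grand = data.mean()
        ss_factor = n * ((data.mean(axis=0) - grand) ** 2).sum()
        ss_subject = k * ((data.mean(axis=1) - grand) ** 2).sum()
        ss_total = ((data - grand) ** 2).sum()
        ss_error = ss_total - ss_factor - ss_subject
        df1, df2 = k - 1, (k - 1) * (n - 1)
        if ss_error <= 0:
            return (0.0, 1.0) if ss_factor == 0 else (np.inf, 0.0)
        F = (ss_factor / df1) / (ss_error / df2)
        return float(F), float(stats.f.sf(F, df1, df2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(*groups)
    if not np.isfinite(F):
        return 0.0, 1.0
    return float(F), float(p)


def posthoc_pairwise(table: pd.DataFrame, reference_level) -> pd.DataFrame:
    """Paired contrasts of every non-reference level against the reference.

    ``table`` needs columns ``subject_id``, ``level``, ``value``. Each
    contrast pairs subjects' values at the two levels; rows report the mean
    difference (level minus reference) and the paired t-test p value. Zero-
    variance differences report p = 1 when the mean difference is 0 and
    p = 0 otherwise.
    """
    wide = table.pivot(index="subject_id", columns="level", values="value")
    if reference_level not in wide.columns:
        raise ValueError(f"reference level {reference_level!r} not present")
    rows = []
    for level in wide.columns:
        if level == reference_level:
            continue
        pair = wide[[level, reference_level]].dropna()
        if len(pair) < 2:
            raise ValueError("need at least two subjects for a paired contrast")
        diff = pair[level] - pair[reference_level]
        mean_diff = float(diff.mean())
        if np.allclose(diff, diff.iloc[0], rtol=0, atol=0):
            p = 1.0 if diff.iloc[0] == 0 else 0.0
        else:
            p = float(stats.ttest_rel(pair[level], pair[reference_level]).pvalue)
        rows.append(
            {
                "level_a": level,
                "level_b": reference_level,
                "mean_difference": mean_diff,
                "p": p,
                "n_pairs": len(pair),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline orchestration


def process_recording(
    series_1s: CountSeries,
    *,
    algorithms=ALGORITHMS,
    epochs=VALID_EPOCHS,
    cutpoints=CUTPOINT_NAMES,
    wear_params: dict | None = None,
):
    """Run the full pipeline for one recording.

    Reintegrates to every requested epoch, detects non-wear with every
    algorithm, classifies with every cut-point set (converted to the epoch),
    summarizes per day, and applies the 360-min valid-day rule judged at
    60-s epochs per algorithm. Returns ``(wt_df, summary_df)`` tidy tables
    restricted to valid days.
    """
    if 60 not in epochs:
        raise ValueError("the valid-day rule requires the 60-s epoch in `epochs`")
    if wear_params is None:
        wear_params = {}
    start = series_1s.start_time
    sid = series_1s.subject_id
    series_by_epoch = {
        e: (series_1s if e == series_1s.epoch_length else reintegrate(series_1s, e))
        for e in sorted(set(epochs))
    }

    wt_frames = []
    summary_frames = []
    for algo in algorithms:
        params = wear_params.get(algo, WearAlgorithmParams(algorithm=algo))
        masks = {e: detect_nonwear(series_by_epoch[e], algo, params) for e in epochs}
        wt_by_epoch = {}
        for e in epochs:
            wt = wear_minutes_per_day(masks[e], start)
            wt.insert(0, "subject_id", sid)
            wt_by_epoch[e] = wt
        summaries_by_epoch = {e: [] for e in epochs}
        for name in cutpoints:
            base = get_cutpoints(name)
            for e in epochs:
                cps = base if e == base.epoch_length else convert_cutpoints(base, e)
                labels = classify_epochs(series_by_epoch[e], masks[e], cps)
                ds = daily_summaries(labels, masks[e], start, subject_id=sid)
                ds.insert(1, "cutpoint", name)
                summaries_by_epoch[e].append(ds)
        stacked = {e: pd.concat(frames, ignore_index=True) for e, frames in summaries_by_epoch.items()}
        valid = apply_valid_day_rule(stacked, wt_by_epoch[60])
        for e in epochs:
            tab = valid[e]
            tab.insert(1, "algorithm", algo)
            tab.insert(2, "epoch_length", e)
            summary_frames.append(tab)
            wt = wt_by_epoch[e].merge(
                wt_by_epoch[60][["subject_id", "day", "wear_min"]].rename(
                    columns={"wear_min": "wt60"}
                ),
                on=["subject_id", "day"],
            )
            wt = wt[wt["wt60"] >= 360.0].drop(columns="wt60")
            wt.insert(1, "algorithm", algo)
            wt.insert(2, "epoch_length", e)
            wt_frames.append(wt)
    return (
        pd.concat(wt_frames, ignore_index=True),
        pd.concat(summary_frames, ignore_index=True),
    )


def process_cohort(recordings, **kwargs):
    """Concatenate :func:`process_recording` outputs over an iterable."""
    wt_all, summary_all = [], []
    for series in recordings:
        wt, summary = process_recording(series, **kwargs)
        wt_all.append(wt)
        summary_all.append(summary)
    return pd.concat(wt_all, ignore_index=True), pd.concat(summary_all, ignore_index=True)


def _subject_level_table(df: pd.DataFrame, level_col: str, measure: str) -> pd.DataFrame:
    """Per-subject mean of ``measure`` at each level, in long form."""
    rows = []
    for level, group in df.groupby(level_col):
        means = participant_means(group)
        for _, r in means.iterrows():
            rows.append(
                {"subject_id": r["subject_id"], "level": level, "value": r[measure]}
            )
    out = pd.DataFrame(rows)
    return out.dropna(subset=["value"])


def compare_by_epoch(
    wt_df: pd.DataFrame,
    summary_df: pd.DataFrame,
    algorithm: str,
    cutpoint: str,
    family_alpha: float = 0.05,
    n_tests: int = BY_EPOCH_N_TESTS,
):
    """Estimates / ANOVA / post-hoc by epoch length for one algorithm x set."""
    alpha = bonferroni_alpha(family_alpha, n_tests)
    cps = get_cutpoints(cutpoint)
    measures = (
        CLASS_MEASURES_SPLIT if cps.has_sb_lpa_split else CLASS_MEASURES_COMBINED
    )
    wt = wt_df[wt_df["algorithm"] == algorithm].rename(columns={"wear_min": "wt_min"})
    cls = summary_df[
        (summary_df["algorithm"] == algorithm) & (summary_df["cutpoint"] == cutpoint)
    ]
    estimates, anova, posthoc = [], [], []
    for measure in ["wt_min"] + measures:
        source = wt if measure == "wt_min" else cls
        reference = (
            WT_REFERENCE_EPOCH[algorithm] if measure == "wt_min" else cps.validated_epoch
        )
        table = _subject_level_table(source, "epoch_length", measure)
        F, p = anova_one_factor(table)
        anova.append(
            {
                "measure": measure,
                "F": F,
                "p": p,
                "alpha_bonferroni": alpha,
                "significant": p < alpha,
            }
        )
        for level, g in table.groupby("level"):
            estimates.append(
                {
                    "measure": measure,
                    "epoch_length": level,
                    "mean": g["value"].mean(),
                    "sd": g["value"].std(ddof=1),
                    "n_subjects": len(g),
                }
            )
        ph = posthoc_pairwise(table, reference)
        ph.insert(0, "measure", measure)
        posthoc.append(ph)
    return {
        "estimates": pd.DataFrame(estimates),
        "anova": pd.DataFrame(anova),
        "posthoc": pd.concat(posthoc, ignore_index=True),
    }


def compare_by_cutpoint(
    summary_df: pd.DataFrame,
    algorithm: str,
    cutpoints=CUTPOINT_NAMES,
    family_alpha: float = 0.05,
    n_tests: int = BY_CUTPOINT_N_TESTS,
):
    """Estimates / ANOVA / pairwise contrasts across cut-point sets.

    Each set contributes its own validated epoch; sets without a SB/LPA
    split are excluded from the SB and LPA comparisons.
    """
    alpha = bonferroni_alpha(family_alpha, n_tests)
    frames = {}
    for name in cutpoints:
        cps = get_cutpoints(name)
        sub = summary_df[
            (summary_df["algorithm"] == algorithm)
            & (summary_df["cutpoint"] == name)
            & (summary_df["epoch_length"] == cps.validated_epoch)
        ].copy()
        if not cps.has_sb_lpa_split:
            # the combined band stands in for SB+LPA where a split measure
            # is not comparable; only MPA/VPA/MVPA rows are used below
            sub["sb_min"] = np.nan
            sub["lpa_min"] = np.nan
        frames[name] = sub
    estimates, anova, posthoc = [], [], []
    for measure in CLASS_MEASURES_SPLIT:
        eligible = [
            name
            for name in cutpoints
            if get_cutpoints(name).has_sb_lpa_split
            or not (measure.startswith("sb_") or measure.startswith("lpa_"))
        ]
        rows = []
        for name in eligible:
            tab = _subject_level_table(frames[name], "cutpoint", measure)
            rows.append(tab)
        table = pd.concat(rows, ignore_index=True)
        if len(eligible) < 2:
            # a single comparable set (e.g. SB with only Mattocks excluded)
            # leaves nothing to test; keep the estimates, skip the F test
            for level, g in table.groupby("level"):
                estimates.append(
                    {
                        "measure": measure,
                        "cutpoint": level,
                        "mean": g["value"].mean(),
                        "sd": g["value"].std(ddof=1),
                        "n_subjects": len(g),
                    }
                )
            continue
        F, p = anova_one_factor(table)
        anova.append(
            {
                "measure": measure,
                "F": F,
                "p": p,
                "alpha_bonferroni": alpha,
                "significant": p < alpha,
            }
        )
        for level, g in table.groupby("level"):
            estimates.append(
                {
                    "measure": measure,
                    "cutpoint": level,
                    "mean": g["value"].mean(),
                    "sd": g["value"].std(ddof=1),
                    "n_subjects": len(g),
                }
            )
        for a, b in itertools.combinations(eligible, 2):
            pair = table[table["level"].isin([a, b])]
            ph = posthoc_pairwise(pair, b)
            ph.insert(0, "measure", measure)
            posthoc.append(ph)
    empty = pd.DataFrame(
        columns=["measure", "level_a", "level_b", "mean_difference", "p", "n_pairs"]
    )
    return {
        "estimates": pd.DataFrame(estimates),
        "anova": pd.DataFrame(anova),
        "posthoc": pd.concat(posthoc, ignore_index=True) if posthoc else empty,
    }


@dataclass(frozen=True)
class GridSpec:
    """Which algorithm x cut-point x epoch combinations the grid covers."""

    algorithms: tuple = ALGORITHMS
    cutpoints: tuple = CUTPOINT_NAMES
    epochs: tuple = VALID_EPOCHS
    family_alpha: float = 0.05
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def digest(self) -> str:
        payload = json.dumps(
            {
                "algorithms": list(self.algorithms),
                "cutpoints": list(self.cutpoints),
                "epochs": list(self.epochs),
                "family_alpha": self.family_alpha,
                "seed": self.seed,
                "extra": self.extra,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_comparison_grid(cohort_dir, out_dir, grid: GridSpec | None = None):
    """Process a simulated (or real) cohort on disk and write report tables.

    Expects a ``manifest.csv`` naming one counts CSV per subject. Writes one
    by-epoch CSV per algorithm x cut-point and one by-cutpoint CSV per
    algorithm, plus ``run_metadata.json``. Requested combinations that
    cannot be produced are reported together in one error, never skipped
    silently.
    """
    grid = grid or GridSpec()
    manifest_path = os.path.join(cohort_dir, "manifest.csv")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"no manifest.csv in {cohort_dir}")
    manifest = pd.read_csv(manifest_path)
    gaps = [name for name in grid.cutpoints if name.lower() not in CUTPOINT_NAMES]
    gaps += [a for a in grid.algorithms if a not in ALGORITHMS]
    if gaps:
        raise ValueError(f"unknown grid entries, nothing written: {gaps}")

    def recordings():
        for _, row in manifest.iterrows():
            yield read_counts_csv(
                os.path.join(cohort_dir, row["counts_file"]),
                subject_id=str(row["subject_id"]),
            )

    wt_df, summary_df = process_cohort(
        recordings(),
        algorithms=grid.algorithms,
        epochs=grid.epochs,
        cutpoints=grid.cutpoints,
    )
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for algo in grid.algorithms:
        for name in grid.cutpoints:
            res = compare_by_epoch(wt_df, summary_df, algo, name, grid.family_alpha)
            path = os.path.join(out_dir, f"by_epoch_{algo}_{name}.csv")
            _write_report(res, path)
            written.append(os.path.basename(path))
        res = compare_by_cutpoint(summary_df, algo, grid.cutpoints, grid.family_alpha)
        path = os.path.join(out_dir, f"by_cutpoint_{algo}.csv")
        _write_report(res, path)
        written.append(os.path.basename(path))
    meta = {
        "config_digest": grid.digest(),
        "seed": grid.seed,
        "n_subjects": int(manifest.shape[0]),
        "tables": written,
    }
    with open(os.path.join(out_dir, "run_metadata.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return wt_df, summary_df


def _write_report(res: dict, path) -> None:
    """Flatten an estimates/anova/posthoc dict into one sectioned CSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for section in ("estimates", "anova", "posthoc"):
            fh.write(f"# {section}\n")
            fh.write(res[section].to_csv(index=False, lineterminator="\n", float_format="%.6g"))
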