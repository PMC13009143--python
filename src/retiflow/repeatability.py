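"""Repeatability and reliability statistics for repeated biomarker sets.

Per-subject mean, sample SD and coefficient of variation over repeated
measurements, group summaries (mean ± 1σ across subjects), and
Student-t 95% confidence intervals of the mean CoV. Single-eye designs
(axial sweep, lateral gaze positions) are summarized directly across
positions. Measurements that did not span enough cardiac cycles (e.g.
interrupted by a blink) are excluded before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BIOMARKER_NAMES
from .errors import DegenerateInputError, InvalidSpecError

__all__ = [
    "cov", "t_quantile_975", "ci95", "exclude_incomplete",
    "summarize_study", "RepeatabilityTable",
]

#: Columns identifying a measurement row in a study table.
KEY_COLUMNS = ("subject_id", "session_id", "repeat_id", "design_label")


def cov(values) -> float:
    """Coefficient of variation, percent: 100 * sample SD / mean.

    Sample (n-1 denominator) standard deviation; requires at least two
    values and a nonzero mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateInputError("CoV needs at least two values")
    mean = values.mean()
    if mean == 0:
        raise DegenerateInputError("CoV undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def t_quantile_975(n: int) -> float:
    """Two-sided 97.5th-percentile Student-t coefficient, df = n - 1."""
    if n < 2:
        raise InvalidSpecError("need a group of at least two")
    return float(stats.t.ppf(0.975, df=n - 1))


def ci95(values):
    """(mean, lower, upper): mean ± t_0.975(n-1) * SD / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateInputError("CI needs at least two values")
    n = values.size
    mean = float(values.mean())
    half = t_quantile_975(n) * float(values.std(ddof=1)) / np.sqrt(n)
    return mean, mean - half, mean + half


def exclude_incomplete(study: pd.DataFrame, min_cycles: int = 2):
    """Drop measurements with fewer than ``min_cycles`` detected cycles.

    Mirrors the blink-exclusion rule: only measurements spanning several
    cardiac cycles enter repeatability analysis. Returns the filtered
    table and a report DataFrame listing removed rows. Groups (subjects)
    left with fewer than two rows are dropped entirely, with a warning
    entry in the report.
    """
    if min_cycles < 1:
        raise InvalidSpecError("min_cycles must be >= 1")
    if "n_detected_cycles" not in study.columns:
        raise InvalidSpecError("study table lacks an n_detected_cycles column")
    removed = study[study["n_detected_cycles"] < min_cycles].copy()
    removed["reason"] = f"fewer than {min_cycles} cardiac cycles"
    kept = study[study["n_detected_cycles"] >= min_cycles].copy()
    drops = []
    for sid, grp in kept.groupby("subject_id"):
        if len(grp) < 2:
            d = grp.copy()
            d["reason"] = "subject left with fewer than two measurements"
            drops.append(d)
            kept = kept[kept["subject_id"] != sid]
    report = pd.concat([removed] + drops, ignore_index=True) if drops \
        else removed.reset_index(drop=True)
    return kept.reset_index(drop=True), report


@dataclass
class RepeatabilityTable:
    """Group summary: one row per metric, plus the CoV confidence interval.

    ``table`` columns: mean_mean / mean_sd (mean and ±1σ of per-subject
    means), sd_mean / sd_sd, cov_mean / cov_sd (%), n (subjects),
    cov_ci_lo / cov_ci_hi (95% CI of the mean CoV).
    """

    table: pd.DataFrame
    design_label: str
    n_groups: int

    def to_csv(self, path):
        self.table.to_csv(path)

    def __str__(self):
        with pd.option_context("display.width", 120,
                               "display.float_format", "{:8.3f}".format):
            return (f"design={self.design_label}  n={self.n_groups}\n"
                    + str(self.table))


def summarize_study(study: pd.DataFrame, metrics=BIOMARKER_NAMES,
                    design_label: str | None = None) -> RepeatabilityTable:
    """Per-metric repeatability summary of a grouped study table.

    For multi-subject designs, per-subject (mean, SD, CoV) statistics
    over that subject's repeats are averaged across subjects, reported
    with their ±1σ group dispersion, plus the t-based 95% CI of the mean
    CoV. Single-group designs (axial/lateral: one eye, several
    positions) are summarized directly across positions.
    """
    if len(study) == 0:
        raise InvalidSpecError("empty study")
    if design_label is None:
        design_label = (study["design_label"].iloc[0]
                        if "design_label" in study.columns else "unknown")
    metrics = [m for m in metrics if m in study.columns]
    if not metrics:
        raise InvalidSpecError("no known metric columns in the study table")
    single_group = design_label in ("axial", "lateral") \
        or study["subject_id"].nunique() == 1

    rows = {}
    if single_group:
        n = len(study)
        if n < 2:
            raise InvalidSpecError("need at least two measurements")
        for m in metrics:
            vals = study[m].to_numpy(dtype=float)
            rows[m] = {
                "mean_mean": vals.mean(), "mean_sd": vals.std(ddof=1),
                "sd_mean": vals.std(ddof=1), "sd_sd": np.nan,
                "cov_mean": cov(vals), "cov_sd": np.nan,
                "n": n, "cov_ci_lo": np.nan, "cov_ci_hi": np.nan,
            }
        n_groups = n
    else:
        groups = list(study.groupby("subject_id"))
        n_groups = len(groups)
        for m in metrics:
            means, sds, covs = [], [], []
            for _, grp in groups:
                vals = grp[m].to_numpy(dtype=float)
                if vals.size < 2:
                    continue
                means.append(vals.mean())
                sds.append(vals.std(ddof=1))
                covs.append(cov(vals))
            means, sds, covs = map(np.asarray, (means, sds, covs))
            _, lo, hi = ci95(covs) if covs.size >= 2 else (np.nan,) * 3
            rows[m] = {
                "mean_mean": means.mean(), "mean_sd": means.std(ddof=1),
                "sd_mean": sds.mean(), "sd_sd": sds.std(ddof=1),
                "cov_mean": covs.mean(), "cov_sd": covs.std(ddof=1),
                "n": covs.size, "cov_ci_lo": lo, "cov_ci_hi": hi,
            }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "metric"
    return RepeatabilityTable(table=table, design_label=design_label,
                              n_groups=n_groups)
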