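"""Plant-growth biotest statistics.

Group summaries (mean +/- sample SD per trait), derived report columns
(percent increase and fold change of shoot dry mass versus the untreated
control, root-to-shoot dry mass ratio), per-week Dunnett flags for shoot
length time courses, and Tukey end-point comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import screen

logger = logging.getLogger(__name__)

TRAITS = ("SL", "SFM", "SDM", "RDM")


@dataclass(frozen=True)
class PercentIncrease:
    percent: float  # 100 * (treat - con) / con, unrounded
    fold: float     # treat / con, unrounded

    @property
    def percent_rounded(self) -> int:
        return int(round(self.percent))

    @property
    def fold_rounded(self) -> float:
        return round(self.fold, 1)


def summarize_groups(growth: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) per soil x treatment x trait.

    Groups with a single plant get a missing SD.
    """
    traits = [t for t in (traits or TRAITS) if t in growth.columns]
    if not traits:
        raise ValueError("no trait columns found")
    rows = []
    for (soil, treatment), g in growth.groupby(["soil", "treatment"], sort=True):
        row = {"soil": soil, "treatment": treatment, "n": len(g)}
        for t in traits:
            v = g[t].astype(float).values
            row[f"{t}_mean"] = float(v.mean())
            row[f"{t}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index(["soil", "treatment"])


def percent_increase(mean_treat: float, mean_con: float) -> PercentIncrease:
    """Percent increase and fold change of a treated group mean over the
    control mean.  ``fold = 1 + percent/100`` exactly (before rounding)."""
    if mean_con <= 0:
        raise ValueError("control mean must be positive")
    return PercentIncrease(percent=100.0 * (mean_treat - mean_con) / mean_con,
                           fold=mean_treat / mean_con)


def root_shoot_ratio(mean_rdm: float, mean_sdm: float) -> float:
    """Ratio of group-mean root dry mass to group-mean shoot dry mass."""
    if mean_sdm <= 0:
        raise ValueError("shoot dry mass mean must be positive")
    return mean_rdm / mean_sdm


def check_variance_homogeneity(growth: pd.DataFrame, trait: str,
                               alpha: float = 0.05) -> float:
    """Levene's test across soil x treatment groups; logs a warning on
    heterogeneity but does not gate any analysis."""
    groups = [g[trait].astype(float).values
              for _, g in growth.groupby(["soil", "treatment"])]
    _, p = stats.levene(*groups)
    if p < alpha:
        logger.warning("Levene's test: heterogeneous variances for %s (p=%.3g)",
                       trait, p)
    return float(p)


def table1_report(growth: pd.DataFrame, control: str = "Con",
                  alpha: float = 0.05) -> pd.DataFrame:
    """End-point biomass report: per-group mean +/- SD with Tukey letters
    for each trait, percent/fold increase of SDM versus the control, and
    the RDM/SDM ratio."""
    summary = summarize_groups(growth)
    traits = [t for t in TRAITS if f"{t}_mean" in summary.columns]
    rows = []
    for soil in summary.index.get_level_values("soil").unique():
        sub = growth[growth["soil"] == soil]
        letters = {}
        for t in traits:
            groups = {tr: g[t].astype(float).values
                      for tr, g in sub.groupby("treatment")}
            letters[t], _ = screen.tukey_letters(groups, alpha=alpha)
        con_sdm = summary.loc[(soil, control), "SDM_mean"] if "SDM_mean" in summary else None
        for treatment in sub["treatment"].unique():
            s = summary.loc[(soil, treatment)]
            row = {"soil": soil, "treatment": treatment, "n": int(s["n"])}
            for t in traits:
                row[f"{t}_mean"] = s[f"{t}_mean"]
                row[f"{t}_sd"] = s[f"{t}_sd"]
                row[f"{t}_letters"] = letters[t][treatment]
            if con_sdm is not None and treatment != control:
                pi = percent_increase(s["SDM_mean"], con_sdm)
                row["SDM_increase_pct"] = pi.percent_rounded
                row["SDM_increase_fold"] = pi.fold_rounded
            if "RDM_mean" in s and "SDM_mean" in s:
                row["RDM_SDM_ratio"] = round(root_shoot_ratio(s["RDM_mean"],
                                                              s["SDM_mean"]), 1)
            rows.append(row)
    return pd.DataFrame(rows)


def timecourse_flags(weekly: pd.DataFrame, control: str = "Con",
                     alpha: float = 0.05, trait: str = "SL") -> pd.DataFrame:
    """Per-week Dunnett comparisons of a weekly trait against the control.

    ``weekly`` needs columns soil, treatment, week and the trait.  Returns a
    tidy frame (soil, week, treatment, p, significant); use
    :func:`first_flagged_week` for detection latency.
    """
    if "week" not in weekly.columns:
        raise ValueError("weekly data requires a 'week' column")
    weeks = sorted(weekly["week"].unique())
    if len(weeks) < 2:
        raise ValueError("need at least 2 weeks")
    rows = []
    for soil, soil_df in weekly.groupby("soil"):
        for week in weeks:
            sub = soil_df[soil_df["week"] == week]
            groups = {t: g[trait].astype(float).values
                      for t, g in sub.groupby("treatment")}
            pvals = screen.dunnett_vs_control(groups, control=control)
            for treatment, p in pvals.items():
                rows.append({"soil": soil, "week": week, "treatment": treatment,
                             "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)


def first_flagged_week(flags: pd.DataFrame) -> dict:
    """Earliest significant week per (soil, treatment); None when never."""
    out = {}
    for (soil, treatment), g in flags.groupby(["soil", "treatment"]):
        sig = g.loc[g["significant"], "week"]
        out[(soil, treatment)] = int(sig.min()) if len(sig) else None
    return out
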