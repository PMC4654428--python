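"""Per-taxon treatment-responder screening.

For each soil and taxon: log-transform relative abundance, one-way ANOVA
across treatments, Tukey HSD pairwise comparisons summarized as a compact
letter display, and classification of each treatment as an increased /
decreased / non-responder relative to the control group.  The same
building blocks serve the diversity-index and qPCR group comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import community

logger = logging.getLogger(__name__)


@dataclass
class ResponderRecord:
    taxon: str
    level: str
    soil: str
    phylum: str
    treatments: list
    means: dict            # treatment -> mean transformed abundance
    sds: dict              # treatment -> SD of transformed abundance
    rel_means: dict        # treatment -> mean relative abundance, percent
    rel_sds: dict
    letters: dict          # treatment -> compact letters
    direction: dict        # treatment -> "increased" | "decreased" | "none"
    p_adjusted: pd.DataFrame = field(repr=False)  # Tukey pairwise p


def anova_oneway(groups: Mapping[str, Sequence]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    Degenerate case: if every observation is identical across all groups,
    F = 0 and p = 1 by convention (flagged via log).
    """
    arrays = _validated(groups)
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0.0:
        logger.debug("anova_oneway: all observations equal; F=0, p=1 convention")
        return 0.0, 1.0
    F, p = stats.f_oneway(*arrays)
    return float(F), float(p)


def _validated(groups: Mapping[str, Sequence]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for name, vals in groups.items():
        a = np.asarray(vals, dtype=float)
        if a.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {name!r} contains non-finite values")
        arrays.append(a)
    return arrays


def tukey_pairwise(groups: Mapping[str, Sequence]) -> pd.DataFrame:
    """Tukey HSD adjusted p-values for all group pairs (studentized range
    with pooled within-group variance)."""
    names = list(groups)
    arrays = _validated(groups)
    pooled_var = np.concatenate([a - a.mean() for a in arrays]).var(ddof=len(arrays))
    n = len(names)
    P = np.ones((n, n))
    if pooled_var == 0.0:
        # zero within-group variance: unequal means differ with certainty
        for i in range(n):
            for j in range(i + 1, n):
                P[i, j] = P[j, i] = 1.0 if arrays[i].mean() == arrays[j].mean() else 0.0
    else:
        res = stats.tukey_hsd(*arrays)
        P = np.asarray(res.pvalue, dtype=float)
    return pd.DataFrame(P, index=names, columns=names)


def compact_letters(names: Sequence[str], significant_pairs) -> dict:
    """Compact letter display via insert-and-absorb.

    Groups sharing a letter are not significantly different.  Letters are
    assigned alphabetically following the order of ``names``.
    """
    names = list(names)
    columns: list[set] = [set(names)]
    for a, b in significant_pairs:
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for new in (col - {a}, col - {b}):
                if not any(new <= other for other in columns):
                    columns.append(new)
        columns = [c for c in columns
                   if not any(c < other for other in columns)]
    # letter order: by earliest member in input order
    columns.sort(key=lambda c: min(names.index(m) for m in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {n: "" for n in names}
    for k, col in enumerate(columns):
        for n in names:
            if n in col:
                letters[n] += alphabet[k]
    return letters


def tukey_letters(groups: Mapping[str, Sequence], alpha: float = 0.05
                  ) -> tuple[dict, pd.DataFrame]:
    """Tukey HSD pairwise p-values plus their compact letter display."""
    P = tukey_pairwise(groups)
    names = list(groups)
    sig = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]
           if P.loc[a, b] < alpha]
    return compact_letters(names, sig), P


def dunnett_vs_control(groups: Mapping[str, Sequence], control: str) -> dict:
    """Two-sided Dunnett many-to-one comparisons against ``control``.

    With a single treatment the procedure reduces exactly to the pooled
    two-sided t-test, which is used directly in that case.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    _validated(groups)
    ctrl = np.asarray(groups[control], dtype=float)
    treatments = [k for k in groups if k != control]
    if not treatments:
        raise ValueError("need at least one non-control group")
    if len(treatments) == 1:
        t = treatments[0]
        _, p = stats.ttest_ind(np.asarray(groups[t], float), ctrl, equal_var=True)
        return {t: float(p)}
    res = stats.dunnett(*[np.asarray(groups[t], float) for t in treatments],
                        control=ctrl, alternative="two-sided")
    return {t: float(p) for t, p in zip(treatments, res.pvalue)}


def _direction(letters: dict, means: dict, control: str) -> dict:
    out = {}
    for t in letters:
        if t == control:
            continue
        shared = set(letters[t]) & set(letters[control])
        if shared:
            out[t] = "none"
        else:
            out[t] = "increased" if means[t] > means[control] else "decreased"
    return out


def screen_responders(
    table: community.OtuTable,
    level: str = "genus",
    alpha: float = 0.05,
    control: str = "Con",
) -> list[ResponderRecord]:
    """Per-soil, per-taxon treatment screen on transformed abundances.

    For each soil: aggregate to ``level``, drop taxa with all-zero counts in
    that soil (logged), transform, Tukey-test across treatments, and classify
    each treatment's direction versus the control.  Output is sorted by soil,
    phylum, then taxon name.
    """
    records: list[ResponderRecord] = []
    meta = table.metadata.loc[table.counts.index]
    for soil in sorted(meta["soil"].unique()):
        sub = table.subset_samples(meta.index[meta["soil"] == soil])
        agg = community.aggregate(sub, level)
        trans = community.transform(agg, level=level).values
        rel = community.relative_abundance(agg, level=level).values * 100.0
        sub_meta = agg.metadata.loc[agg.counts.index]
        treatments = list(dict.fromkeys(sub_meta["treatment"]))
        if control not in treatments:
            raise ValueError(f"control {control!r} absent in soil {soil!r}")
        for taxon in agg.counts.columns:
            if agg.counts[taxon].sum() == 0:
                logger.info("soil %s: taxon %s absent everywhere; skipped", soil, taxon)
                continue
            groups = {t: trans.loc[sub_meta["treatment"] == t, taxon].values
                      for t in treatments}
            letters, P = tukey_letters(groups, alpha=alpha)
            means = {t: float(np.mean(v)) for t, v in groups.items()}
            sds = {t: float(np.std(v, ddof=1)) for t, v in groups.items()}
            rel_groups = {t: rel.loc[sub_meta["treatment"] == t, taxon].values
                          for t in treatments}
            records.append(ResponderRecord(
                taxon=taxon,
                level=level,
                soil=soil,
                phylum=str(agg.taxonomy.loc[taxon, "phylum"]),
                treatments=treatments,
                means=means,
                sds=sds,
                rel_means={t: float(np.mean(v)) for t, v in rel_groups.items()},
                rel_sds={t: float(np.std(v, ddof=1)) for t, v in rel_groups.items()},
                letters=letters,
                direction=_direction(letters, means, control),
                p_adjusted=P,
            ))
    records.sort(key=lambda r: (r.soil, r.phylum, r.taxon))
    return records


def responders_frame(records: Sequence[ResponderRecord], ndigits: int = 1
                     ) -> pd.DataFrame:
    """Flatten responder records into a report table (one row per soil x
    taxon; per-treatment mean, SD, letters, direction as columns)."""
    rows = []
    for r in records:
        row = {"soil": r.soil, "phylum": r.phylum, "taxon": r.taxon, "level": r.level}
        for t in r.treatments:
            row[f"{t}_mean_pct"] = round(r.rel_means[t], ndigits)
            row[f"{t}_sd_pct"] = round(r.rel_sds[t], ndigits)
            row[f"{t}_letters"] = r.letters[t]
            if t in r.direction:
                row[f"{t}_direction"] = r.direction[t]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class DiversityComparison:
    within_soil_letters: dict   # soil -> {treatment: letters}
    within_soil_p: dict         # soil -> Tukey pairwise p DataFrame
    soil_means: dict
    cross_soil_p: float | None  # two-sample t-test between the two soils


def diversity_compare(diversity: pd.DataFrame, alpha: float = 0.05
                      ) -> DiversityComparison:
    """Compare per-sample diversity indices across treatments within each
    soil (Tukey letters) and between soils (two-sample t-test on all
    replicates; only computed for exactly two soils)."""
    letters, pmats, soil_means = {}, {}, {}
    for soil, sub in diversity.groupby("soil"):
        groups = {t: g["invsimpson"].values for t, g in sub.groupby("treatment")}
        letters[soil], pmats[soil] = tukey_letters(groups, alpha=alpha)
        soil_means[soil] = float(sub["invsimpson"].mean())
    soils = sorted(soil_means)
    cross_p = None
    if len(soils) == 2:
        a = diversity.loc[diversity["soil"] == soils[0], "invsimpson"].values
        b = diversity.loc[diversity["soil"] == soils[1], "invsimpson"].values
        cross_p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return DiversityComparison(within_soil_letters=letters, within_soil_p=pmats,
                               soil_means=soil_means, cross_soil_p=cross_p)


def qpcr_compare(qpcr: pd.DataFrame, alpha: float = 0.05,
                 value_col: str = "copies") -> dict:
    """ANOVA + Tukey letters of log10 gene copy numbers across treatments
    within each soil (copy numbers span orders of magnitude)."""
    out = {}
    for soil, sub in qpcr.groupby("soil"):
        groups = {t: np.log10(g[value_col].values) for t, g in sub.groupby("treatment")}
        F, p = anova_oneway(groups)
        lett, P = tukey_letters(groups, alpha=alpha)
        out[soil] = {"F": F, "p": p, "letters": lett, "pairwise_p": P}
    return out
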