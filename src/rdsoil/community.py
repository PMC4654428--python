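"""OTU-table handling: taxonomic aggregation, relative abundance, the
log10(percent + 1) transformation, dominance filtering, analytic
rarefaction, and the unbiased inverse-Simpson diversity index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

LEVELS = ("domain", "phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"


@dataclass
class OtuTable:
    """Sample x OTU count table with taxonomy and sample metadata.

    counts
        DataFrame, rows = samples, columns = OTU ids, nonnegative integers;
        every sample total must be positive.
    taxonomy
        DataFrame indexed by OTU id with the six columns of ``LEVELS``;
        ``"unclassified"`` is allowed at any level.
    metadata
        DataFrame indexed by sample id with columns soil, treatment,
        replicate.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        totals = counts.sum(axis=1)
        empty = totals[totals <= 0]
        if len(empty):
            raise ValueError(f"samples with zero total counts: {list(empty.index)}")
        missing_tax = set(counts.columns) - set(self.taxonomy.index)
        if missing_tax:
            raise ValueError(f"taxonomy missing for OTUs: {sorted(missing_tax)[:5]}")
        if list(self.taxonomy.columns) != list(LEVELS):
            raise ValueError(f"taxonomy columns must be {LEVELS}")
        missing_meta = set(counts.index) - set(self.metadata.index)
        if missing_meta:
            raise ValueError(f"metadata missing for samples: {sorted(missing_meta)[:5]}")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids: Iterable) -> "OtuTable":
        ids = list(sample_ids)
        return OtuTable(self.counts.loc[ids], self.taxonomy, self.metadata.loc[ids])


@dataclass
class AbundanceMatrix:
    """Samples x taxa real matrix, either relative or transformed."""

    values: pd.DataFrame
    kind: str  # "relative" | "transformed"
    level: str = "otu"

    def __post_init__(self):
        if self.kind not in ("relative", "transformed"):
            raise ValueError("kind must be 'relative' or 'transformed'")
        if self.kind == "relative":
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative rows must sum to 1")
        elif (self.values.values < 0).any():
            raise ValueError("transformed values must be nonnegative")


def _lineage_prefix(taxonomy: pd.DataFrame, level: str) -> pd.Series:
    idx = LEVELS.index(level)
    return taxonomy[list(LEVELS[: idx + 1])].agg(";".join, axis=1)


def aggregate(table: OtuTable, level: str) -> OtuTable:
    """Sum counts over OTUs sharing the lineage prefix down to ``level``.

    OTUs unclassified at ``level`` are pooled per parent lineage (the
    prefix string keeps them distinct between parents).  Column sums are
    conserved for every sample.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    idx = LEVELS.index(level)
    prefix = _lineage_prefix(table.taxonomy.loc[table.counts.columns], level)
    agg_counts = table.counts.T.groupby(prefix.values, sort=True).sum().T
    rows = []
    for taxon in agg_counts.columns:
        parts = taxon.split(";")
        rows.append(parts + [UNCLASSIFIED] * (len(LEVELS) - len(parts)))
    taxonomy = pd.DataFrame(rows, index=agg_counts.columns, columns=list(LEVELS))
    return OtuTable(agg_counts, taxonomy, table.metadata)


def relative_abundance(table: OtuTable, level: str = "otu") -> AbundanceMatrix:
    """Per-sample n/N proportions."""
    values = table.counts.div(table.totals, axis=0)
    return AbundanceMatrix(values, kind="relative", level=level)


def transform(table: OtuTable, level: str = "otu") -> AbundanceMatrix:
    """Variance-stabilizing log10(n/N * 100 + 1) of percent relative abundance.

    Zero counts map to exactly 0; a taxon at 100% maps to log10(101).
    """
    rel = table.counts.div(table.totals, axis=0)
    values = np.log10(rel * 100.0 + 1.0)
    return AbundanceMatrix(values, kind="transformed", level=level)


def dominant_taxa(rel: AbundanceMatrix, threshold_pct: float = 1.0) -> list:
    """Taxa whose mean relative abundance (percent) over all samples is
    >= ``threshold_pct``.  The boundary is inclusive."""
    if rel.kind != "relative":
        raise ValueError("dominance filter expects a relative AbundanceMatrix")
    mean_pct = rel.values.mean(axis=0) * 100.0
    if threshold_pct == 0:
        return list(mean_pct.index[mean_pct > 0])
    return list(mean_pct.index[mean_pct >= threshold_pct])


def _log_choose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def rarefaction_curve(counts: Sequence, depths: Sequence) -> np.ndarray:
    """Analytic expected richness E[S_d] at each subsampling depth.

    Hypergeometric expectation E[S_d] = S_obs - sum_i C(N - n_i, d) / C(N, d),
    evaluated with log-gamma for stability.  No resampling.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("sample has no positive counts")
    N = counts.sum()
    depths = np.asarray(depths, dtype=float)
    if np.any(depths > N):
        raise ValueError("depth exceeds sample total")
    if np.any(depths < 0):
        raise ValueError("depths must be nonnegative")
    S_obs = counts.size
    out = np.empty(depths.shape, dtype=float)
    rem = N - counts
    for k, d in enumerate(depths):
        ok = rem >= d  # taxa that can be entirely missed at depth d
        miss = np.zeros_like(counts)
        if ok.any():
            miss[ok] = np.exp(_log_choose(rem[ok], d) - _log_choose(np.array(N), d))
        out[k] = S_obs - miss.sum()
    return out


def invsimpson(counts: Sequence) -> float:
    """Unbiased inverse Simpson index 1/D, D = sum n_i(n_i-1) / (N(N-1)).

    Returns ``math.inf`` when every taxon is a singleton (D = 0).
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    N = counts.sum()
    if N < 2:
        raise ValueError("inverse Simpson needs a sample total of at least 2")
    D = (counts * (counts - 1.0)).sum() / (N * (N - 1.0))
    if D == 0.0:
        return math.inf
    return 1.0 / D


def diversity_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample inverse Simpson with metadata columns attached."""
    idx = table.counts.index
    vals = [invsimpson(table.counts.loc[s].values) for s in idx]
    out = table.metadata.loc[idx, ["soil", "treatment", "replicate"]].copy()
    out["invsimpson"] = vals
    return out
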