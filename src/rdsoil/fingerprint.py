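"""Fingerprint lane analysis: Pearson similarity, UPGMA, and the
within-vs-between-group permutation d-test.

A fingerprint set is an ordered collection of densitometric lane profiles
(one intensity vector per sample).  Similarity between two lanes is the
Pearson correlation of the raw profiles; group structure is quantified by
the d statistic — 100 times the difference between the mean within-group
and mean between-group pairwise similarity — and tested by permuting group
labels over lanes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from ._perm import (
    DEFAULT_EXHAUSTIVE_CAP,
    iter_distinct_arrangements,
    n_distinct_arrangements,
)

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class FingerprintSet:
    """Labelled lane intensity profiles of common length."""

    lane_ids: tuple
    groups: tuple
    profiles: np.ndarray  # (n_lanes, n_bins)

    def __post_init__(self):
        profiles = np.asarray(self.profiles, dtype=float)
        object.__setattr__(self, "profiles", profiles)
        object.__setattr__(self, "lane_ids", tuple(self.lane_ids))
        object.__setattr__(self, "groups", tuple(self.groups))
        if profiles.ndim != 2 or profiles.shape[0] < 2 or profiles.shape[1] < 2:
            raise ValueError("need >=2 lanes of common length >=2")
        if len(self.lane_ids) != profiles.shape[0] or len(self.groups) != profiles.shape[0]:
            raise ValueError("lane_ids/groups length must match number of lanes")
        if not np.all(np.isfinite(profiles)):
            raise ValueError("lane intensities must be finite")

    @property
    def n_lanes(self) -> int:
        return self.profiles.shape[0]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric Pearson-correlation matrix keyed by sample id."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(self.ids))
        n = len(self.ids)
        if values.shape != (n, n):
            raise ValueError("matrix shape must match ids")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(values < -1 - 1e-9) or np.any(values > 1 + 1e-9):
            raise ValueError("Pearson similarities must lie in [-1, 1]")

    def pair(self, a, b) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass(frozen=True)
class PermutationResult:
    d_observed: float  # percentage points
    p_value: float
    n_permutations: int
    scheme: str  # "exhaustive" | "monte_carlo"
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")
        if self.p_value < 1.0 / self.n_permutations - 1e-12:
            raise ValueError("p-value below 1/n_permutations")


@dataclass(frozen=True)
class UpgmaTree:
    newick: str
    merges: np.ndarray = field(repr=False)  # scipy linkage matrix
    ids: tuple = ()

    def cophenetic(self) -> np.ndarray:
        """Square matrix of cophenetic distances between leaves."""
        return squareform(cophenet(self.merges))


def pearson_similarity(fp: FingerprintSet) -> SimilarityMatrix:
    """Pairwise Pearson correlation of raw lane profiles.

    No background subtraction or binning is applied; any preprocessing is
    the caller's responsibility.  A constant lane has undefined correlation
    and raises ``ValueError`` naming the lane.
    """
    variances = fp.profiles.var(axis=1)
    for lane_id, v in zip(fp.lane_ids, variances):
        if v == 0.0:
            raise ValueError(f"lane {lane_id!r} has zero intensity variance; "
                             "Pearson correlation is undefined")
    S = np.corrcoef(fp.profiles)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids=fp.lane_ids, values=np.clip(S, -1.0, 1.0))


def upgma(S: SimilarityMatrix) -> UpgmaTree:
    """Average-linkage agglomeration on the dissimilarity 1 - S.

    Merge heights are the UPGMA cophenetic distances (nondecreasing); the
    Newick branch lengths place each leaf at half the root height, giving an
    ultrametric tree.
    """
    n = len(S.ids)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    D = 1.0 - S.values
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    return UpgmaTree(newick=_to_newick(Z, S.ids), merges=Z, ids=S.ids)


def _to_newick(Z: np.ndarray, ids: Sequence) -> str:
    n = len(ids)
    heights = {i: 0.0 for i in range(n)}
    subtrees = {i: str(ids[i]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + k
        heights[node] = h / 2.0  # leaf-to-node along the ultrametric scale
        left = f"{subtrees[a]}:{heights[node] - heights[a]:.10g}"
        right = f"{subtrees[b]}:{heights[node] - heights[b]:.10g}"
        subtrees[node] = f"({left},{right})"
    return subtrees[n + len(Z) - 1] + ";"


def _group_codes(S: SimilarityMatrix, labels: Sequence) -> np.ndarray:
    labels = list(labels)
    if len(labels) != len(S.ids):
        raise ValueError("one label per sample required")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    for g in uniq:
        if labels.count(g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members (no within pair)")
    code = {g: i for i, g in enumerate(uniq)}
    return np.array([code[g] for g in labels], dtype=np.intp)


def _d_value(S_pairs: np.ndarray, ii: np.ndarray, jj: np.ndarray,
             codes: np.ndarray) -> float:
    same = codes[ii] == codes[jj]
    return 100.0 * (S_pairs[same].mean() - S_pairs[~same].mean())


def d_statistic(S: SimilarityMatrix, labels: Sequence) -> float:
    """d = 100 * (mean within-group similarity - mean between-group similarity).

    Means are taken over unordered off-diagonal pairs; reported in
    percentage points.
    """
    codes = _group_codes(S, labels)
    n = len(S.ids)
    ii, jj = np.triu_indices(n, k=1)
    return _d_value(S.values[ii, jj], ii, jj, codes)


def permutation_test(
    S: SimilarityMatrix,
    labels: Sequence,
    n_mc: int = 9_999,
    seed: int | None = None,
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
) -> PermutationResult:
    """One-sided permutation test of the d statistic.

    Labels are permuted over samples with group sizes fixed.  When the
    number of distinct label arrangements is at most ``exhaustive_cap`` the
    null is enumerated exactly; the p-value counts arrangements whose d is
    >= the observed (the identity arrangement is one of them, so p > 0).
    Otherwise ``n_mc`` Monte-Carlo draws are used with the identity added to
    numerator and denominator.
    """
    codes = _group_codes(S, labels)
    n = len(S.ids)
    ii, jj = np.triu_indices(n, k=1)
    S_pairs = S.values[ii, jj]
    d_obs = _d_value(S_pairs, ii, jj, codes)

    total = n_distinct_arrangements(list(codes))
    if total <= exhaustive_cap:
        hits = 0
        for arrangement in iter_distinct_arrangements(list(codes)):
            if _d_value(S_pairs, ii, jj, np.asarray(arrangement)) >= d_obs - _TIE_EPS:
                hits += 1
        return PermutationResult(d_observed=d_obs, p_value=hits / total,
                                 n_permutations=total, scheme="exhaustive", seed=seed)

    if n_mc < 100:
        raise ValueError("n_mc must be >= 100 in Monte-Carlo mode")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(codes)
        if _d_value(S_pairs, ii, jj, perm) >= d_obs - _TIE_EPS:
            hits += 1
    return PermutationResult(d_observed=d_obs, p_value=(hits + 1) / (n_mc + 1),
                             n_permutations=n_mc + 1, scheme="monte_carlo", seed=seed)
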