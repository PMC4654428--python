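"""Bray-Curtis distances, principal coordinate analysis, and rank-based
ANOSIM permutation tests (one-way, and two-way crossed with within-block
permutation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from ._perm import (
    DEFAULT_EXHAUSTIVE_CAP,
    iter_distinct_arrangements,
    n_distinct_arrangements,
)

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class DistanceMatrix:
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
            raise ValueError("distance matrix must be symmetric")
        if np.any(values < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("diagonal must be zero")


@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray    # all eigenvalues, descending
    explained: np.ndarray      # fraction of positive inertia per retained axis


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    design: str  # "one_way" | "two_way"
    scheme: str  # "exhaustive" | "monte_carlo"
    block_factor: str | None = None

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.R <= 1.0 + 1e-9:
            raise ValueError("ANOSIM R must lie in [-1, 1]")
        if self.p_value < 1.0 / self.n_permutations - 1e-12:
            raise ValueError("p-value below 1/n_permutations")


def genus_ordination_input(table, threshold_pct: float = 1.0):
    """Genus-level transformed abundance matrix for ordination.

    Restricted to genera from dominant phyla (mean relative abundance >=
    ``threshold_pct`` percent over all samples) that are classified at genus
    level; unclassified-at-genus rows are dropped for this analysis only.
    """
    from . import community

    phylum_rel = community.relative_abundance(community.aggregate(table, "phylum"),
                                              level="phylum")
    dominant = set(community.dominant_taxa(phylum_rel, threshold_pct))
    genus = community.aggregate(table, "genus")
    tax = genus.taxonomy.loc[genus.counts.columns]
    dom_prefix = tax["domain"] + ";" + tax["phylum"]
    keep = dom_prefix.isin(dominant) & (tax["genus"] != community.UNCLASSIFIED)
    kept = list(genus.counts.columns[keep])
    if not kept:
        raise ValueError("no classified genera left after the dominance filter")
    trans = community.transform(genus, level="genus")
    return trans.values[kept]


def bray_curtis(values, ids: Sequence | None = None) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample rows.

    D[i][j] = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk); rows must be
    nonnegative with positive sums.
    """
    if isinstance(values, pd.DataFrame):
        ids = tuple(values.index) if ids is None else tuple(ids)
        X = values.values.astype(float)
    else:
        X = np.asarray(values, dtype=float)
        ids = tuple(range(X.shape[0])) if ids is None else tuple(ids)
    if np.any(X < 0):
        raise ValueError("abundances must be nonnegative")
    sums = X.sum(axis=1)
    if np.any(sums <= 0):
        bad = [ids[i] for i in np.flatnonzero(sums <= 0)]
        raise ValueError(f"all-zero samples have undefined Bray-Curtis distance: {bad}")
    D = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(ids=ids, values=D)


def pcoa(D: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    Gower double-centering of -D^2/2, symmetric eigendecomposition,
    coordinates = eigenvectors scaled by sqrt of the positive eigenvalues.
    Negative eigenvalues are reported but their axes are dropped; explained
    fractions are relative to the positive inertia.
    """
    A = -0.5 * D.values ** 2
    n = A.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    B = H @ A @ H
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(np.abs(eigvals).max(), 1.0) * 1e-12
    positive = eigvals > tol
    n_pos = int(positive.sum())
    keep = n_pos if n_axes is None else n_axes
    if keep > n_pos:
        warnings.warn(f"requested {keep} axes but only {n_pos} positive "
                      f"eigenvalues; truncating", stacklevel=2)
        keep = n_pos
    coords = eigvecs[:, :keep] * np.sqrt(np.maximum(eigvals[:keep], 0.0))
    pos_sum = eigvals[positive].sum() if n_pos else 1.0
    explained = np.maximum(eigvals[:keep], 0.0) / pos_sum
    frame = pd.DataFrame(coords, index=list(D.ids),
                         columns=[f"axis{i + 1}" for i in range(keep)])
    return PcoaResult(coordinates=frame, eigenvalues=eigvals, explained=explained)


def _anosim_r(rank_matrix: np.ndarray, codes: np.ndarray) -> float:
    """Clarke's R from a square matrix of off-diagonal distance ranks."""
    n = len(codes)
    ii, jj = np.triu_indices(n, k=1)
    same = codes[ii] == codes[jj]
    r = rank_matrix[ii, jj]
    r_within = r[same].mean()
    r_between = r[~same].mean()
    return (r_between - r_within) / (n * (n - 1) / 4.0)


def _rank_matrix(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    ranks = rankdata(D[ii, jj])  # midranks on ties
    M = np.zeros_like(D)
    M[ii, jj] = ranks
    M[jj, ii] = ranks
    return M


def _codes(labels: Sequence) -> np.ndarray:
    labels = list(labels)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    for g in uniq:
        if labels.count(g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    code = {g: i for i, g in enumerate(uniq)}
    return np.array([code[g] for g in labels], dtype=np.intp)


def anosim(
    D: DistanceMatrix,
    labels: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
    design: str = "one_way",
    blocks: Sequence | None = None,
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
) -> AnosimResult:
    """Rank-based analysis of similarities, one-sided for large R.

    One-way: R = (mean between-group rank - mean within-group rank) divided
    by n(n-1)/4, with labels permuted over all samples.  Two-way crossed:
    R is the average of the one-way R computed within each block (ranks
    re-assigned within block), and labels are permuted independently within
    blocks only.
    """
    codes = _codes(labels)
    if design == "one_way":
        return _anosim_one_way(D, codes, n_perm, seed, exhaustive_cap)
    if design == "two_way":
        if blocks is None:
            raise ValueError("two_way design requires a block factor")
        return _anosim_two_way(D, codes, list(blocks), n_perm, seed)
    raise ValueError(f"unknown design {design!r}")


def _anosim_one_way(D, codes, n_perm, seed, exhaustive_cap) -> AnosimResult:
    rank_m = _rank_matrix(D.values)
    r_obs = _anosim_r(rank_m, codes)
    total = n_distinct_arrangements(list(codes))
    if total <= exhaustive_cap:
        hits = sum(
            1
            for arrangement in iter_distinct_arrangements(list(codes))
            if _anosim_r(rank_m, np.asarray(arrangement)) >= r_obs - _TIE_EPS
        )
        return AnosimResult(R=r_obs, p_value=hits / total, n_permutations=total,
                            design="one_way", scheme="exhaustive")
    rng = np.random.default_rng(seed)
    hits = sum(
        1
        for _ in range(n_perm)
        if _anosim_r(rank_m, rng.permutation(codes)) >= r_obs - _TIE_EPS
    )
    return AnosimResult(R=r_obs, p_value=(hits + 1) / (n_perm + 1),
                        n_permutations=n_perm + 1, design="one_way",
                        scheme="monte_carlo")


def _anosim_two_way(D, codes, blocks, n_perm, seed) -> AnosimResult:
    if len(blocks) != len(codes):
        raise ValueError("one block label per sample required")
    block_ids = sorted(set(blocks))
    blocks = np.asarray(blocks, dtype=object)
    members = {b: np.flatnonzero(blocks == b) for b in block_ids}
    rank_ms = {}
    for b, idx in members.items():
        sub_codes = codes[idx]
        sizes = np.bincount(sub_codes)
        sizes = sizes[sizes > 0]
        if len(sizes) < 2 or sizes.min() < 2:
            raise ValueError(f"block {b!r} needs >=2 groups of >=2 samples")
        rank_ms[b] = _rank_matrix(D.values[np.ix_(idx, idx)])

    def avg_r(all_codes: np.ndarray) -> float:
        return float(np.mean([
            _anosim_r(rank_ms[b], all_codes[idx]) for b, idx in members.items()
        ]))

    r_obs = avg_r(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = codes.copy()
        for idx in members.values():
            perm[idx] = rng.permutation(perm[idx])
        if avg_r(perm) >= r_obs - _TIE_EPS:
            hits += 1
    return AnosimResult(R=r_obs, p_value=(hits + 1) / (n_perm + 1),
                        n_permutations=n_perm + 1, design="two_way",
                        scheme="monte_carlo", block_factor="block")
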