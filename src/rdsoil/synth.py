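"""Synthetic data generators.

Stand-ins for the wet-lab inputs of the pipeline: gel-style lane intensity
profiles with tunable within-/between-group structure, Dirichlet-multinomial
OTU count tables with planted per-taxon treatment effects, plant-growth
tables, and qPCR copy-number tables.

All generators are pure functions of (params, seed).  Randomness is drawn
from per-entity counter-based streams (see :mod:`rdsoil._rng`), so adding a
group or replicate never shifts the draws of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .community import LEVELS, OtuTable
from .fingerprint import FingerprintSet

DEFAULT_DEPTH_RANGE = (4_228, 10_005)  # observed per-sample classified-read range


# ---------------------------------------------------------------- fingerprints

@dataclass(frozen=True)
class FingerprintSimParams:
    n_groups: int = 2
    reps_per_group: int = 4
    profile_length: int = 200
    n_bands: int = 12
    band_width: float = 2.0
    within_group_noise_sd: float = 0.05
    between_group_band_shift: float = 0.3
    seed: int = 0
    group_labels: tuple | None = None

    def __post_init__(self):
        if self.n_groups < 1 or self.reps_per_group < 2 or self.n_bands < 1:
            raise ValueError("need n_groups >= 1, reps_per_group >= 2, n_bands >= 1")
        if self.profile_length < 10 * self.n_bands:
            raise ValueError("profile_length must be >= 10 * n_bands")
        if self.band_width <= 0:
            raise ValueError("band_width must be positive")
        if self.within_group_noise_sd < 0 or self.between_group_band_shift < 0:
            raise ValueError("noise and shift parameters must be >= 0")
        if self.group_labels is not None:
            if len(self.group_labels) != self.n_groups:
                raise ValueError("group_labels length must equal n_groups")
            object.__setattr__(self, "group_labels", tuple(self.group_labels))

    def labels(self) -> tuple:
        if self.group_labels is not None:
            return self.group_labels
        return tuple(f"G{i + 1}" for i in range(self.n_groups))


def _render_lanes(positions, amps, width, grid):
    profile = np.zeros_like(grid, dtype=float)
    for p, a in zip(positions, amps):
        profile += a * np.exp(-0.5 * ((grid - p) / width) ** 2)
    return profile


def simulate_fingerprints(params: FingerprintSimParams) -> FingerprintSet:
    """Gaussian-bump band model on a flat baseline.

    A shared band template (positions + amplitudes) is drawn once; each
    group then deletes, jitters, or gains bands at a rate set by
    ``between_group_band_shift``; each replicate lane perturbs band
    amplitudes/positions and adds pixel noise at ``within_group_noise_sd``.
    With both parameters at 0 every lane is identical.
    """
    L, bw = params.profile_length, params.band_width
    grid = np.arange(L, dtype=float)
    margin = 3.0 * bw
    t_rng = stream(params.seed, "fingerprint", "template")
    base_pos = t_rng.uniform(margin, L - margin, params.n_bands)
    base_amp = t_rng.uniform(0.5, 1.5, params.n_bands)

    lane_ids, groups, profiles = [], [], []
    for g, label in enumerate(params.labels()):
        g_rng = stream(params.seed, "fingerprint", "group", g)
        pos, amp = [], []
        for p, a in zip(base_pos, base_amp):
            if g_rng.random() < params.between_group_band_shift:
                if g_rng.random() < 0.5:
                    continue  # band lost in this group
                p = np.clip(p + g_rng.normal(0.0, 5.0 * bw), margin, L - margin)
            pos.append(p)
            amp.append(a)
        n_gain = g_rng.binomial(params.n_bands, params.between_group_band_shift / 2.0)
        pos.extend(g_rng.uniform(margin, L - margin, n_gain))
        amp.extend(g_rng.uniform(0.5, 1.5, n_gain))
        pos, amp = np.asarray(pos), np.asarray(amp)

        for r in range(params.reps_per_group):
            l_rng = stream(params.seed, "fingerprint", "lane", g, r)
            sd = params.within_group_noise_sd
            lane_amp = amp * np.maximum(0.0, 1.0 + l_rng.normal(0.0, sd, amp.shape))
            lane_pos = pos + l_rng.normal(0.0, sd * bw, pos.shape)
            profile = _render_lanes(lane_pos, lane_amp, bw, grid)
            profile = np.maximum(profile + l_rng.normal(0.0, 0.5 * sd, L), 0.0)
            lane_ids.append(f"{label}_{r + 1}")
            groups.append(label)
            profiles.append(profile)
    return FingerprintSet(lane_ids=tuple(lane_ids), groups=tuple(groups),
                          profiles=np.asarray(profiles))


# ----------------------------------------------------------------- OTU tables

@dataclass(frozen=True)
class OtuSimParams:
    groups: tuple = (("Kle", "Con"), ("Kle", "H50"), ("Kle", "Gamma"),
                     ("Alv", "Con"), ("Alv", "H50"), ("Alv", "Gamma"))
    n_samples_per_group: int = 4
    n_otus: int = 200
    depth_range: tuple = DEFAULT_DEPTH_RANGE
    base_composition: object = "logseries"  # vector, or "logseries"
    responder_spec: tuple = ()  # (otu_index, affected_group, effect) triples
    overdispersion: float = 500.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups",
                           tuple((str(s), str(t)) for s, t in self.groups))
        object.__setattr__(self, "responder_spec", tuple(self.responder_spec))
        if self.n_samples_per_group < 1 or self.n_otus < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("depth_range must satisfy 0 < min <= max")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        for otu_idx, _, effect in self.responder_spec:
            if not 0 <= otu_idx < self.n_otus:
                raise ValueError(f"responder otu_index {otu_idx} out of range")
            if effect <= 0:
                raise ValueError("responder effects must be > 0")

    def base_proportions(self) -> np.ndarray:
        if isinstance(self.base_composition, str):
            if self.base_composition != "logseries":
                raise ValueError(f"unknown generator {self.base_composition!r}")
            i = np.arange(1, self.n_otus + 1, dtype=float)
            p = 0.998 ** i / i
        else:
            p = np.asarray(self.base_composition, dtype=float)
            if p.shape != (self.n_otus,):
                raise ValueError("base composition length must equal n_otus")
            if p.sum() <= 0 or np.any(p < 0):
                raise ValueError("base composition must be nonnegative, positive sum")
        return p / p.sum()


def _group_matches(spec_group, soil: str, treatment: str) -> bool:
    if isinstance(spec_group, (tuple, list)):
        return tuple(spec_group) == (soil, treatment)
    return spec_group in (soil, treatment, f"{soil}{treatment}")


def _default_taxonomy(n_otus: int) -> pd.DataFrame:
    rows = []
    for i in range(n_otus):
        phylum = f"Phylum{i % 6 + 1}"
        rows.append(["Bacteria", phylum, f"Class{i % 6 + 1}", f"Order{i % 12 + 1}",
                     f"Family{i % 24 + 1}", f"Genus{i + 1}"])
    return pd.DataFrame(rows, index=[f"Otu{i + 1:05d}" for i in range(n_otus)],
                        columns=list(LEVELS))


def simulate_otu_table(params: OtuSimParams) -> OtuTable:
    """Dirichlet-multinomial count table with planted responder effects.

    Per group, responder effects multiply the expected relative abundance of
    the targeted OTUs before renormalization; per sample, a composition is
    drawn from Dirichlet(expected * overdispersion) and counts from a
    multinomial at a depth uniform over ``depth_range``.
    """
    base = params.base_proportions()
    taxonomy = _default_taxonomy(params.n_otus)
    otu_ids = list(taxonomy.index)
    lo, hi = params.depth_range

    counts, sample_ids, meta_rows = [], [], []
    for soil, treatment in params.groups:
        expected = base.copy()
        for otu_idx, grp, effect in params.responder_spec:
            if _group_matches(grp, soil, treatment):
                expected[otu_idx] *= effect
        expected /= expected.sum()
        alpha = expected * params.overdispersion
        g_rng = stream(params.seed, "otu", soil, treatment)
        for r in range(params.n_samples_per_group):
            depth = int(g_rng.integers(lo, hi + 1))
            if params.n_otus == 1:
                comp = np.ones(1)
            else:
                comp = g_rng.dirichlet(alpha)
            counts.append(g_rng.multinomial(depth, comp))
            sample_ids.append(f"{soil}{treatment}_{r + 1}")
            meta_rows.append({"soil": soil, "treatment": treatment,
                              "replicate": r + 1})
    counts = pd.DataFrame(np.asarray(counts, dtype=np.int64),
                          index=sample_ids, columns=otu_ids)
    metadata = pd.DataFrame(meta_rows, index=sample_ids)
    return OtuTable(counts=counts, taxonomy=taxonomy, metadata=metadata)


# --------------------------------------------------------------------- growth

@dataclass(frozen=True)
class GrowthSimParams:
    """Normal per-trait draws, truncated at zero.

    ``group_means``/``group_sds`` map (soil, treatment) to a (SL, SFM, SDM,
    RDM) tuple.
    """

    group_means: dict = field(default_factory=dict)
    group_sds: dict = field(default_factory=dict)
    n_plants: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.group_means:
            raise ValueError("group_means must not be empty")
        if set(self.group_means) != set(self.group_sds):
            raise ValueError("group_means and group_sds must share keys")
        if self.n_plants < 2:
            raise ValueError("n_plants must be >= 2")
        for g, means in self.group_means.items():
            if len(means) != 4 or any(m <= 0 for m in means):
                raise ValueError(f"group {g}: need 4 positive trait means")
            if len(self.group_sds[g]) != 4 or any(s < 0 for s in self.group_sds[g]):
                raise ValueError(f"group {g}: need 4 nonnegative trait SDs")


def simulate_growth(params: GrowthSimParams) -> pd.DataFrame:
    """Per-plant growth table with columns soil, treatment, replicate and
    the four traits; draws are normal, truncated at 0."""
    rows = []
    for (soil, treatment), means in params.group_means.items():
        sds = params.group_sds[(soil, treatment)]
        rng = stream(params.seed, "growth", soil, treatment)
        draws = np.maximum(rng.normal(means, sds, size=(params.n_plants, 4)), 0.0)
        for r in range(params.n_plants):
            rows.append({"plant_id": f"{soil}{treatment}_{r + 1}", "soil": soil,
                         "treatment": treatment, "replicate": r + 1,
                         "SL": draws[r, 0], "SFM": draws[r, 1],
                         "SDM": draws[r, 2], "RDM": draws[r, 3]})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------- qPCR

@dataclass(frozen=True)
class QpcrSimParams:
    """Log10 copy-number means/SDs per (soil, treatment)."""

    group_log10_means: dict = field(default_factory=dict)
    group_log10_sds: dict = field(default_factory=dict)
    n_reps: int = 4
    seed: int = 0

    def __post_init__(self):
        if not self.group_log10_means:
            raise ValueError("group_log10_means must not be empty")
        if set(self.group_log10_means) != set(self.group_log10_sds):
            raise ValueError("means and sds must share keys")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")


def simulate_qpcr(params: QpcrSimParams) -> pd.DataFrame:
    """Per-replicate 16S copy-number table (linear scale ``copies``)."""
    rows = []
    for (soil, treatment), mu in params.group_log10_means.items():
        sd = params.group_log10_sds[(soil, treatment)]
        rng = stream(params.seed, "qpcr", soil, treatment)
        log10_copies = rng.normal(mu, sd, params.n_reps)
        for r in range(params.n_reps):
            rows.append({"sample_id": f"{soil}{treatment}_{r + 1}", "soil": soil,
                         "treatment": treatment, "replicate": r + 1,
                         "copies": 10.0 ** log10_copies[r]})
    return pd.DataFrame(rows)
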