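"""End-to-end driver: run the enabled analysis stages from a single config
mapping (usually loaded from YAML) on synthetic or user-supplied data and
write per-stage reports plus a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, biotest, community, io, ordination, screen, synth
from . import fingerprint as fp_mod

logger = logging.getLogger(__name__)

STAGES = ("fingerprint", "diversity", "ordination", "screen", "biotest", "qpcr")


def _parse_group_key(key):
    if isinstance(key, str) and ":" in key:
        soil, treatment = key.split(":", 1)
        return soil, treatment
    if isinstance(key, (tuple, list)) and len(key) == 2:
        return tuple(key)
    raise ValueError(f"group key {key!r} must be 'Soil:Treatment' or a pair")


def _growth_params(block: dict, seed: int) -> synth.GrowthSimParams:
    means = {_parse_group_key(k): tuple(v) for k, v in block["group_means"].items()}
    sds = {_parse_group_key(k): tuple(v) for k, v in block["group_sds"].items()}
    return synth.GrowthSimParams(group_means=means, group_sds=sds,
                                 n_plants=int(block.get("n_plants", 10)),
                                 seed=int(block.get("seed", seed)))


def _load_streams(config: dict, seed: int) -> dict:
    """Resolve each data stream from explicit input paths or synth params."""
    inputs = config.get("inputs", {}) or {}
    synth_cfg = config.get("synth", {}) or {}
    streams: dict = {}

    if "lanes" in inputs and "fingerprints" in synth_cfg:
        raise ValueError("fingerprint stream: give input paths OR synth params, not both")
    if "lanes" in inputs:
        streams["fingerprints"] = io.read_lanes_csv(inputs["lanes"])
    elif "fingerprints" in synth_cfg:
        block = dict(synth_cfg["fingerprints"])
        block.setdefault("seed", seed)
        streams["fingerprints"] = synth.simulate_fingerprints(
            synth.FingerprintSimParams(**block))

    if "otu_counts" in inputs and "otu" in synth_cfg:
        raise ValueError("OTU stream: give input paths OR synth params, not both")
    if "otu_counts" in inputs:
        streams["otu"] = io.read_otu_table(inputs["otu_counts"], inputs["taxonomy"],
                                           inputs["metadata"])
    elif "otu" in synth_cfg:
        block = dict(synth_cfg["otu"])
        block.setdefault("seed", seed)
        if "groups" in block:
            block["groups"] = tuple(_parse_group_key(g) for g in block["groups"])
        if "responder_spec" in block:
            block["responder_spec"] = tuple(
                (int(i), g if isinstance(g, str) else _parse_group_key(g), float(e))
                for i, g, e in block["responder_spec"])
        streams["otu"] = synth.simulate_otu_table(synth.OtuSimParams(**block))

    if "growth" in inputs and "growth" in synth_cfg:
        raise ValueError("growth stream: give input paths OR synth params, not both")
    if "growth" in inputs:
        streams["growth"] = io.read_growth_csv(inputs["growth"])
    elif "growth" in synth_cfg:
        streams["growth"] = synth.simulate_growth(_growth_params(synth_cfg["growth"], seed))

    if "qpcr" in inputs:
        streams["qpcr"] = pd.read_csv(inputs["qpcr"])
    elif "qpcr" in synth_cfg:
        block = dict(synth_cfg["qpcr"])
        block.setdefault("seed", seed)
        means = {_parse_group_key(k): float(v)
                 for k, v in block.pop("group_log10_means").items()}
        sds = {_parse_group_key(k): float(v)
               for k, v in block.pop("group_log10_sds").items()}
        streams["qpcr"] = synth.simulate_qpcr(synth.QpcrSimParams(
            group_log10_means=means, group_log10_sds=sds, **block))
    return streams


def run_pipeline(config: dict, outdir) -> dict:
    """Execute enabled stages in dependency order; returns the manifest.

    Deterministic for a fixed seed: rerunning with the same config yields a
    byte-identical report bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = {s: bool(config.get("stages", {}).get(s, False)) for s in STAGES}
    seed = config.get("seed")
    if seed is None and (any(enabled.values()) or config.get("synth")):
        raise ValueError("a seed is mandatory when any stochastic stage is enabled")
    seed = int(seed) if seed is not None else 0
    alpha = float(config.get("alpha", 0.05))
    n_perm = config.get("permutations", "exhaustive")

    streams = _load_streams(config, seed)
    headline: dict = {}

    if enabled["fingerprint"]:
        if "fingerprints" not in streams:
            raise ValueError("stage 'fingerprint': no lane data configured")
        headline["fingerprint"] = _run_fingerprint(
            streams["fingerprints"], config, outdir, seed, n_perm)

    if enabled["diversity"]:
        if "otu" not in streams:
            raise ValueError("stage 'diversity': no OTU table configured")
        headline["diversity"] = _run_diversity(streams["otu"], outdir, alpha)

    if enabled["ordination"]:
        if "otu" not in streams:
            raise ValueError("stage 'ordination': no OTU table configured")
        headline["ordination"] = _run_ordination(streams["otu"], config, outdir, seed)

    if enabled["screen"]:
        if "otu" not in streams:
            raise ValueError("stage 'screen': no OTU table configured")
        headline["screen"] = _run_screen(streams["otu"], config, outdir, alpha)

    if enabled["biotest"]:
        if "growth" not in streams:
            raise ValueError("stage 'biotest': no growth table configured")
        headline["biotest"] = _run_biotest(streams["growth"], config, outdir, alpha)

    if enabled["qpcr"]:
        if "qpcr" not in streams:
            raise ValueError("stage 'qpcr': no qPCR table configured")
        headline["qpcr"] = _run_qpcr(streams["qpcr"], outdir, alpha)

    manifest = {
        "version": __version__,
        "seed": seed,
        "alpha": alpha,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "stages": {s: enabled[s] for s in STAGES},
        "headline": headline,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _perm_kwargs(n_perm):
    if n_perm == "exhaustive":
        return {}
    return {"n_mc": int(n_perm), "exhaustive_cap": 0}


def _run_fingerprint(fps, config, outdir, seed, n_perm) -> dict:
    S = fp_mod.pearson_similarity(fps)
    io.write_tsv(pd.DataFrame(S.values, index=S.ids, columns=S.ids),
                 outdir / "similarity.tsv", index=True)
    (outdir / "dendrogram.nwk").write_text(fp_mod.upgma(S).newick + "\n")

    pairs = config.get("fingerprint", {}).get("comparisons")
    group_order = list(dict.fromkeys(fps.groups))
    if pairs is None:
        pairs = [[a, b] for i, a in enumerate(group_order) for b in group_order[i + 1:]]
    rows = []
    for a, b in pairs:
        mask = [g in (a, b) for g in fps.groups]
        sub_ids = [i for i, m in zip(S.ids, mask) if m]
        idx = [S.ids.index(i) for i in sub_ids]
        sub = fp_mod.SimilarityMatrix(ids=sub_ids,
                                      values=S.values[np.ix_(idx, idx)])
        labels = [g for g, m in zip(fps.groups, mask) if m]
        res = fp_mod.permutation_test(sub, labels, seed=seed, **_perm_kwargs(n_perm))
        rows.append({"comparison": f"{a} vs. {b}", "d_value": round(res.d_observed, 2),
                     "p_value": res.p_value, "scheme": res.scheme,
                     "n_permutations": res.n_permutations})
    report = pd.DataFrame(rows)
    io.write_tsv(report, outdir / "fingerprint_dtest.tsv")
    return {"comparisons": rows}


def _run_diversity(table, outdir, alpha) -> dict:
    div = community.diversity_table(table)
    io.write_tsv(div.rename_axis("sample_id"), outdir / "diversity.tsv", index=True)
    depths = np.unique(np.linspace(1, int(table.totals.min()), 25).astype(int))
    curves = {"depth": depths}
    for s in table.sample_ids:
        curves[s] = community.rarefaction_curve(table.counts.loc[s].values, depths)
    io.write_tsv(pd.DataFrame(curves), outdir / "rarefaction.tsv")
    comp = screen.diversity_compare(div, alpha=alpha)
    return {"soil_means": comp.soil_means, "cross_soil_p": comp.cross_soil_p,
            "letters": {s: comp.within_soil_letters[s] for s in comp.within_soil_letters}}


def _run_ordination(table, config, outdir, seed) -> dict:
    ord_cfg = config.get("ordination", {}) or {}
    threshold = float(ord_cfg.get("dominant_threshold_pct", 1.0))
    values = ordination.genus_ordination_input(table, threshold)
    D = ordination.bray_curtis(values)
    io.write_tsv(pd.DataFrame(D.values, index=D.ids, columns=D.ids),
                 outdir / "bray_curtis.tsv", index=True)
    res = ordination.pcoa(D)
    coords = res.coordinates.copy()
    io.write_tsv(coords.rename_axis("sample_id"), outdir / "pcoa_coordinates.tsv",
                 index=True)

    meta = table.metadata.loc[list(D.ids)]
    n_perm = int(ord_cfg.get("n_perm", 999))
    rows, summary = [], {}
    soil_res = ordination.anosim(D, meta["soil"], n_perm=n_perm, seed=seed)
    rows.append({"test": "one-way soil", "R": soil_res.R, "p": soil_res.p_value})
    summary["soil_R"] = soil_res.R
    for soil in sorted(meta["soil"].unique()):
        ids = [i for i in D.ids if meta.loc[i, "soil"] == soil]
        idx = [D.ids.index(i) for i in ids]
        sub = ordination.DistanceMatrix(ids=ids, values=D.values[np.ix_(idx, idx)])
        r = ordination.anosim(sub, meta.loc[ids, "treatment"], n_perm=n_perm, seed=seed)
        rows.append({"test": f"one-way treatment ({soil})", "R": r.R, "p": r.p_value})
        summary[f"treatment_R_{soil}"] = r.R
    two = ordination.anosim(D, meta["treatment"], n_perm=n_perm, seed=seed,
                            design="two_way", blocks=meta["soil"])
    rows.append({"test": "two-way treatment | soil blocks", "R": two.R,
                 "p": two.p_value})
    io.write_tsv(pd.DataFrame(rows), outdir / "anosim.tsv")
    summary["explained_axis1"] = float(res.explained[0]) if len(res.explained) else 0.0
    return summary


def _run_screen(table, config, outdir, alpha) -> dict:
    scr_cfg = config.get("screen", {}) or {}
    control = scr_cfg.get("control", "Con")
    summary = {}
    for level, name in (("genus", "responders_genus.tsv"),
                        ("phylum", "responders_phylum.tsv")):
        records = screen.screen_responders(table, level=level, alpha=alpha,
                                           control=control)
        io.write_tsv(screen.responders_frame(records), outdir / name)
        n_resp = sum(any(d != "none" for d in r.direction.values()) for r in records)
        summary[f"n_responders_{level}"] = n_resp
    return summary


def _run_biotest(growth, config, outdir, alpha) -> dict:
    control = config.get("biotest", {}).get("control", "Con")
    report = biotest.table1_report(growth, control=control, alpha=alpha)
    io.write_tsv(report, outdir / "biotest_table.tsv")
    out = {"groups": len(report)}
    if "week" in growth.columns:
        flags = biotest.timecourse_flags(growth, control=control, alpha=alpha)
        io.write_tsv(flags, outdir / "biotest_weekly_flags.tsv")
        out["first_flagged"] = {f"{s}:{t}": w for (s, t), w
                                in biotest.first_flagged_week(flags).items()}
    return out


def _run_qpcr(qpcr, outdir, alpha) -> dict:
    res = screen.qpcr_compare(qpcr, alpha=alpha)
    rows = []
    for soil, r in res.items():
        for treatment, letters in r["letters"].items():
            rows.append({"soil": soil, "treatment": treatment, "letters": letters,
                         "anova_p": r["p"]})
    io.write_tsv(pd.DataFrame(rows), outdir / "qpcr.tsv")
    return {soil: r["p"] for soil, r in res.items()}
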