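"""Plain-text readers and writers.

Formats: lane-profile CSV (lane_id,label,bin_0..bin_{L-1}); OTU count TSV
(rows = OTUs, columns = samples); taxonomy TSV in the mothur consensus
dialect (confidence suffixes like ``(100)`` are stripped on read);
sample-metadata TSV; growth and qPCR CSV.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .community import LEVELS, UNCLASSIFIED, OtuTable
from .fingerprint import FingerprintSet

_CONFIDENCE = re.compile(r"\(\d+(\.\d+)?\)")


# ------------------------------------------------------------------ lanes CSV

def write_lanes_csv(fp: FingerprintSet, path) -> None:
    L = fp.profiles.shape[1]
    frame = pd.DataFrame(fp.profiles, columns=[f"bin_{i}" for i in range(L)])
    frame.insert(0, "label", fp.groups)
    frame.insert(0, "lane_id", fp.lane_ids)
    frame.to_csv(path, index=False)


def read_lanes_csv(path) -> FingerprintSet:
    frame = pd.read_csv(path)
    bins = [c for c in frame.columns if c.startswith("bin_")]
    if not bins:
        raise ValueError(f"{path}: no bin_* columns found")
    return FingerprintSet(lane_ids=tuple(frame["lane_id"].astype(str)),
                          groups=tuple(frame["label"].astype(str)),
                          profiles=frame[bins].values.astype(float))


# ------------------------------------------------------------------- OTU TSVs

def write_otu_table(table: OtuTable, counts_path, taxonomy_path, metadata_path) -> None:
    table.counts.T.rename_axis("otu_id").to_csv(counts_path, sep="\t")
    lineage = table.taxonomy[list(LEVELS)].agg(";".join, axis=1)
    pd.DataFrame({"otu_id": table.taxonomy.index, "lineage": lineage.values}) \
        .to_csv(taxonomy_path, sep="\t", index=False)
    table.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    """Parse a taxonomy TSV; accepts plain (otu_id, lineage) files and the
    mothur consensus dialect (OTU, Size, Taxonomy) with confidence
    suffixes."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in frame.columns}
    otu_col = cols.get("otu_id") or cols.get("otu") or frame.columns[0]
    tax_col = cols.get("lineage") or cols.get("taxonomy") or frame.columns[-1]
    rows = []
    for lineage in frame[tax_col]:
        lineage = _CONFIDENCE.sub("", str(lineage)).strip().rstrip(";")
        parts = [p.strip() or UNCLASSIFIED for p in lineage.split(";")]
        parts = (parts + [UNCLASSIFIED] * len(LEVELS))[: len(LEVELS)]
        rows.append(parts)
    return pd.DataFrame(rows, index=frame[otu_col].astype(str).values,
                        columns=list(LEVELS))


def read_otu_table(counts_path, taxonomy_path, metadata_path) -> OtuTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0).T
    counts = counts.astype(np.int64)
    counts.index.name = None
    counts.columns.name = None
    taxonomy = read_taxonomy(taxonomy_path)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    if "replicate" in metadata.columns:
        metadata["replicate"] = metadata["replicate"].astype(int)
    return OtuTable(counts=counts, taxonomy=taxonomy, metadata=metadata)


# ---------------------------------------------------------------- growth CSVs

def write_growth_csv(growth: pd.DataFrame, path) -> None:
    growth.to_csv(path, index=False)


def read_growth_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"soil", "treatment"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)
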