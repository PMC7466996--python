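"""Plain-text I/O: TSV matrices, BED/bedGraph tracks, GMT gene sets, YAML config."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chip import ReadStartTrack
from .synth import SimConfig

__all__ = [
    "read_matrix_tsv", "write_matrix_tsv",
    "write_bedgraph", "read_bedgraph",
    "write_catalog_bed",
    "read_gmt", "write_gmt",
    "load_sim_config", "dump_sim_config",
    "write_track_bedgraphs",
]


def read_matrix_tsv(path) -> pd.DataFrame:
    """Gene-by-sample matrix with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def write_bedgraph(values: np.ndarray, contig: str, path) -> None:
    """Run-length-encoded bedGraph of one per-position array."""
    values = np.asarray(values)
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [values.size]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0:
                fh.write(f"{contig}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, contig_lengths: dict) -> dict:
    """Per-contig dense arrays from a bedGraph file."""
    arrays = {c: np.zeros(n) for c, n in contig_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "start", "end", "value"])
    for row in df.itertuples():
        arrays[row.contig][row.start:row.end] = row.value
    return arrays


def write_track_bedgraphs(track: ReadStartTrack, prefix) -> list:
    """One bedGraph per strand of a read-start track; returns the paths."""
    prefix = Path(prefix)
    paths = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        path = prefix.with_name(prefix.name + f".{tag}.bedgraph")
        with open(path, "w") as fh:
            for contig, by_strand in track.starts.items():
                vals = by_strand[strand]
                for pos in np.flatnonzero(vals):
                    fh.write(f"{contig}\t{pos}\t{pos + 1}\t{vals[pos]}\n")
        paths.append(path)
    return paths


def write_catalog_bed(catalog: pd.DataFrame, path,
                      contig: str = "chrI") -> None:
    """BED6 of gene bodies (0-based half-open; score column holds 0)."""
    with open(path, "w") as fh:
        for gene in catalog.itertuples():
            lo, hi = sorted((int(gene.tss), int(gene.tts)))
            fh.write(f"{contig}\t{lo}\t{hi}\t{gene.gene_id}\t0\t{gene.strand}\n")


def read_gmt(path) -> dict:
    """GMT gene sets: name, description, members per tab-separated line."""
    groups = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                groups[parts[0]] = set(filter(None, parts[2:]))
    return groups


def write_gmt(groups: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in groups.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
    if "copy_numbers" in raw:
        raw["copy_numbers"] = tuple(raw["copy_numbers"])
    return SimConfig(**raw)


def dump_sim_config(config: SimConfig, path) -> None:
    data = {f.name: getattr(config, f.name) for f in fields(SimConfig)}
    data["copy_numbers"] = list(data["copy_numbers"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
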