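"""Readers, writers, and core containers for the prioritization pipeline.

All genomic coordinates are 0-based half-open (BED convention) everywhere
inside the package; any 1-based input must be converted at the boundary.
Downstream stages consume only the containers defined here and never
re-parse files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("craniodev")
if not logger.handlers:  # stderr logging with stage timings
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class stage_timer:
    """Context manager logging the wall time of a pipeline stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s started", self.name)
        return self

    def __exit__(self, *exc):
        logger.info("stage %s finished in %.2fs", self.name, time.perf_counter() - self.t0)
        return False


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ["chrom", "start", "end", "name"]


def segment_set(records: Iterable[tuple] | pd.DataFrame) -> pd.DataFrame:
    """Build a validated segment table (chrom, start, end, name).

    Intervals are 0-based half-open.  Raises ``ValueError`` on start >= end
    or negative coordinates.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "name" not in df.columns:
            df["name"] = [f"seg{i}" for i in range(len(df))]
        df = df[SEGMENT_COLUMNS].reset_index(drop=True)
    else:
        rows = []
        for i, rec in enumerate(records):
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            name = rec[3] if len(rec) > 3 and rec[3] is not None else f"seg{i}"
            rows.append((chrom, start, end, name))
        df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    if len(df):
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValueError("negative segment coordinate")
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"segment with start >= end at row {bad}")
    else:
        df = pd.DataFrame(columns=SEGMENT_COLUMNS).astype(
            {"start": np.int64, "end": np.int64}
        )
    return df


@dataclasses.dataclass
class ExpressionMatrix:
    """Nonnegative gene x sample counts plus a sample -> tissue map.

    ``counts`` is a DataFrame indexed by gene_id with sample columns;
    ``sample_tissue`` maps every sample to its tissue label.
    """

    counts: pd.DataFrame
    sample_tissue: pd.Series

    def __post_init__(self):
        self.sample_tissue = pd.Series(self.sample_tissue)
        if not self.counts.index.is_unique:
            raise ValueError("duplicate gene ids in expression matrix")
        missing = [s for s in self.counts.columns if s not in self.sample_tissue.index]
        if missing:
            raise ValueError(f"samples without tissue label: {missing[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.sample_tissue = self.sample_tissue.loc[list(self.counts.columns)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts.loc[list(genes)], self.sample_tissue)


@dataclasses.dataclass
class RunConfig:
    """Thresholds and parameters for every pipeline stage."""

    seed: int = 0
    gini_threshold: float = 0.7
    max_link_distance: int = 1_000_000
    permutations: int = 1000
    soft_power: float = 18.0
    min_module_size: int = 100
    merge_height: float = 0.18
    cut_height: float = 0.995
    hub_fraction: float = 0.10
    max_decile: int = 3
    min_extra_criteria: int = 2
    min_enhancers: int = 1
    median_distance_cutoff: int = 400_000
    bin_width: int = 20_000

    def __post_init__(self):
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if not (0 < self.hub_fraction < 1):
            raise ValueError("hub_fraction must be in (0,1)")
        if not (0 < self.merge_height < 1):
            raise ValueError("merge_height must be in (0,1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED4 into a segment table; extra columns are ignored."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start},{end})")
            name = fields[3] if len(fields) > 3 else f"seg{len(rows)}"
            rows.append((fields[0], start, end, name))
    return segment_set(rows)


def write_bed(segments: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for rec in segments.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\n")


def read_counts(path) -> pd.DataFrame:
    """Read a TSV matrix (header row, gene_id first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and not df[col].isna().any():
            row = df.index[vals.isna()][0]
            raise ParseError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        df[col] = vals
    return df


def read_table(path) -> pd.DataFrame:
    """Generic keyed TSV: header row, first column is the key."""
    return read_counts(path)


def read_gene_list(path) -> set:
    """One gene id per line; blank lines and '#' comments are skipped."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def read_annotation(path) -> pd.DataFrame:
    """Read a TSS annotation table (gene_id, chrom, tss, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
    return validate_annotation(df)


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in annotation")
    if (df["tss"] < 0).any():
        raise ValueError("negative TSS position")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    df = df.copy()
    df["tss"] = df["tss"].astype(np.int64)
    return df.reset_index(drop=True)


def read_expression(counts_path, tissue_map_path) -> ExpressionMatrix:
    """Counts TSV plus a two-column sample -> tissue TSV."""
    counts = read_counts(counts_path)
    tmap = pd.read_csv(tissue_map_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(counts, tmap)


def write_manifest(path, config: RunConfig, inputs: Mapping[str, str], stage: str) -> None:
    """JSON run manifest recording inputs, parameters, seed, and versions."""
    import craniodev

    manifest = {
        "stage": stage,
        "inputs": dict(inputs),
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {
            "craniodev": craniodev.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
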