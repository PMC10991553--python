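"""Readers and writers for the text formats the pipeline exchanges.

Tracks travel as bedGraph (4 columns, 0-based half-open), one file per
strand; reads as BED6 with the score column standing in for mapping
quality (alignment itself is out of scope); genomes as two-column
chrom.sizes; tables as TSV. Writers prepend a comment header with the
tool version, a configuration hash, and the seed so that reruns are
traceable; readers skip ``#`` comment and ``track`` lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .core import Genome, ReadSet, StrandCoverage

_COMMENT = "#"


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(seed: int | None = None, config: dict[str, Any] | None = None) -> str:
    parts = [f"resectquant v{__version__}"]
    if config is not None:
        parts.append(f"config={config_hash(config)}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return f"{_COMMENT} " + " ".join(parts) + "\n"


def read_chrom_sizes(path: str | Path) -> Genome:
    """Parse a two-column (name, length) chrom.sizes file."""
    sizes: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(_COMMENT):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            name, raw_len = fields
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            try:
                length = int(raw_len)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed length {raw_len!r}") from err
            seen.add(name)
            sizes.append((name, length))
    if not sizes:
        raise ValueError(f"{path}: no chromosomes found")
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f"{chrom}\t{genome[chrom]}\n")


def _read_bedgraph_vector(path: str | Path, genome: Genome) -> dict[str, np.ndarray]:
    vectors = {c: np.zeros(genome[c]) for c in genome}
    occupied = {c: np.zeros(genome[c], dtype=bool) for c in genome}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(_COMMENT) or line.startswith("track"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end > genome[chrom] or start >= end:
                raise ValueError(f"{path}:{lineno}: bad interval {chrom}:{start}-{end}")
            if occupied[chrom][start:end].any():
                raise ValueError(f"{path}:{lineno}: overlapping interval {chrom}:{start}-{end}")
            occupied[chrom][start:end] = True
            vectors[chrom][start:end] = value
    return vectors


def read_bedgraph_pair(
    fwd_path: str | Path, rev_path: str | Path, genome: Genome
) -> StrandCoverage:
    """Load a forward/reverse bedGraph pair into dense per-base vectors.

    Positions not covered by any interval are 0; overlapping intervals
    within one file are rejected.
    """
    return StrandCoverage(
        genome=genome,
        fwd=_read_bedgraph_vector(fwd_path, genome),
        rev=_read_bedgraph_vector(rev_path, genome),
    )


def _write_bedgraph_vector(
    vector_by_chrom: dict[str, np.ndarray],
    genome: Genome,
    path: str | Path,
    seed: int | None,
    config: dict[str, Any] | None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed=seed, config=config))
        for chrom in genome:
            v = np.asarray(vector_by_chrom[chrom])
            if len(v) == 0:
                continue
            # run-length encode: one row per maximal constant run, zeros skipped
            change = np.flatnonzero(v[1:] != v[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    val = v[s]
                    text = f"{val:.6g}" if val != int(val) else str(int(val))
                    fh.write(f"{chrom}\t{s}\t{e}\t{text}\n")


def write_bedgraph_pair(
    cov: StrandCoverage,
    fwd_path: str | Path,
    rev_path: str | Path,
    seed: int | None = None,
    config: dict[str, Any] | None = None,
) -> None:
    _write_bedgraph_vector(cov.fwd, cov.genome, fwd_path, seed, config)
    _write_bedgraph_vector(cov.rev, cov.genome, rev_path, seed, config)


def read_bed_reads(
    path: str | Path, genome: Genome, min_score: float | None = None
) -> tuple[ReadSet, int]:
    """Load BED6 reads; returns the read set and the number dropped by score."""
    rows = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(_COMMENT) or line.startswith("track"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}")
            chrom, start, end, name, score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            start, end = int(start), int(end)
            if chrom not in genome or start < 0 or end > genome[chrom] or start >= end:
                raise ValueError(f"{path}:{lineno}: bad interval {chrom}:{start}-{end}")
            score_val = float(score)
            if min_score is not None and score_val < min_score:
                dropped += 1
                continue
            rows.append((chrom, start, end, name, score_val, strand))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return ReadSet(reads=df, name=str(path)), dropped


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: dict[str, Any] | None = None,
) -> None:
    """Write a table as TSV with the standard provenance header."""
    with open(path, "w") as fh:
        fh.write(_header(seed=seed, config=config))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment=_COMMENT)


def write_bed3(
    intervals: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: dict[str, Any] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed=seed, config=config))
        for _, row in intervals.iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\n")
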