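"""Core genomic containers shared by the simulator and the quantification stages.

Coordinates are 0-based, half-open everywhere. The forward strand is the
reference strand read 5'->3' with increasing coordinate. A double-strand
break at coordinate ``x0`` falls between positions ``x0 - 1`` and ``x0``:
the right-hand fragment occupies positions ``>= x0``, the left-hand
fragment positions ``< x0``. Because 5'->3' resection degrades the
5'-terminated strand of each fragment, coverage loss appears on the
forward strand right of the break and on the reverse strand left of it;
the persisting 3' single-stranded DNA has the opposite polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

STRANDS = ("fwd", "rev")


class Genome:
    """Ordered collection of chromosome names and lengths (bp)."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        if not items:
            raise ValueError("genome must contain at least one chromosome")
        self._sizes: dict[str, int] = {}
        for name, length in items:
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._sizes[name] = length

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self._sizes)

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self._sizes == other._sizes

    def __repr__(self) -> str:
        return f"Genome({self._sizes!r})"


@dataclass
class StrandCoverage:
    """Per-chromosome, per-strand, per-base coverage vectors.

    ``fwd`` and ``rev`` map chromosome name to a dense non-negative vector
    of length equal to the chromosome. Values may be floats (expected
    coverage, normalized tracks) or integer counts.
    """

    genome: Genome
    fwd: dict[str, np.ndarray]
    rev: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for strand in STRANDS:
            vectors = getattr(self, strand)
            for chrom in self.genome:
                if chrom not in vectors:
                    raise ValueError(f"missing {strand} vector for chromosome {chrom!r}")
                v = np.asarray(vectors[chrom], dtype=float)
                if v.shape != (self.genome[chrom],):
                    raise ValueError(
                        f"{strand} vector for {chrom!r} has length {v.shape}, "
                        f"expected {self.genome[chrom]}"
                    )
                if np.any(v < 0):
                    raise ValueError(f"negative coverage on {chrom!r} ({strand})")
                vectors[chrom] = v

    @classmethod
    def zeros(cls, genome: Genome) -> "StrandCoverage":
        return cls(
            genome=genome,
            fwd={c: np.zeros(genome[c]) for c in genome},
            rev={c: np.zeros(genome[c]) for c in genome},
        )

    def strand(self, name: str) -> dict[str, np.ndarray]:
        if name not in STRANDS:
            raise ValueError(f"unknown strand {name!r}")
        return getattr(self, name)

    def summed(self, chrom: str) -> np.ndarray:
        """Strand-summed coverage for one chromosome."""
        return self.fwd[chrom] + self.rev[chrom]

    def scaled(self, factor: float) -> "StrandCoverage":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return StrandCoverage(
            genome=self.genome,
            fwd={c: self.fwd[c] * factor for c in self.genome},
            rev={c: self.rev[c] * factor for c in self.genome},
        )


@dataclass
class ReadSet:
    """Strand-tagged read intervals (the post-alignment currency).

    ``reads`` has columns chrom, start, end, strand ('+'/'-') and an
    optional numeric score standing in for mapping quality.
    """

    reads: pd.DataFrame
    name: str = "reads"

    REQUIRED = ("chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.reads.columns:
                raise ValueError(f"ReadSet missing column {col!r}")
        bad = ~self.reads["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(
                f"invalid strand value(s): {self.reads.loc[bad, 'strand'].unique()!r}"
            )
        if (self.reads["start"] >= self.reads["end"]).any():
            raise ValueError("reads must satisfy start < end")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakSet:
    """Half-open genomic intervals used as normalization references."""

    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.chrom, p.start, p.end) for p in self.peaks],
            columns=["chrom", "start", "end"],
        )


@dataclass
class RatioTrack:
    """Positionwise coverage ratio with mask semantics.

    Masked positions (denominator zero) carry NaN; they are undefined, not
    infinite, and are excluded from any downstream averaging.
    """

    genome: Genome
    fwd: dict[str, np.ndarray]
    rev: dict[str, np.ndarray]

    def strand(self, name: str) -> dict[str, np.ndarray]:
        if name not in STRANDS:
            raise ValueError(f"unknown strand {name!r}")
        return getattr(self, name)


@dataclass
class BinnedProfile:
    """Per-strand values over fixed-width bins centred on the DSB.

    ``edges`` are bin boundaries in bp relative to the break (length
    n_bins + 1, ascending, tiling [-half, +half)). Masked bins carry NaN.
    """

    edges: np.ndarray
    fwd: np.ndarray
    rev: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.fwd = np.asarray(self.fwd, dtype=float)
        self.rev = np.asarray(self.rev, dtype=float)
        n = len(self.edges) - 1
        if self.fwd.shape != (n,) or self.rev.shape != (n,):
            raise ValueError("value arrays must have one entry per bin")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def strand(self, name: str) -> np.ndarray:
        if name not in STRANDS:
            raise ValueError(f"unknown strand {name!r}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for strand in STRANDS:
            vals = self.strand(strand)
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "bin_start": int(self.edges[i]),
                        "bin_end": int(self.edges[i + 1]),
                        "strand": strand,
                        "value": v,
                        "masked": bool(np.isnan(v)),
                    }
                )
        return pd.DataFrame(rows)
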