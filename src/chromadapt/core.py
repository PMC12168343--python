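"""Core containers shared across the pipeline.

All coordinates are 0-based, half-open intervals on the forward strand of a
named chromosome; strand only encodes transcription orientation. Conversion
from 1-based closed conventions (GTF) happens at format boundaries only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "GeneModel",
    "ReadSet",
    "WindowTrack",
    "Peak",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths of a (toy or real) assembly."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "GenomeSpec":
        return cls(tuple(sizes), tuple(sizes.values()))

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def n_windows(self, window_size: int) -> dict[str, int]:
        """Number of fixed-width windows tiling each chromosome."""
        return {c: math.ceil(l / window_size) for c, l in self.sizes.items()}


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand, exon structure and derived TSS/TTS.

    ``start``/``end`` delimit the gene body; exons must lie within it.  The
    transcription start site is ``start`` on the plus strand and ``end`` on
    the minus strand (the TTS is the opposite anchor).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: need 0 <= start < end")
        if not self.exons:
            object.__setattr__(self, "exons", ((self.start, self.end),))
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


_READ_COLUMNS = ("chrom", "start", "end", "strand")


@dataclass
class ReadSet:
    """Aligned single-end read intervals for one sample.

    Backed by a DataFrame with columns chrom/start/end/strand so that
    deduplication and subsampling are vectorised.
    """

    records: pd.DataFrame
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        missing = [c for c in _READ_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"ReadSet missing columns: {missing}")
        self.records = self.records.loc[:, list(_READ_COLUMNS)].reset_index(drop=True)

    @classmethod
    def from_arrays(
        cls,
        chrom: Iterable[str],
        start: Iterable[int],
        end: Iterable[int],
        strand: Iterable[str],
        sample_id: str = "sample",
    ) -> "ReadSet":
        df = pd.DataFrame(
            {
                "chrom": np.asarray(list(chrom), dtype=object),
                "start": np.asarray(list(start), dtype=np.int64),
                "end": np.asarray(list(end), dtype=np.int64),
                "strand": np.asarray(list(strand), dtype=object),
            }
        )
        return cls(df, sample_id)

    def __len__(self) -> int:
        return len(self.records)

    def validate(self, genome: GenomeSpec | None = None) -> None:
        r = self.records
        if (r["start"] < 0).any():
            raise ValueError("negative read start coordinate")
        if (r["end"] <= r["start"]).any():
            raise ValueError("read end must exceed start")
        if not r["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        if genome is not None:
            sizes = genome.sizes
            unknown = set(r["chrom"]) - set(sizes)
            if unknown:
                raise ValueError(f"unknown chromosomes: {sorted(unknown)}")
            for chrom, grp in r.groupby("chrom", sort=False):
                if (grp["end"] > sizes[chrom]).any():
                    raise ValueError(f"read beyond end of {chrom}")


@dataclass
class WindowTrack:
    """Per-chromosome vectors over a fixed-width window tiling."""

    window_size: int
    data: dict[str, np.ndarray]
    value_kind: str = "count"  # count | density | difference

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.value_kind not in ("count", "density", "difference"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        self.data = {c: np.asarray(v) for c, v in self.data.items()}
        if self.value_kind == "count":
            for c, v in self.data.items():
                if (v < 0).any():
                    raise ValueError(f"negative counts on {c}")

    @classmethod
    def zeros(
        cls, genome: GenomeSpec, window_size: int, value_kind: str = "count"
    ) -> "WindowTrack":
        data = {
            c: np.zeros(n, dtype=float)
            for c, n in genome.n_windows(window_size).items()
        }
        return cls(window_size, data, value_kind)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def same_grid(self, other: "WindowTrack") -> bool:
        return self.window_size == other.window_size and {
            c: len(v) for c, v in self.data.items()
        } == {c: len(v) for c, v in other.data.items()}

    def rpm(self) -> "WindowTrack":
        """Depth-normalise to reads (signal) per million total."""
        tot = self.total()
        if tot <= 0:
            raise ValueError("cannot RPM-normalise an empty track")
        scale = 1e6 / tot
        return WindowTrack(
            self.window_size,
            {c: v * scale for c, v in self.data.items()},
            "density",
        )


@dataclass(frozen=True)
class Peak:
    """A maximal run of enriched windows called significant."""

    chrom: str
    start: int
    end: int
    n_windows: int
    min_p: float
    mean_ip: float = field(default=float("nan"))
    mean_input: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("peak end must exceed start")
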