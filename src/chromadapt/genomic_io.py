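"""Readers and writers for the interval formats the pipeline touches.

Internally everything is 0-based half-open (BED-native).  GTF-lite input is
1-based closed and converted on read; no other format needs conversion.
Malformed lines raise :class:`FormatError` carrying the 1-based line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenomeSpec, ReadSet, WindowTrack

__all__ = [
    "FormatError",
    "read_reads",
    "write_reads",
    "read_genes",
    "write_genes",
    "write_track",
    "read_track",
    "read_gene_sets",
    "write_genome",
    "read_genome",
]


class FormatError(ValueError):
    """A parse or validation failure tied to a specific file line."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _split_lines(path):
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield i, line.split("\t")


def read_reads(
    path, format: str = "bed6", genome: GenomeSpec | None = None
) -> ReadSet:
    """Load aligned-read intervals from BED6 or tagAlign.

    Both formats carry chrom/start/end/name/score/strand columns; tagAlign
    stores the read sequence in the name field, which is ignored here.
    """
    if format.lower() not in ("bed6", "tagalign"):
        raise ValueError(f"unsupported read format {format!r}")
    sizes = genome.sizes if genome is not None else None
    chroms, starts, ends, strands = [], [], [], []
    for line_no, fields in _split_lines(path):
        if len(fields) < 6:
            raise FormatError(path, line_no, f"expected 6 columns, got {len(fields)}")
        chrom, s, e, _name, _score, strand = fields[:6]
        try:
            start, end = int(s), int(e)
        except ValueError:
            raise FormatError(path, line_no, f"non-integer coordinates {s!r}/{e!r}")
        if start < 0:
            raise FormatError(path, line_no, "negative start coordinate")
        if end <= start:
            raise FormatError(path, line_no, f"end {end} <= start {start}")
        if strand not in ("+", "-"):
            raise FormatError(path, line_no, f"bad strand {strand!r}")
        if sizes is not None:
            if chrom not in sizes:
                raise FormatError(path, line_no, f"unknown chromosome {chrom!r}")
            if end > sizes[chrom]:
                raise FormatError(path, line_no, f"interval beyond end of {chrom}")
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
        strands.append(strand)
    return ReadSet.from_arrays(chroms, starts, ends, strands,
                               sample_id=Path(path).stem)


def write_reads(reads: ReadSet, path) -> None:
    """Write a ReadSet as 6-column BED (name='.', score=0)."""
    df = reads.records
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": ".",
            "score": 0,
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def _parse_bed12_row(path, line_no, fields) -> GeneModel:
    if len(fields) < 12:
        raise FormatError(path, line_no, f"expected 12 columns, got {len(fields)}")
    chrom, s, e, name, _score, strand = fields[:6]
    try:
        start, end = int(s), int(e)
        n_exons = int(fields[9])
        sizes = [int(v) for v in fields[10].rstrip(",").split(",")]
        offsets = [int(v) for v in fields[11].rstrip(",").split(",")]
    except ValueError:
        raise FormatError(path, line_no, "malformed numeric field")
    if len(sizes) != n_exons or len(offsets) != n_exons:
        raise FormatError(path, line_no, "blockCount disagrees with block lists")
    exons = tuple((start + o, start + o + l) for o, l in zip(offsets, sizes))
    try:
        return GeneModel(name, chrom, strand, start, end, exons)
    except ValueError as exc:
        raise FormatError(path, line_no, str(exc))


def read_genes(path, format: str = "bed12") -> list[GeneModel]:
    """Load gene models from BED12 or GTF-lite.

    GTF-lite is tab-separated seqname/source/feature/start/end/score/strand/
    frame/attributes with 1-based closed coordinates; only rows whose feature
    is ``gene`` or ``exon`` are used and the gene_id attribute groups exons.
    """
    fmt = format.lower().replace("-", "")
    if fmt == "bed12":
        return [_parse_bed12_row(path, n, f) for n, f in _split_lines(path)]
    if fmt != "gtflite":
        raise ValueError(f"unsupported gene format {format!r}")

    bodies: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for line_no, fields in _split_lines(path):
        if len(fields) < 9:
            raise FormatError(path, line_no, f"expected 9 columns, got {len(fields)}")
        chrom, _src, feature, s, e, _score, strand, _frame, attrs = fields[:9]
        if feature not in ("gene", "exon"):
            continue
        try:
            start1, end1 = int(s), int(e)
        except ValueError:
            raise FormatError(path, line_no, "non-integer coordinates")
        if start1 < 1 or end1 < start1:
            raise FormatError(path, line_no, "bad 1-based closed interval")
        start, end = start1 - 1, end1  # to 0-based half-open
        gid = None
        for token in attrs.split(";"):
            token = token.strip()
            if token.startswith("gene_id"):
                gid = token.split(None, 1)[1].strip().strip('"')
        if gid is None:
            raise FormatError(path, line_no, "missing gene_id attribute")
        if feature == "gene":
            if gid not in bodies:
                order.append(gid)
            bodies[gid] = (chrom, strand, start, end)
        else:
            exons.setdefault(gid, []).append((start, end))
    genes = []
    for gid in order:
        chrom, strand, start, end = bodies[gid]
        ex = tuple(sorted(exons.get(gid, [(start, end)])))
        try:
            genes.append(GeneModel(gid, chrom, strand, start, end, ex))
        except ValueError as exc:
            raise FormatError(path, 0, f"{gid}: {exc}")
    return genes


def write_genes(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as BED12."""
    with open(path, "w") as fh:
        for g in genes:
            ex = sorted(g.exons)
            sizes = ",".join(str(e - s) for s, e in ex)
            offsets = ",".join(str(s - g.start) for s, _ in ex)
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                        g.start, g.end, "0,0,0", len(ex), sizes, offsets,
                    )
                )
                + "\n"
            )


def write_track(track: WindowTrack, path) -> None:
    """Write a WindowTrack as bedGraph, run-length encoding equal windows."""
    w = track.window_size
    with open(path, "w") as fh:
        for chrom, values in track.data.items():
            v = np.asarray(values)
            if len(v) == 0:
                continue
            change = np.flatnonzero(v[1:] != v[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                val = v[s]
                txt = repr(int(val)) if float(val).is_integer() else repr(float(val))
                fh.write(f"{chrom}\t{s * w}\t{e * w}\t{txt}\n")


def read_track(
    path, genome: GenomeSpec, window_size: int, value_kind: str = "count"
) -> WindowTrack:
    """Read a bedGraph written on a compatible window grid back into a track."""
    track = WindowTrack.zeros(genome, window_size, value_kind="count")
    for c in track.data:
        track.data[c] = track.data[c].astype(float)
    for line_no, fields in _split_lines(path):
        if len(fields) < 4:
            raise FormatError(path, line_no, "expected 4 bedGraph columns")
        chrom, s, e, val = fields[:4]
        if chrom not in track.data:
            raise FormatError(path, line_no, f"unknown chromosome {chrom!r}")
        start, end, value = int(s), int(e), float(val)
        if start % window_size or (end % window_size and end != genome.sizes[chrom]):
            raise FormatError(path, line_no, "interval not aligned to window grid")
        i, j = start // window_size, -(-end // window_size)
        track.data[chrom][i:j] = value
    track.value_kind = value_kind
    return track


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a 2-column TSV (category_id, gene_id) into category -> gene set."""
    sets: dict[str, set[str]] = {}
    for line_no, fields in _split_lines(path):
        if len(fields) < 2:
            raise FormatError(path, line_no, "expected 2 columns")
        sets.setdefault(fields[0], set()).add(fields[1])
    return sets


def write_genome(genome: GenomeSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(genome.sizes, fh, indent=1)


def read_genome(path) -> GenomeSpec:
    with open(path) as fh:
        return GenomeSpec.from_dict({k: int(v) for k, v in json.load(fh).items()})
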