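"""Interval I/O and genome/transcript coordinate projection.

All internal coordinates are 0-based half-open (BED convention). The
transcript frame places position 0 at the 5' end of the 3'UTR in sense
orientation, so for minus-strand genes genomic coordinates are reflected.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

REGION_5UTR = "5UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3UTR"


@dataclass
class GenomicInterval:
    """A BED-like interval: 0-based half-open, stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class UtrModel:
    """One gene's 3'UTR (longest protein-coding transcript) with optional
    sequence and the transcript's region map for cluster assignment.

    ``region_map`` holds the genome-frame intervals of the transcript's
    5'UTR, CDS and 3'UTR; it is only needed by :func:`assign_region`.
    """

    gene_id: str
    transcript_id: str
    interval: GenomicInterval
    sequence: str | None = None
    region_map: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("UTR models require a known strand")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != UTR length {self.length}"
            )

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class Track:
    """Per-nucleotide values over one 3'UTR in the transcript frame."""

    utr_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file (optionally gzipped) into intervals.

    Missing strand defaults to '+'. Malformed lines raise a ``ValueError``
    naming the offending line number.
    """
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "+"
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, name, score)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as 6-column BED; round-trips through :func:`read_bed`."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_bedgraph(path) -> Iterator[tuple[str, int, int, float]]:
    """Yield (chrom, start, end, value) records from a bedGraph file."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            yield fields[0], int(fields[1]), int(fields[2]), float(fields[3])


def write_bedgraph(records: Iterable[tuple[str, int, int, float]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def track_to_bedgraph(track: Track) -> list[tuple[str, int, int, float]]:
    """Run-length encode a transcript-frame track as bedGraph records."""
    vals = track.values
    if vals.size == 0:
        return []
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [vals.size]))
    return [
        (track.utr_id, int(s), int(e), float(vals[s]))
        for s, e in zip(starts, ends)
    ]


def bedgraph_to_tracks(
    records, lengths: dict[str, int], fill: float = 0.0
) -> dict[str, Track]:
    """Assemble per-UTR tracks from transcript-frame bedGraph records.

    ``lengths`` maps utr_id -> track length; positions not covered by any
    record take ``fill`` (use NaN for sparse score tracks like phyloP).
    """
    arrays = {uid: np.full(n, fill, dtype=float) for uid, n in lengths.items()}
    for uid, start, end, value in records:
        if uid not in arrays:
            continue
        arr = arrays[uid]
        arr[max(0, start) : min(len(arr), end)] = value
    return {uid: Track(uid, arr) for uid, arr in arrays.items()}


def to_transcript_frame(
    iv: GenomicInterval, utr: UtrModel, clip: bool = True
) -> tuple[int, int]:
    """Project a genome-frame interval into the UTR's transcript frame.

    Position 0 is the 5' end of the 3'UTR; for minus-strand UTRs the genome
    interval is reflected (rel_start = utr.end - iv.end). Intervals partially
    outside the UTR are clipped to [0, length) by default.
    """
    u = utr.interval
    if iv.chrom != u.chrom:
        raise ValueError(f"chromosome mismatch: {iv.chrom} vs {u.chrom}")
    if iv.end <= u.start or iv.start >= u.end:
        raise ValueError("interval does not overlap the UTR")
    if u.strand == "+":
        rel_start, rel_end = iv.start - u.start, iv.end - u.start
    else:
        rel_start, rel_end = u.end - iv.end, u.end - iv.start
    if clip:
        rel_start = max(rel_start, 0)
        rel_end = min(rel_end, utr.length)
    return rel_start, rel_end


def from_transcript_frame(
    rel_start: int, rel_end: int, utr: UtrModel
) -> GenomicInterval:
    """Inverse of :func:`to_transcript_frame` for in-bounds coordinates."""
    u = utr.interval
    if u.strand == "+":
        start, end = u.start + rel_start, u.start + rel_end
    else:
        start, end = u.end - rel_end, u.end - rel_start
    return GenomicInterval(u.chrom, start, end, u.strand)


def _overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def assign_region(cluster: GenomicInterval, utr_model: UtrModel) -> str:
    """Assign a cluster to one transcript region: 5UTR, CDS or 3UTR.

    A cluster overlapping both a UTR and the CDS gets the UTR label; a
    cluster overlapping both UTRs (rare) gets the one with larger overlap,
    ties going to the 3'UTR.
    """
    overlaps = {
        region: _overlap(cluster, iv)
        for region, iv in utr_model.region_map.items()
        if _overlap(cluster, iv) > 0
    }
    if not overlaps:
        raise ValueError(
            f"cluster [{cluster.start}, {cluster.end}) does not overlap "
            f"transcript {utr_model.transcript_id}"
        )
    utr_hits = {r: o for r, o in overlaps.items() if r in (REGION_5UTR, REGION_3UTR)}
    if utr_hits:
        # UTR wins over CDS; larger overlap breaks a 5'UTR/3'UTR conflict
        return max(utr_hits, key=lambda r: (utr_hits[r], r == REGION_3UTR))
    return REGION_CDS
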