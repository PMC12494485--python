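"""Mismatch-filtered read recruitment and per-base coverage.

Environmental reads recruited against MAGs or viral contigs are first
screened on their edit distance (alignments with two or more mismatches are
discarded, keeping only near-identical recruitment), then turned into
per-base depth tracks.  Hypervariable regions of the underlying population
under-recruit reads and show up as coverage drops, which downstream modules
call as metagenomic/metaviromic islands.

Coordinates are 0-based, half-open throughout the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import CoordinateError, DegenerateGenomeError, InvalidRecordError

__all__ = [
    "AlignmentRecord",
    "GenomeSet",
    "CoverageTrack",
    "filter_alignments",
    "compute_coverage",
    "genome_mean_coverage",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One recruited read alignment.

    ``mismatches`` is an NM-style edit count (indels included as provided by
    the upstream mapper).  ``is_primary`` distinguishes the primary alignment
    from secondary/supplementary placements, which never contribute depth.
    """

    query_id: str
    contig_id: str
    start: int
    end: int
    mismatches: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.mismatches < 0:
            raise InvalidRecordError(
                f"negative mismatch count on {self.query_id}: {self.mismatches}"
            )
        if self.start >= self.end:
            raise InvalidRecordError(
                f"empty or inverted interval on {self.query_id}: "
                f"[{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class GenomeSet:
    """A named replicon set: a MAG (many contigs) or a vOTU (one contig)."""

    genome_id: str
    contigs: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "contigs", tuple(tuple(c) for c in self.contigs))
        ids = [cid for cid, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise InvalidRecordError(f"duplicate contig ids in {self.genome_id}")
        for cid, length in self.contigs:
            if length <= 0:
                raise InvalidRecordError(
                    f"non-positive length for {cid} in {self.genome_id}"
                )

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.contigs)

    def contig_length(self, contig_id: str) -> int:
        for cid, length in self.contigs:
            if cid == contig_id:
                return length
        raise CoordinateError(f"{contig_id} is not a contig of {self.genome_id}")


@dataclass
class CoverageTrack:
    """Per-base integer depth for one contig."""

    contig_id: str
    depth: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise InvalidRecordError("depth must be one-dimensional")
        if (self.depth < 0).any():
            raise InvalidRecordError(f"negative depth on {self.contig_id}")

    def __len__(self) -> int:
        return len(self.depth)


def filter_alignments(
    records: Iterable[AlignmentRecord], max_mismatches: int = 1
) -> list[AlignmentRecord]:
    """Keep primary alignments with at most ``max_mismatches`` edits.

    The default of 1 implements the recruitment rule that alignments with two
    or more mismatches are removed.  Input order is preserved and the filter
    is idempotent.
    """
    if max_mismatches < 0:
        raise InvalidRecordError("max_mismatches must be >= 0")
    out = []
    for rec in records:
        if rec.mismatches < 0:  # defensive; dataclass already rejects this
            raise InvalidRecordError(f"negative mismatch count on {rec.query_id}")
        if rec.is_primary and rec.mismatches <= max_mismatches:
            out.append(rec)
    return out


def compute_coverage(
    records: Iterable[AlignmentRecord], genome: GenomeSet
) -> list[CoverageTrack]:
    """Per-base depth for every member contig of ``genome``.

    ``depth[i]`` counts alignments whose reference span contains base ``i``
    (only the aligned reference span contributes; clipped read bases do not).
    Contigs that recruit no reads get an all-zero track, so the output always
    has one track per member contig, in genome order.
    """
    lengths = dict(genome.contigs)
    # difference-array accumulation: O(reads + genome length)
    diffs = {cid: np.zeros(length + 1, dtype=np.int64) for cid, length in genome.contigs}
    for rec in records:
        if rec.contig_id not in lengths:
            raise CoordinateError(
                f"alignment {rec.query_id} references {rec.contig_id}, "
                f"not a contig of {genome.genome_id}"
            )
        if rec.start < 0 or rec.end > lengths[rec.contig_id]:
            raise CoordinateError(
                f"alignment {rec.query_id} [{rec.start}, {rec.end}) exceeds "
                f"{rec.contig_id} length {lengths[rec.contig_id]}"
            )
        d = diffs[rec.contig_id]
        d[rec.start] += 1
        d[rec.end] -= 1
    return [
        CoverageTrack(cid, np.cumsum(diffs[cid][:-1]))
        for cid, _ in genome.contigs
    ]


def genome_mean_coverage(
    tracks: Sequence[CoverageTrack], genome: GenomeSet
) -> float:
    """Length-weighted mean depth over all member contigs.

    Equals total aligned bases divided by genome length, the quantity island
    calling compares per-base depth against.
    """
    if genome.genome_length == 0:
        raise DegenerateGenomeError(f"{genome.genome_id} has zero length")
    track_ids = {t.contig_id for t in tracks}
    genome_ids = {cid for cid, _ in genome.contigs}
    if track_ids != genome_ids:
        raise CoordinateError(
            f"tracks {sorted(track_ids)} do not cover exactly the contigs of "
            f"{genome.genome_id} {sorted(genome_ids)}"
        )
    for t in tracks:
        if len(t) != genome.contig_length(t.contig_id):
            raise CoordinateError(
                f"track length {len(t)} != contig length for {t.contig_id}"
            )
    total = sum(int(t.depth.sum()) for t in tracks)
    return total / genome.genome_length
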