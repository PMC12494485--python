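"""Two-regime detection of metagenomic/metaviromic islands (MGIs/MVIs).

An island is a maximal stretch of under-recruited bases.  Which predicate
applies depends on the genome's mean coverage:

* mean >= 5x ("drop" regime): every base in the stretch has depth at most
  (1 - drop_fraction) x genome mean, i.e. the coverage dropped by at least
  25% with the defaults, and the stretch is >= 100 b long;
* 2x <= mean < 5x ("zero" regime): every base has zero depth and the
  stretch is >= 200 b long;
* mean < 2x: the genome is too shallow to call islands and yields none.

The predicate is evaluated per base (not on windowed averages), stretches
never span contig boundaries, and stretches touching a contig end are
reported with ``at_contig_edge`` set rather than discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, GenomeSet
from .errors import ConsistencyError, InvalidRecordError

__all__ = ["IslandParams", "Island", "detect_islands", "island_summary"]


@dataclass(frozen=True)
class IslandParams:
    """Thresholds of the two-regime island rule.

    ``gap_merge`` optionally fuses qualifying runs separated by at most that
    many non-qualifying bases; the default of 0 performs no merging, so every
    reported island satisfies its predicate at every base.
    """

    drop_fraction: float = 0.25
    min_len_drop: int = 100
    min_len_zero: int = 200
    high_cov_threshold: float = 5.0
    low_cov_threshold: float = 2.0
    gap_merge: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.drop_fraction < 1.0:
            raise InvalidRecordError("drop_fraction must be in (0, 1)")
        if self.min_len_drop <= 0 or self.min_len_zero <= 0:
            raise InvalidRecordError("minimum island lengths must be positive")
        if not self.low_cov_threshold < self.high_cov_threshold:
            raise InvalidRecordError(
                "low_cov_threshold must be below high_cov_threshold"
            )
        if self.gap_merge < 0:
            raise InvalidRecordError("gap_merge must be >= 0")


@dataclass(frozen=True)
class Island:
    """One maximal low-coverage stretch, 0-based half-open."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    regime: str  # "drop" | "zero"
    genome_mean: float
    island_mean: float
    at_contig_edge: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def _qualifying_runs(mask: np.ndarray) -> Iterable[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as (start, end) half-open pairs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return zip(edges[0::2], edges[1::2])


def _merge_runs(
    runs: list[tuple[int, int]], gap_merge: int
) -> list[tuple[int, int]]:
    if gap_merge <= 0 or not runs:
        return runs
    merged = [runs[0]]
    for start, end in runs[1:]:
        if start - merged[-1][1] <= gap_merge:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def detect_islands(
    tracks: Sequence[CoverageTrack],
    genome_mean: float,
    params: IslandParams | None = None,
    genome_id: str = "",
) -> list[Island]:
    """Call islands on a genome's coverage tracks under the two-regime rule.

    Returns maximal qualifying runs meeting the regime's minimum length,
    sorted by (contig_id, start).  Genomes with mean below the zero-regime
    floor return an empty list.
    """
    if genome_mean < 0:
        raise InvalidRecordError("genome mean coverage must be >= 0")
    params = params or IslandParams()

    if genome_mean >= params.high_cov_threshold:
        regime = "drop"
        min_len = params.min_len_drop
        # "dropped >= 25%": at or below (1 - drop_fraction) x mean
        threshold = (1.0 - params.drop_fraction) * genome_mean
    elif genome_mean >= params.low_cov_threshold:
        regime = "zero"
        min_len = params.min_len_zero
        threshold = None
    else:
        return []

    islands: list[Island] = []
    for track in sorted(tracks, key=lambda t: t.contig_id):
        if regime == "drop":
            mask = track.depth <= threshold
        else:
            mask = track.depth == 0
        runs = _merge_runs(list(_qualifying_runs(mask)), params.gap_merge)
        for start, end in runs:
            start, end = int(start), int(end)
            if end - start < min_len:
                continue
            islands.append(
                Island(
                    genome_id=genome_id,
                    contig_id=track.contig_id,
                    start=start,
                    end=end,
                    regime=regime,
                    genome_mean=float(genome_mean),
                    island_mean=float(track.depth[start:end].mean()),
                    at_contig_edge=(start == 0 or end == len(track)),
                )
            )
    islands.sort(key=lambda i: (i.contig_id, i.start))
    return islands


def island_summary(
    islands: Iterable[Island], genomes: Sequence[GenomeSet]
) -> pd.DataFrame:
    """Per-genome island counts, base totals and genome fractions.

    Every genome appears, with ``n_islands=0`` when nothing was called.
    """
    lengths = {g.genome_id: g.genome_length for g in genomes}
    counts = {gid: [0, 0] for gid in lengths}
    for isl in islands:
        if isl.genome_id not in counts:
            raise ConsistencyError(f"island references unknown genome {isl.genome_id}")
        counts[isl.genome_id][0] += 1
        counts[isl.genome_id][1] += isl.length
    rows = [
        {
            "genome_id": gid,
            "n_islands": n,
            "total_island_bases": bases,
            "fraction_of_genome": bases / lengths[gid],
        }
        for gid, (n, bases) in counts.items()
    ]
    return pd.DataFrame(rows, columns=[
        "genome_id", "n_islands", "total_island_bases", "fraction_of_genome"
    ])
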