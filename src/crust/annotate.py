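"""Island-gene overlap and eggNOG/COG functional category profiling.

A gene belongs to an island when the two intervals overlap by at least one
base ("fully or partially contained").  Functional profiles follow per-hit
accounting: a protein annotated with a multi-letter category string such as
"EGP" contributes one hit to each of E, G and P.  Letters whose relative
share falls below a threshold (2% by default) are collapsed into an
"Others" bucket when the profile is reported.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .islands import Island

__all__ = [
    "COG_CATEGORIES",
    "CdsFeature",
    "CategoryProfile",
    "overlap_islands_with_cds",
    "summarize_categories",
    "top_cogs",
]

# the standard one-letter COG functional category alphabet
COG_CATEGORIES = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature with eggNOG annotation.

    ``categories`` is the protein's concatenated category string over all of
    its COGs (repeats preserved — per-hit accounting never deduplicates at
    the (protein, letter) level).
    """

    contig_id: str
    start: int
    end: int
    strand: str
    protein_id: str
    cog_ids: tuple[str, ...] = ()
    categories: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty CDS interval on {self.protein_id}")
        object.__setattr__(self, "cog_ids", tuple(self.cog_ids))


@dataclass
class CategoryProfile:
    """Per-letter hit counts and relative shares (percent of all hits)."""

    counts: dict[str, int] = field(default_factory=dict)
    relative: dict[str, float] = field(default_factory=dict)
    others_bucket: list[str] = field(default_factory=list)
    others_threshold: float = 2.0

    @property
    def total_hits(self) -> int:
        return sum(self.counts.values())

    def collapsed(self) -> dict[str, float]:
        """Relative shares with sub-threshold letters folded into "Others"."""
        out = {
            letter: share
            for letter, share in self.relative.items()
            if letter not in self.others_bucket
        }
        if self.others_bucket:
            out["Others"] = sum(self.relative[l] for l in self.others_bucket)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": letter,
                "count": self.counts[letter],
                "percent": self.relative[letter],
                "in_others": letter in self.others_bucket,
            }
            for letter in sorted(self.counts, key=lambda l: (-self.counts[l], l))
        ]
        return pd.DataFrame(rows, columns=["category", "count", "percent", "in_others"])


def overlap_islands_with_cds(
    islands: Sequence[Island], features: Sequence[CdsFeature]
) -> list[tuple[Island, CdsFeature]]:
    """All (island, CDS) pairs overlapping by >= 1 base on the same contig.

    Each pair is reported exactly once; a gene spanning two islands yields
    two pairs.  Output order is deterministic: islands in (contig, start)
    order, hits in (start, end, protein_id) order.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for feat in features:
        trees[feat.contig_id].addi(feat.start, feat.end, feat)
    pairs: list[tuple[Island, CdsFeature]] = []
    for isl in sorted(islands, key=lambda i: (i.contig_id, i.start, i.end)):
        if isl.contig_id not in trees:
            continue
        hits = [iv.data for iv in trees[isl.contig_id].overlap(isl.start, isl.end)]
        hits.sort(key=lambda f: (f.start, f.end, f.protein_id))
        pairs.extend((isl, feat) for feat in hits)
    return pairs


def _dedupe_by_protein(
    items: Iterable[CdsFeature | tuple[Island, CdsFeature]],
) -> list[CdsFeature]:
    seen: dict[str, CdsFeature] = {}
    for item in items:
        feat = item[1] if isinstance(item, tuple) else item
        seen.setdefault(feat.protein_id, feat)
    return list(seen.values())


def summarize_categories(
    items: Iterable[CdsFeature | tuple[Island, CdsFeature]],
    others_threshold: float = 2.0,
    exclude_S: bool = False,
) -> CategoryProfile:
    """Per-hit eggNOG category profile of annotated proteins.

    ``items`` may be CDS features or (island, CDS) pairs; pairs are
    deduplicated by protein_id first, so a gene overlapping several islands
    is profiled once.  Each letter of a protein's category string is one
    hit.  With ``exclude_S`` the poorly characterized "function unknown"
    category is removed before shares are computed, mirroring rankings
    quoted "excluding category S"; otherwise S stays in the denominator.
    Letters outside the standard alphabet are kept but flagged with a
    warning so upstream annotation problems surface.
    """
    counts: Counter[str] = Counter()
    for feat in _dedupe_by_protein(items):
        for letter in feat.categories:
            if letter not in COG_CATEGORIES:
                warnings.warn(
                    f"unknown eggNOG category letter {letter!r} on "
                    f"{feat.protein_id}; counted in 'unknown' bucket",
                    stacklevel=2,
                )
            counts[letter] += 1
    if exclude_S:
        counts.pop("S", None)
    total = sum(counts.values())
    relative = {
        letter: (100.0 * n / total if total else 0.0) for letter, n in counts.items()
    }
    others = sorted(l for l, share in relative.items() if share < others_threshold)
    return CategoryProfile(
        counts=dict(counts),
        relative=relative,
        others_bucket=others,
        others_threshold=others_threshold,
    )


def top_cogs(
    pairs: Iterable[CdsFeature | tuple[Island, CdsFeature]],
    n: int = 20,
    cog_info: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """The ``n`` most abundant COGs among island genes.

    Genes are deduplicated by protein_id; each of a protein's COGs then
    counts once.  Ranking is by descending count with lexicographic
    tie-break on cog_id, so the table is deterministic.  ``cog_info``
    optionally maps cog_id -> (category, function label) to fill the
    descriptive columns.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts: Counter[str] = Counter()
    for feat in _dedupe_by_protein(pairs):
        for cog in feat.cog_ids:
            counts[cog] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    info = cog_info or {}
    rows = [
        {
            "cog_id": cog,
            "category": info.get(cog, ("", ""))[0],
            "function_label": info.get(cog, ("", ""))[1],
            "count": count,
        }
        for cog, count in ranked
    ]
    return pd.DataFrame(rows, columns=["cog_id", "category", "function_label", "count"])
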