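"""Score filtering and all-agree consensus of per-classifier viral taxonomy.

Four independent classification routes (protein alignment, gene alignment,
profile search, composite scorer) each propose a lineage with a score whose
kind dictates its validity filter: bit-score >= 50, percent identity > 90,
or virus score > 0.7.  A rank is then named in the consensus only when every
classifier that assigned something at that rank agrees; a single
disagreement, or no assignment at all, leaves the rank "unclassified".
Classifiers that are silent at a rank abstain — they never veto.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import AmbiguityError, InvalidRecordError

__all__ = [
    "RANKS",
    "CLASSIFIERS",
    "UNCLASSIFIED",
    "LineageCall",
    "ConsensusLineage",
    "filter_calls",
    "consensus",
    "consensus_all",
    "classification_rates",
]

RANKS = ("realm", "kingdom", "phylum", "class", "order", "family", "genus", "species")
CLASSIFIERS = ("aln_protein", "aln_gene", "profile_search", "composite_scorer")
UNCLASSIFIED = "unclassified"

# score_kind -> predicate on the call's score
_SCORE_FILTERS = {
    "bitscore": lambda s: s >= 50.0,
    "pct_identity": lambda s: s > 90.0,
    "virus_score": lambda s: s > 0.7,
}


@dataclass(frozen=True)
class LineageCall:
    """One classifier's lineage proposal for one vOTU."""

    votu_id: str
    classifier: str
    ranks: Mapping[str, str]
    score: float
    score_kind: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", dict(self.ranks))
        if self.score_kind not in _SCORE_FILTERS:
            raise InvalidRecordError(
                f"unknown score_kind {self.score_kind!r} on {self.votu_id}"
            )


@dataclass(frozen=True)
class ConsensusLineage:
    votu_id: str
    ranks: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {rank: self.ranks.get(rank, UNCLASSIFIED) for rank in RANKS}
        object.__setattr__(self, "ranks", full)


def filter_calls(calls: Iterable[LineageCall]) -> list[LineageCall]:
    """Drop calls whose score fails the filter for their score kind."""
    return [c for c in calls if _SCORE_FILTERS[c.score_kind](c.score)]


def consensus(
    calls: Iterable[LineageCall], truncate_below_conflict: bool = False
) -> ConsensusLineage:
    """All-agree consensus over one vOTU's filtered calls.

    Ranks are evaluated independently by default.  With
    ``truncate_below_conflict`` every rank below the first unclassified one
    is also forced to unclassified, enforcing lineage consistency.
    """
    calls = list(calls)
    votu_ids = {c.votu_id for c in calls}
    if len(votu_ids) > 1:
        raise AmbiguityError(f"calls span multiple vOTUs: {sorted(votu_ids)}")
    seen = set()
    for c in calls:
        if c.classifier in seen:
            raise AmbiguityError(
                f"classifier {c.classifier} appears twice for {c.votu_id}"
            )
        seen.add(c.classifier)
    votu_id = calls[0].votu_id if calls else ""

    ranks: dict[str, str] = {}
    for rank in RANKS:
        names = {c.ranks[rank] for c in calls if c.ranks.get(rank)}
        ranks[rank] = names.pop() if len(names) == 1 else UNCLASSIFIED
    if truncate_below_conflict:
        blocked = False
        for rank in RANKS:
            if blocked:
                ranks[rank] = UNCLASSIFIED
            elif ranks[rank] == UNCLASSIFIED:
                blocked = True
    return ConsensusLineage(votu_id=votu_id, ranks=ranks)


def consensus_all(
    calls: Iterable[LineageCall], truncate_below_conflict: bool = False
) -> list[ConsensusLineage]:
    """Per-vOTU consensus over a mixed call list, sorted by votu_id."""
    by_votu: dict[str, list[LineageCall]] = defaultdict(list)
    for c in calls:
        by_votu[c.votu_id].append(c)
    return [
        consensus(by_votu[v], truncate_below_conflict=truncate_below_conflict)
        for v in sorted(by_votu)
    ]


def classification_rates(
    consensuses: Iterable[ConsensusLineage],
) -> pd.DataFrame:
    """Fraction of vOTUs with a named (non-unclassified) value per rank."""
    consensuses = list(consensuses)
    if not consensuses:
        return pd.DataFrame(columns=["rank", "n_classified", "percent"])
    n = len(consensuses)
    rows = []
    for rank in RANKS:
        named = sum(1 for c in consensuses if c.ranks[rank] != UNCLASSIFIED)
        rows.append(
            {"rank": rank, "n_classified": named, "percent": 100.0 * named / n}
        )
    return pd.DataFrame(rows, columns=["rank", "n_classified", "percent"])
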