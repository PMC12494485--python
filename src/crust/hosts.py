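"""Virus-host evidence filtering, association typing and AMG curation.

Sequence-match evidence is thresholded at the protocol's cut-offs (protein
matches: identity and query coverage >= 80/80; gene or tRNA matches: 90/90).
Each vOTU's set of linked MAGs is then typed by its host specificity:
"unique" (one MAG), "multiple_family_consensus" (several MAGs, one family),
or "multiple_class_or_higher" (hosts span families or worse).  Auxiliary
metabolic gene calls from the two callers are combined and calls sitting on
the first or last gene of a contig are discarded, since contig termini are
assembly- and prophage-boundary-artefact prone.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import InvalidRecordError, NoAssociationError

__all__ = [
    "MatchRecord",
    "AssociationRecord",
    "AmgCall",
    "ASSOCIATION_TYPES",
    "filter_matches",
    "classify_association",
    "association_spectrum",
    "curate_amgs",
]

ASSOCIATION_TYPES = (
    "unique",
    "multiple_family_consensus",
    "multiple_class_or_higher",
)


@dataclass(frozen=True)
class MatchRecord:
    """One BLAST-style hit between viral and host sequences."""

    query_id: str
    subject_id: str
    pct_identity: float
    query_coverage: float
    bitscore: float
    kind: str  # "protein" | "gene" | "trna"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0 and 0.0 <= self.query_coverage <= 100.0):
            raise InvalidRecordError(
                f"percentages outside [0, 100] on {self.query_id}->{self.subject_id}"
            )
        if self.kind not in ("protein", "gene", "trna"):
            raise InvalidRecordError(f"unknown match kind {self.kind!r}")


@dataclass(frozen=True)
class AssociationRecord:
    """A vOTU -> MAG link with the MAG's taxonomy."""

    votu_id: str
    mag_id: str
    mag_lineage: Mapping[str, str] = field(default_factory=dict)
    source: str = "host_predictor"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mag_lineage", dict(self.mag_lineage))


@dataclass(frozen=True)
class AmgCall:
    """One auxiliary-metabolic-gene call on a vOTU contig."""

    votu_id: str
    gene_index: int  # ordinal CDS position, 1-based
    total_genes: int
    cog_id: str
    categories: str = ""
    callers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 1 <= self.gene_index <= self.total_genes:
            raise InvalidRecordError(
                f"gene_index {self.gene_index} outside 1..{self.total_genes} "
                f"on {self.votu_id}"
            )
        object.__setattr__(self, "callers", frozenset(self.callers))


def filter_matches(records: Iterable[MatchRecord]) -> list[MatchRecord]:
    """Keep hits clearing the per-kind identity/coverage thresholds.

    Protein hits need >= 80% identity and >= 80% query coverage; gene and
    tRNA hits need >= 90/90.
    """
    kept = []
    for r in records:
        if r.kind == "protein":
            ok = r.pct_identity >= 80.0 and r.query_coverage >= 80.0
        else:  # gene / trna
            ok = r.pct_identity >= 90.0 and r.query_coverage >= 90.0
        if ok:
            kept.append(r)
    return kept


def classify_association(
    votu_id: str, linked: Iterable[AssociationRecord]
) -> str:
    """Host-specificity type of one vOTU from its linked MAGs."""
    linked = [r for r in linked if r.votu_id == votu_id]
    if not linked:
        raise NoAssociationError(f"{votu_id} has no linked MAGs")
    by_mag = {r.mag_id: r for r in linked}
    if len(by_mag) == 1:
        return "unique"
    families = {r.mag_lineage.get("family") for r in by_mag.values()}
    if len(families) == 1 and None not in families and "" not in families:
        return "multiple_family_consensus"
    return "multiple_class_or_higher"


def association_spectrum(
    associations: Iterable[AssociationRecord],
) -> pd.DataFrame:
    """Counts and percentages of association types over linked vOTUs.

    Only vOTUs with at least one association contribute; all three types
    appear in the table even at zero count.
    """
    by_votu: dict[str, list[AssociationRecord]] = defaultdict(list)
    for r in associations:
        by_votu[r.votu_id].append(r)
    counts = {t: 0 for t in ASSOCIATION_TYPES}
    for votu_id, linked in by_votu.items():
        counts[classify_association(votu_id, linked)] += 1
    total = sum(counts.values())
    rows = [
        {
            "type": t,
            "n_votus": counts[t],
            "percent": (100.0 * counts[t] / total) if total else 0.0,
        }
        for t in ASSOCIATION_TYPES
    ]
    return pd.DataFrame(rows, columns=["type", "n_votus", "percent"])


def curate_amgs(
    calls: Iterable[AmgCall],
    edge_mode: str = "first_last_gene",
    combine: str = "union",
    end_buffer_bp: int = 500,
    gene_positions: Mapping[tuple[str, int], tuple[int, int]] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[AmgCall]:
    """Combine the two callers' AMG calls and drop contig-end calls.

    Calls are deduplicated by (votu_id, gene_index, cog_id) with caller sets
    merged.  ``combine="union"`` keeps every deduplicated call (default);
    ``"intersection"`` keeps only calls seen by both callers.  Edge removal
    then discards the first and last gene of each contig
    (``edge_mode="first_last_gene"``) or, with ``edge_mode="bp_buffer"``,
    any gene within ``end_buffer_bp`` of a contig terminus (requires
    ``gene_positions`` mapping (votu_id, gene_index) -> (start, end) and
    ``contig_lengths``).
    """
    if edge_mode not in ("first_last_gene", "bp_buffer"):
        raise InvalidRecordError(f"unknown edge_mode {edge_mode!r}")
    if combine not in ("union", "intersection"):
        raise InvalidRecordError(f"unknown combine mode {combine!r}")

    merged: dict[tuple[str, int, str], AmgCall] = {}
    for call in calls:
        key = (call.votu_id, call.gene_index, call.cog_id)
        if key in merged:
            prev = merged[key]
            merged[key] = AmgCall(
                votu_id=prev.votu_id,
                gene_index=prev.gene_index,
                total_genes=prev.total_genes,
                cog_id=prev.cog_id,
                categories=prev.categories or call.categories,
                callers=prev.callers | call.callers,
            )
        else:
            merged[key] = call

    out = []
    for key in sorted(merged):
        call = merged[key]
        if combine == "intersection" and len(call.callers) < 2:
            continue
        if edge_mode == "first_last_gene":
            if call.gene_index == 1 or call.gene_index == call.total_genes:
                continue
        else:
            if gene_positions is None or contig_lengths is None:
                raise InvalidRecordError(
                    "bp_buffer edge mode needs gene_positions and contig_lengths"
                )
            start, end = gene_positions[(call.votu_id, call.gene_index)]
            length = contig_lengths[call.votu_id]
            if start < end_buffer_bp or end > length - end_buffer_bp:
                continue
        out.append(call)
    return out
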