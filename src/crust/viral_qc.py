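"""Decision rules for viral-candidate screening, vOTU retention, MAG quality
tiering and lifestyle assignment.

These are the fixed thresholds the curation protocol applies to the tabular
outputs of the upstream discovery and quality tools (VirSorter2, VIBRANT,
Seeker, DeepVirFinder, CheckV, CheckM2, BACPHLIP).  Boundary semantics are
literal: ``>=`` and ``>`` are exactly as the protocol states them, and an
absent score means the tool did not run on that contig — never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import InvalidRecordError

__all__ = [
    "CandidateScoreRecord",
    "VotuQcRecord",
    "MagQualityRecord",
    "LifestyleCall",
    "screen_candidates",
    "retain_votus",
    "tier_mags",
    "call_lifestyle",
]


@dataclass(frozen=True)
class CandidateScoreRecord:
    """Per-contig scores from the four viral discovery tools."""

    contig_id: str
    length: int
    vs2_score: Optional[float] = None
    dvf_score: Optional[float] = None
    dvf_p: Optional[float] = None
    seeker_score: Optional[float] = None
    vibrant_call: bool = False


@dataclass(frozen=True)
class VotuQcRecord:
    """CheckV/VirSorter2 quality metrics for one vOTU."""

    votu_id: str
    length: int
    viral_genes: int
    host_genes: int
    vs2_score: Optional[float] = None
    hallmark_genes: int = 0

    def __post_init__(self) -> None:
        if self.viral_genes < 0 or self.host_genes < 0 or self.hallmark_genes < 0:
            raise InvalidRecordError(f"negative gene count on {self.votu_id}")


@dataclass(frozen=True)
class MagQualityRecord:
    """Completeness/contamination estimates for one MAG."""

    mag_id: str
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise InvalidRecordError(
                f"completeness outside [0, 100] on {self.mag_id}: {self.completeness}"
            )
        if self.contamination < 0.0:
            raise InvalidRecordError(f"negative contamination on {self.mag_id}")


@dataclass(frozen=True)
class LifestyleCall:
    votu_id: str
    virulent_score: float
    temperate_score: float
    call: str  # "virulent" | "temperate" | "unassigned"


def screen_candidates(
    records: Iterable[CandidateScoreRecord], min_length: int = 5000
) -> list[str]:
    """Contigs accepted as viral candidates.

    A contig passes when it is at least ``min_length`` bases long and at
    least one tool clears its threshold: VirSorter2 score >= 0.7,
    DeepVirFinder score >= 0.9 with P <= 0.05, Seeker score >= 0.9, or a
    positive VIBRANT call.
    """
    passed = []
    for r in records:
        if r.length < min_length:
            continue
        vs2 = r.vs2_score is not None and r.vs2_score >= 0.7
        dvf = (
            r.dvf_score is not None
            and r.dvf_p is not None
            and r.dvf_score >= 0.9
            and r.dvf_p <= 0.05
        )
        seeker = r.seeker_score is not None and r.seeker_score >= 0.9
        if vs2 or dvf or seeker or r.vibrant_call:
            passed.append(r.contig_id)
    return passed


def retain_votus(
    records: Iterable[VotuQcRecord], min_length: int = 5000
) -> list[str]:
    """vOTUs surviving quality curation.

    A vOTU of sufficient length is retained if it meets at least one of:
    it contains a viral gene; it contains neither viral nor host genes; or
    it contains no viral gene but has a VirSorter2 score >= 0.95 or more
    than two hallmark viral genes.
    """
    kept = []
    for r in records:
        if r.length < min_length:
            continue
        has_viral = r.viral_genes >= 1
        clean = r.viral_genes == 0 and r.host_genes == 0
        rescued = r.viral_genes == 0 and (
            (r.vs2_score is not None and r.vs2_score >= 0.95)
            or r.hallmark_genes > 2
        )
        if has_viral or clean or rescued:
            kept.append(r.votu_id)
    return kept


def tier_mags(records: Iterable[MagQualityRecord]) -> pd.DataFrame:
    """Partition MAGs into high / medium / rejected quality tiers.

    High: completeness > 90 and contamination < 5.  Medium: not high,
    completeness >= 50 and contamination < 10.  Everything else is
    rejected.  Every MAG lands in exactly one tier.
    """
    rows = []
    for r in records:
        if r.completeness > 90.0 and r.contamination < 5.0:
            tier = "high"
        elif r.completeness >= 50.0 and r.contamination < 10.0:
            tier = "medium"
        else:
            tier = "rejected"
        rows.append({"mag_id": r.mag_id, "tier": tier})
    return pd.DataFrame(rows, columns=["mag_id", "tier"])


def call_lifestyle(
    scores: Iterable[tuple[str, float, float]], min_score: float = 0.80
) -> list[LifestyleCall]:
    """Assign virulent/temperate lifestyle from classifier score pairs.

    The larger score wins when it reaches ``min_score``; below that the
    annotation is not considered valid and the vOTU stays unassigned.  An
    exact tie at or above the threshold is also unassigned (conservative).
    """
    calls = []
    for votu_id, virulent, temperate in scores:
        if not (0.0 <= virulent <= 1.0 and 0.0 <= temperate <= 1.0):
            raise InvalidRecordError(f"lifestyle scores outside [0, 1] on {votu_id}")
        if virulent > temperate and virulent >= min_score:
            call = "virulent"
        elif temperate > virulent and temperate >= min_score:
            call = "temperate"
        else:
            call = "unassigned"
        calls.append(LifestyleCall(votu_id, virulent, temperate, call))
    return calls
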