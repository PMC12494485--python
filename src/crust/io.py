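"""Readers and writers for the tabular dialects the pipeline consumes.

Alignments come in either as SAM/BAM (via pysam; the NM tag supplies the
edit count) or as a plain TSV with the same fields.  Genome membership,
classifier calls, QC metrics, host predictions, AMG calls and count
matrices are all TSV; coverage goes out as bedGraph and islands as BED6.
GFF3 is ingested through gffutils with 1-based inclusive coordinates
converted to the internal 0-based half-open convention.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotate import CdsFeature
from .coverage import AlignmentRecord, CoverageTrack, GenomeSet
from .errors import InvalidRecordError
from .hosts import AmgCall, AssociationRecord, MatchRecord
from .islands import Island
from .taxonomy import RANKS, LineageCall
from .viral_qc import CandidateScoreRecord, MagQualityRecord, VotuQcRecord

__all__ = [
    "read_alignments_sam",
    "read_alignments_tsv",
    "write_alignments_tsv",
    "read_genomes_tsv",
    "write_genomes_tsv",
    "write_bedgraph",
    "read_bedgraph",
    "write_islands_bed",
    "read_islands_bed",
    "read_gff3_cds",
    "read_emapper_tsv",
    "annotate_features",
    "read_lineage_calls_tsv",
    "read_candidate_records_tsv",
    "read_votu_qc_tsv",
    "read_mag_quality_tsv",
    "read_lifestyle_tsv",
    "read_host_predictions_tsv",
    "read_match_records_tsv",
    "read_amg_calls_tsv",
    "read_counts_tsv",
]

_ALN_COLUMNS = ["query_id", "contig_id", "start", "end", "mismatches", "is_primary"]


def read_alignments_sam(path: str) -> list[AlignmentRecord]:
    """Alignment records from SAM/BAM; NM tag is the mismatch count.

    Unmapped reads are skipped; secondary/supplementary alignments are kept
    but flagged non-primary so the mismatch filter can exclude them.
    """
    mode = "rb" if path.endswith(".bam") else "r"
    records = []
    with pysam.AlignmentFile(path, mode, check_sq=False) as handle:
        for aln in handle.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            records.append(
                AlignmentRecord(
                    query_id=aln.query_name,
                    contig_id=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    mismatches=int(nm),
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                )
            )
    return records


def read_alignments_tsv(path: str) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        AlignmentRecord(
            query_id=str(r.query_id),
            contig_id=str(r.contig_id),
            start=int(r.start),
            end=int(r.end),
            mismatches=int(r.mismatches),
            is_primary=bool(r.is_primary),
        )
        for r in df.itertuples(index=False)
    ]


def write_alignments_tsv(records: Iterable[AlignmentRecord], path: str) -> None:
    df = pd.DataFrame(
        [
            (r.query_id, r.contig_id, r.start, r.end, r.mismatches, r.is_primary)
            for r in records
        ],
        columns=_ALN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_genomes_tsv(path: str) -> list[GenomeSet]:
    """Genome membership table: genome_id, contig_id, length."""
    df = pd.read_csv(path, sep="\t")
    genomes = []
    for gid, grp in df.groupby("genome_id", sort=True):
        contigs = tuple(
            (str(r.contig_id), int(r.length)) for r in grp.itertuples(index=False)
        )
        genomes.append(GenomeSet(genome_id=str(gid), contigs=contigs))
    return genomes


def write_genomes_tsv(genomes: Iterable[GenomeSet], path: str) -> None:
    rows = [
        {"genome_id": g.genome_id, "contig_id": cid, "length": length}
        for g in genomes
        for cid, length in g.contigs
    ]
    pd.DataFrame(rows, columns=["genome_id", "contig_id", "length"]).to_csv(
        path, sep="\t", index=False
    )


def write_bedgraph(tracks: Iterable[CoverageTrack], path: str) -> None:
    """Run-length-encoded per-base depth, one contig after another."""
    with open(path, "w") as handle:
        for track in tracks:
            depth = track.depth
            if len(depth) == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(depth)]))
            for s, e in zip(starts, ends):
                handle.write(f"{track.contig_id}\t{s}\t{e}\t{int(depth[s])}\n")


def read_bedgraph(path: str, contig_lengths: dict[str, int]) -> list[CoverageTrack]:
    """Rebuild full-length depth arrays from a bedGraph file."""
    arrays = {cid: np.zeros(n, dtype=np.int64) for cid, n in contig_lengths.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["contig_id", "start", "end", "depth"]
    )
    for r in df.itertuples(index=False):
        cid = str(r.contig_id)
        if cid not in arrays:
            raise InvalidRecordError(f"bedGraph contig {cid} not in genome table")
        arrays[cid][int(r.start) : int(r.end)] = int(r.depth)
    return [CoverageTrack(cid, arr) for cid, arr in arrays.items()]


def write_islands_bed(islands: Iterable[Island], path: str) -> None:
    """BED6: name = genome_id:regime, score = round(100 x island/genome mean)."""
    with open(path, "w") as handle:
        for isl in islands:
            score = (
                round(100.0 * isl.island_mean / isl.genome_mean)
                if isl.genome_mean > 0
                else 0
            )
            handle.write(
                f"{isl.contig_id}\t{isl.start}\t{isl.end}\t"
                f"{isl.genome_id}:{isl.regime}\t{score}\t.\n"
            )


def read_islands_bed(path: str, genome_means: dict[str, float]) -> list[Island]:
    islands = []
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            contig_id, start, end, name, score, _strand = line.rstrip("\n").split("\t")
            genome_id, regime = name.rsplit(":", 1)
            mean = genome_means.get(genome_id, 0.0)
            islands.append(
                Island(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=int(start),
                    end=int(end),
                    regime=regime,
                    genome_mean=mean,
                    island_mean=int(score) * mean / 100.0,
                    at_contig_edge=False,
                )
            )
    return islands


def read_gff3_cds(path: str) -> list[CdsFeature]:
    """CDS features from GFF3, converted to 0-based half-open coordinates.

    The feature's protein id is taken from the ``ID`` attribute.  eggNOG
    annotation is attached separately via :func:`annotate_features`.
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    features = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        protein_id = feat.attributes.get("ID", [feat.id])[0]
        features.append(
            CdsFeature(
                contig_id=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                protein_id=protein_id,
            )
        )
    return features


def write_gff3_cds(cds: pd.DataFrame, path: str) -> None:
    """Emit CDS rows (0-based half-open) as GFF3 (1-based inclusive)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for r in cds.itertuples(index=False):
            handle.write(
                f"{r.contig_id}\tcrust\tCDS\t{int(r.start) + 1}\t{int(r.end)}\t.\t"
                f"{r.strand}\t0\tID={r.protein_id}\n"
            )


def read_emapper_tsv(path: str) -> pd.DataFrame:
    """emapper-style annotation: protein_id, cog_ids (comma-sep), categories."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return df


def annotate_features(
    features: Sequence[CdsFeature], emapper: pd.DataFrame
) -> list[CdsFeature]:
    """Join eggNOG annotations onto CDS features by protein_id."""
    ann = {
        str(r.protein_id): (str(r.cog_ids), str(r.categories))
        for r in emapper.itertuples(index=False)
    }
    out = []
    for feat in features:
        cogs, cats = ann.get(feat.protein_id, ("", ""))
        cog_ids = tuple(c for c in cogs.split(",") if c)
        out.append(
            CdsFeature(
                contig_id=feat.contig_id,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                protein_id=feat.protein_id,
                cog_ids=cog_ids,
                categories=cats,
            )
        )
    return out


def read_lineage_calls_tsv(path: str, classifier: str | None = None) -> list[LineageCall]:
    """One classifier's calls: votu_id, rank columns, score, score_kind."""
    df = pd.read_csv(path, sep="\t", dtype={"votu_id": str})
    calls = []
    for row in df.to_dict("records"):
        ranks = {
            rank: str(row[rank])
            for rank in RANKS
            if rank in row and pd.notna(row[rank]) and str(row[rank]) != ""
        }
        calls.append(
            LineageCall(
                votu_id=str(row["votu_id"]),
                classifier=classifier or str(row.get("classifier", "")),
                ranks=ranks,
                score=float(row["score"]),
                score_kind=str(row["score_kind"]),
            )
        )
    return calls


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_candidate_records_tsv(path: str) -> list[CandidateScoreRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        CandidateScoreRecord(
            contig_id=str(r.contig_id),
            length=int(r.length),
            vs2_score=_opt(r.vs2_score),
            dvf_score=_opt(r.dvf_score),
            dvf_p=_opt(r.dvf_p),
            seeker_score=_opt(r.seeker_score),
            vibrant_call=bool(r.vibrant_call),
        )
        for r in df.itertuples(index=False)
    ]


def read_votu_qc_tsv(path: str) -> list[VotuQcRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        VotuQcRecord(
            votu_id=str(r.votu_id),
            length=int(r.length),
            viral_genes=int(r.viral_genes),
            host_genes=int(r.host_genes),
            vs2_score=_opt(r.vs2_score),
            hallmark_genes=int(r.hallmark_genes),
        )
        for r in df.itertuples(index=False)
    ]


def read_mag_quality_tsv(path: str) -> list[MagQualityRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        MagQualityRecord(
            mag_id=str(r.mag_id),
            completeness=float(r.completeness),
            contamination=float(r.contamination),
        )
        for r in df.itertuples(index=False)
    ]


def read_lifestyle_tsv(path: str) -> list[tuple[str, float, float]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r.votu_id), float(r.virulent_score), float(r.temperate_score))
        for r in df.itertuples(index=False)
    ]


def read_host_predictions_tsv(path: str) -> list[AssociationRecord]:
    """Host predictions: votu_id, mag_id, lineage columns, source."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    lineage_cols = [c for c in df.columns if c in ("domain",) + RANKS]
    records = []
    for row in df.to_dict("records"):
        lineage = {c: row[c] for c in lineage_cols if row[c]}
        records.append(
            AssociationRecord(
                votu_id=row["votu_id"],
                mag_id=row["mag_id"],
                mag_lineage=lineage,
                source=row.get("source", "host_predictor") or "host_predictor",
            )
        )
    return records


def read_match_records_tsv(path: str) -> list[MatchRecord]:
    """BLAST outfmt-6-like table with a ``kind`` column."""
    df = pd.read_csv(path, sep="\t")
    return [
        MatchRecord(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            pct_identity=float(r.pct_identity),
            query_coverage=float(r.query_coverage),
            bitscore=float(r.bitscore),
            kind=str(r.kind),
        )
        for r in df.itertuples(index=False)
    ]


def read_amg_calls_tsv(path: str, caller: str) -> list[AmgCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        AmgCall(
            votu_id=str(r.votu_id),
            gene_index=int(r.gene_index),
            total_genes=int(r.total_genes),
            cog_id=str(r.cog_id),
            categories=str(getattr(r, "categories", "") or ""),
            callers=frozenset([caller]),
        )
        for r in df.itertuples(index=False)
    ]


def read_counts_tsv(path: str) -> tuple[pd.DataFrame, pd.Series]:
    """idxstats-like wide table: contig_id, length, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("contig_id")
    lengths = df.pop("length")
    return df, lengths


def sha256_file(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
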