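"""TPM abundance: length- and depth-normalized read counts.

Mapped-read counts per contig (idxstats-style) are normalized per sample:
rate_i = count_i / length_i, TPM_i = 10^6 * rate_i / sum(rates).  Every
sample column with any reads therefore sums to exactly one million, making
samples of different sequencing depth directly comparable.  Displayed
abundances use the variance-stabilizing log10(TPM + 1) transform.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidRecordError

__all__ = ["tpm", "log_transform", "aggregate_by_taxon", "pool_counts_by_genome"]


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Per-sample TPM from a contigs x samples count matrix.

    ``lengths`` gives each row's length in bases, indexed like ``counts``.
    Columns whose counts are all zero stay all zero.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise InvalidRecordError(f"rows without a length: {missing[:5]}")
    if (lengths <= 0).any():
        raise InvalidRecordError("all row lengths must be positive")
    if (counts < 0).to_numpy().any():
        raise InvalidRecordError("counts must be non-negative")
    rates = counts.div(lengths, axis=0)
    denom = rates.sum(axis=0)
    # leave all-zero samples all-zero rather than dividing by zero
    denom = denom.replace(0.0, np.nan)
    out = rates.div(denom, axis=1) * 1e6
    return out.fillna(0.0)


def log_transform(tpm_matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10(TPM + 1)."""
    if (tpm_matrix < 0).to_numpy().any():
        raise InvalidRecordError("TPM values must be non-negative")
    return np.log10(tpm_matrix + 1.0)


def aggregate_by_taxon(
    tpm_matrix: pd.DataFrame,
    contig_taxonomy: Mapping[str, str],
    unassigned_label: str = "unclassified",
) -> pd.DataFrame:
    """Sum member-contig TPM per taxon; rows sorted by decreasing mean.

    ``contig_taxonomy`` maps contig id to the taxon name at the rank of
    interest; contigs without an entry fall into ``unassigned_label``.
    Aggregation conserves each sample's column total exactly.
    """
    taxa = pd.Series(
        [contig_taxonomy.get(c, unassigned_label) for c in tpm_matrix.index],
        index=tpm_matrix.index,
    )
    agg = tpm_matrix.groupby(taxa, sort=False).sum()
    order = agg.mean(axis=1).sort_values(ascending=False, kind="stable").index
    return agg.loc[order]


def pool_counts_by_genome(
    counts: pd.DataFrame,
    lengths: pd.Series,
    genome_map: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Pool contig counts and lengths up to genome level.

    Genome-level TPM should be computed from pooled member-contig counts
    over the summed genome length (not by averaging contig TPMs); this
    helper produces the pooled matrix and length vector for :func:`tpm`.
    """
    genomes = pd.Series(
        [genome_map.get(c, c) for c in counts.index], index=counts.index
    )
    pooled = counts.groupby(genomes, sort=True).sum()
    pooled_lengths = lengths.reindex(counts.index).groupby(genomes, sort=True).sum()
    return pooled, pooled_lengths
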