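"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive pure Python (per-base loops,
quadratic all-pairs scans, literal predicate transcriptions) and shares no
code path with the package.
"""

from __future__ import annotations


def brute_coverage(intervals, contig_length):
    """Per-base depth by counting every alignment at every base."""
    depth = [0] * contig_length
    for start, end in intervals:
        for i in range(start, end):
            depth[i] += 1
    return depth


def scan_islands(depth, genome_mean, drop_fraction=0.25, min_len_drop=100,
                 min_len_zero=200, high=5.0, low=2.0):
    """Maximal qualifying runs by a base-at-a-time scan.

    Returns a list of (start, end, regime) tuples, or [] below the low
    regime.  Maximality holds by construction: a run ends exactly when the
    next base fails the predicate (or the contig ends).
    """
    if genome_mean >= high:
        regime = "drop"
        min_len = min_len_drop
        ok = lambda d: d <= (1.0 - drop_fraction) * genome_mean
    elif genome_mean >= low:
        regime = "zero"
        min_len = min_len_zero
        ok = lambda d: d == 0
    else:
        return []
    runs = []
    start = None
    for i, d in enumerate(depth):
        if ok(d):
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_len:
                runs.append((start, i, regime))
            start = None
    if start is not None and len(depth) - start >= min_len:
        runs.append((start, len(depth), regime))
    return runs


def quadratic_overlaps(intervals_a, intervals_b):
    """All (i, j) index pairs whose intervals overlap by >= 1 base."""
    pairs = set()
    for i, (ca, sa, ea) in enumerate(intervals_a):
        for j, (cb, sb, eb) in enumerate(intervals_b):
            if ca == cb and sa < eb and sb < ea:
                pairs.add((i, j))
    return pairs


# --- literal transcriptions of the curation decision rules -----------------

def candidate_passes(length, vs2, dvf, dvf_p, seeker, vibrant, min_length=5000):
    if length < min_length:
        return False
    if vs2 is not None and vs2 >= 0.7:
        return True
    if dvf is not None and dvf_p is not None and dvf >= 0.9 and dvf_p <= 0.05:
        return True
    if seeker is not None and seeker >= 0.9:
        return True
    return bool(vibrant)


def votu_retained(length, viral_genes, host_genes, vs2, hallmark, min_length=5000):
    if length < min_length:
        return False
    if viral_genes >= 1:
        return True
    if viral_genes == 0 and host_genes == 0:
        return True
    if viral_genes == 0 and ((vs2 is not None and vs2 >= 0.95) or hallmark > 2):
        return True
    return False


def mag_tier(completeness, contamination):
    if completeness > 90 and contamination < 5:
        return "high"
    if completeness >= 50 and contamination < 10:
        return "medium"
    return "rejected"


def lineage_call_kept(score_kind, score):
    if score_kind == "bitscore":
        return score >= 50
    if score_kind == "pct_identity":
        return score > 90
    if score_kind == "virus_score":
        return score > 0.7
    raise ValueError(score_kind)


def match_kept(kind, pct_identity, query_coverage):
    if kind == "protein":
        return pct_identity >= 80 and query_coverage >= 80
    return pct_identity >= 90 and query_coverage >= 90


def lifestyle_label(virulent, temperate, min_score=0.80):
    if virulent > temperate and virulent >= min_score:
        return "virulent"
    if temperate > virulent and temperate >= min_score:
        return "temperate"
    return "unassigned"


def consensus_rank(names):
    """All-agree rule on the set of names assigned at one rank."""
    distinct = set(names)
    return distinct.pop() if len(distinct) == 1 else "unclassified"


def curate_amgs_oracle(rows):
    """rows: (votu, gene_index, total_genes, cog, caller) tuples.

    Union + dedupe by (votu, index, cog) with caller merge, then drop
    first/last-gene calls.  Returns {(votu, index, cog): frozenset(callers)}.
    """
    merged = {}
    for votu, idx, total, cog, caller in rows:
        key = (votu, idx, cog)
        merged.setdefault(key, [total, set()])
        merged[key][1].add(caller)
    out = {}
    for (votu, idx, cog), (total, callers) in merged.items():
        if idx == 1 or idx == total:
            continue
        out[(votu, idx, cog)] = frozenset(callers)
    return out
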