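"""Seeded synthetic inputs with planted ground truth for every stage.

The generator emulates pooled-sample read recruitment against a set of
genomes: each contig gets a uniform baseline depth except inside planted
low-coverage islands, where the expected depth is ``baseline x
island_depth_fraction``.  Two read models are provided:

* Poisson mode — read starts are Poisson with rate
  ``target_depth(midpoint) / read_length``, so per-base depth is Poisson
  around a symmetric moving average of the target and island boundaries
  are smoothed over about one read length, centred on the planted edges.  Per-alignment mismatch counts follow the configured mass over
  {0, 1, 2, 3}, and the total rate is scaled by 1 / P(mismatches <= 1) so
  the depth expectation refers to alignments that survive the mismatch
  filter.
* Noiseless mode — each constant-depth region is tiled with exact
  region-spanning zero-mismatch alignments, giving rectangular coverage
  with exact boundaries, for boundary-exact recovery tests.

The table generator produces classifier, QC, host-prediction, AMG and
annotation tables whose agreement with the planted truth is controlled, so
downstream decision rules can be validated against known answers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import AlignmentRecord, GenomeSet
from .errors import ConfigError
from .taxonomy import CLASSIFIERS, RANKS

__all__ = [
    "SimConfig",
    "PlantedIsland",
    "TruthSet",
    "simulate_recruitment",
    "simulate_tables",
    "expected_named_rank_fraction",
    "rank_assign_probs_uniform_depth",
    "evaluate_island_recovery",
]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study.

    Defaults emulate the study conditions: ~10 kb contigs recruited at
    5-30x from four pooled 2x100 bp samples, a couple of planted islands
    per genome at a quarter of baseline depth, and read edit counts
    concentrated on 0-1 mismatches.
    """

    seed: int = 0
    n_genomes: int = 5
    contigs_per_genome: int = 1
    contig_length_range: tuple[int, int] = (8000, 12000)
    mean_depth_range: tuple[float, float] = (8.0, 30.0)
    n_islands_per_genome: int = 2
    island_length_range: tuple[int, int] = (300, 800)
    island_depth_fraction: float = 0.25
    read_length: int = 100
    mismatch_rate: tuple[float, float, float, float] = (0.80, 0.12, 0.06, 0.02)
    n_samples: int = 4
    noiseless: bool = False
    # tabular stages
    n_votus: int = 60
    n_mags: int = 12
    classifier_agreement: float = 0.9
    n_decoy_names: int = 3
    host_link_rate: float = 0.4
    host_multi_family_rate: float = 0.25
    host_multi_class_rate: float = 0.05
    host_decoy_rate: float = 0.0
    amg_votu_rate: float = 0.3

    def __post_init__(self) -> None:
        if abs(sum(self.mismatch_rate) - 1.0) > 1e-9:
            raise ConfigError("mismatch_rate must sum to 1")
        if not 0.0 <= self.island_depth_fraction <= 1.0:
            raise ConfigError("island_depth_fraction must be in [0, 1]")
        if not 0.0 <= self.classifier_agreement <= 1.0:
            raise ConfigError("classifier_agreement must be in [0, 1]")
        lo, hi = self.contig_length_range
        if lo <= 0 or hi < lo:
            raise ConfigError("invalid contig_length_range")
        ilo, ihi = self.island_length_range
        if ilo <= 0 or ihi < ilo:
            raise ConfigError("invalid island_length_range")
        if self.n_islands_per_genome > 0 and ihi > lo:
            raise ConfigError("islands may not be longer than the shortest contig")


@dataclass(frozen=True)
class PlantedIsland:
    genome_id: str
    contig_id: str
    start: int
    end: int
    depth_fraction: float
    baseline: float


@dataclass
class TruthSet:
    """Planted ground truth for recovery tests."""

    islands: list[PlantedIsland] = field(default_factory=list)
    baselines: dict[str, float] = field(default_factory=dict)  # genome -> depth
    lineages: dict[str, dict[str, str]] = field(default_factory=dict)
    hosts: dict[str, frozenset[str]] = field(default_factory=dict)
    mag_lineages: dict[str, dict[str, str]] = field(default_factory=dict)
    amgs: list[tuple[str, int, str]] = field(default_factory=list)
    lifestyles: dict[str, str] = field(default_factory=dict)


def _place_islands(
    rng: np.random.Generator,
    contig_length: int,
    n_islands: int,
    length_range: tuple[int, int],
    margin: int,
    min_gap: int,
) -> list[tuple[int, int]]:
    """Non-overlapping island intervals, >= min_gap apart, away from edges."""
    placed: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < n_islands:
        attempts += 1
        if attempts > 1000:
            raise ConfigError(
                f"cannot place {n_islands} islands of {length_range} on a "
                f"{contig_length} b contig"
            )
        ilen = int(rng.integers(length_range[0], length_range[1] + 1))
        lo, hi = margin, contig_length - margin - ilen
        if hi < lo:
            raise ConfigError("island longer than contig interior")
        start = int(rng.integers(lo, hi + 1))
        end = start + ilen
        if all(start >= e + min_gap or end <= s - min_gap for s, e in placed):
            placed.append((start, end))
    return sorted(placed)


def simulate_recruitment(
    config: SimConfig,
) -> tuple[list[GenomeSet], list[AlignmentRecord], TruthSet]:
    """Genomes, recruited alignments and planted-island truth.

    Identical configs (including seed) produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    p_keep = config.mismatch_rate[0] + config.mismatch_rate[1]
    if not config.noiseless and p_keep <= 0:
        raise ConfigError("mismatch_rate leaves no alignments below the filter")

    genomes: list[GenomeSet] = []
    records: list[AlignmentRecord] = []
    truth = TruthSet()
    read_counter = itertools.count()

    for g in range(config.n_genomes):
        genome_id = f"G{g + 1:03d}"
        baseline = float(
            rng.uniform(config.mean_depth_range[0], config.mean_depth_range[1])
        )
        truth.baselines[genome_id] = baseline
        contigs = []
        for c in range(config.contigs_per_genome):
            contig_id = f"{genome_id}_c{c + 1}"
            length = int(
                rng.integers(
                    config.contig_length_range[0], config.contig_length_range[1] + 1
                )
            )
            contigs.append((contig_id, length))
            islands = (
                _place_islands(
                    rng,
                    length,
                    config.n_islands_per_genome,
                    config.island_length_range,
                    margin=2 * config.read_length,
                    min_gap=2 * config.read_length + 100,
                )
                if config.n_islands_per_genome > 0
                else []
            )
            for start, end in islands:
                truth.islands.append(
                    PlantedIsland(
                        genome_id=genome_id,
                        contig_id=contig_id,
                        start=start,
                        end=end,
                        depth_fraction=config.island_depth_fraction,
                        baseline=baseline,
                    )
                )
            # target post-filter depth along the contig
            target = np.full(length, baseline)
            for start, end in islands:
                target[start:end] = baseline * config.island_depth_fraction

            if config.noiseless:
                records.extend(
                    _tile_regions(contig_id, target, read_counter)
                )
            else:
                records.extend(
                    _poisson_reads(
                        rng, contig_id, target, config, p_keep, read_counter
                    )
                )
        genomes.append(GenomeSet(genome_id=genome_id, contigs=tuple(contigs)))
    return genomes, records, truth


def _tile_regions(
    contig_id: str, target: np.ndarray, counter
) -> list[AlignmentRecord]:
    """Exact rectangular coverage: depth copies of region-spanning reads."""
    records = []
    change = np.flatnonzero(np.diff(target)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(target)]))
    for s, e in zip(starts, ends):
        depth = int(round(float(target[s])))
        for _ in range(depth):
            records.append(
                AlignmentRecord(
                    query_id=f"r{next(counter)}",
                    contig_id=contig_id,
                    start=int(s),
                    end=int(e),
                    mismatches=0,
                )
            )
    return records


def _poisson_reads(
    rng: np.random.Generator,
    contig_id: str,
    target: np.ndarray,
    config: SimConfig,
    p_keep: float,
    counter,
) -> list[AlignmentRecord]:
    length = len(target)
    rl = min(config.read_length, length)
    n_starts = length - rl + 1
    # rate anchored at the read midpoint, so expected post-filter depth is a
    # symmetric moving average of the target (boundary smoothing centred on
    # the planted edges rather than lagging them)
    centers = np.arange(n_starts) + rl // 2
    rates = target[centers] / rl / p_keep
    counts = rng.poisson(rates)
    starts = np.repeat(np.arange(n_starts), counts)
    mismatches = rng.choice(4, size=len(starts), p=np.asarray(config.mismatch_rate))
    records = []
    for s, nm in zip(starts, mismatches):
        records.append(
            AlignmentRecord(
                query_id=f"r{next(counter)}",
                contig_id=contig_id,
                start=int(s),
                end=int(s) + rl,
                mismatches=int(nm),
            )
        )
    return records


# ---------------------------------------------------------------------------
# tabular stages
# ---------------------------------------------------------------------------

_SCORE_KIND = {
    "aln_protein": "bitscore",
    "aln_gene": "pct_identity",
    "profile_search": "bitscore",
    "composite_scorer": "virus_score",
}
_PASSING_SCORE = {"bitscore": 120.0, "pct_identity": 96.0, "virus_score": 0.9}

# small in-silico COG pool with realistic categories (integration,
# recombination, transposition, transport — the classes enriched in islands)
_COG_POOL = (
    ("COG0582", "L"), ("COG0438", "M"), ("COG1961", "L"), ("COG4974", "L"),
    ("COG1629", "P"), ("COG0457", "S"), ("COG2801", "L"), ("COG0477", "EGP"),
    ("COG3385", "L"), ("COG4771", "P"), ("COG0286", "V"), ("COG3335", "L"),
    ("COG0642", "T"), ("COG1028", "IQ"), ("COG3209", "M"), ("COG1215", "M"),
    ("COG0553", "L"), ("COG2205", "T"), ("COG1192", "D"), ("COG0451", "GM"),
    ("COG0270", "L"), ("COG0209", "F"), ("COG0208", "F"), ("COG5410", "K"),
)


def simulate_tables(
    config: SimConfig,
    truth: TruthSet,
    genomes: Sequence[GenomeSet] | None = None,
) -> dict[str, pd.DataFrame]:
    """Classifier, QC, host, AMG, annotation and count tables with truth.

    Mutates ``truth`` in place (lineages, hosts, AMGs, lifestyles) and
    returns the tables keyed by name.  When ``genomes`` (from
    :func:`simulate_recruitment`) are supplied, CDS/emapper annotation
    tables covering their contigs are generated as well.  All randomness
    descends from ``config.seed`` so output is reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    tables: dict[str, pd.DataFrame] = {}

    votu_ids = [f"vOTU{i + 1:04d}" for i in range(config.n_votus)]
    mag_ids = [f"Ice{i + 1}" for i in range(config.n_mags)]

    # --- MAG taxonomy: families grouped under classes, >= 2 MAGs per family
    n_families = max(2, config.n_mags // 3)
    fam_class = {
        f"family_f{j}": f"class_c{j % max(2, n_families // 2)}"
        for j in range(n_families)
    }
    families = list(fam_class)
    for i, mag in enumerate(mag_ids):
        fam = families[i % n_families]
        truth.mag_lineages[mag] = {
            "domain": "Bacteria",
            "phylum": "phylum_p0",
            "class": fam_class[fam],
            "family": fam,
            "genus": f"genus_{mag}",
            "species": f"species_{mag}",
        }

    # --- viral lineages (prefix-consistent: one true path index per vOTU)
    for votu in votu_ids:
        path = int(rng.integers(0, 4))
        truth.lineages[votu] = {rank: f"{rank}_true{path}" for rank in RANKS}

    # --- classifier tables: per-classifier random assignment depth (prefix),
    #     per-rank agreement errors
    a = config.classifier_agreement
    m = config.n_decoy_names
    rows_by_classifier: dict[str, list[dict]] = {c: [] for c in CLASSIFIERS}
    for votu in votu_ids:
        for classifier in CLASSIFIERS:
            depth = int(rng.integers(0, len(RANKS) + 1))  # 0 = assigns nothing
            row: dict[str, object] = {"votu_id": votu}
            for i, rank in enumerate(RANKS):
                if i >= depth:
                    row[rank] = ""
                    continue
                if rng.random() < a:
                    row[rank] = truth.lineages[votu][rank]
                else:
                    row[rank] = f"{rank}_decoy{int(rng.integers(0, m))}"
            kind = _SCORE_KIND[classifier]
            row["score"] = _PASSING_SCORE[kind]
            row["score_kind"] = kind
            rows_by_classifier[classifier].append(row)
    for classifier, rows in rows_by_classifier.items():
        tables[f"taxonomy_{classifier}"] = pd.DataFrame(
            rows, columns=["votu_id", *RANKS, "score", "score_kind"]
        )

    # --- host predictions
    fam_members: dict[str, list[str]] = {}
    for mag, lin in truth.mag_lineages.items():
        fam_members.setdefault(lin["family"], []).append(mag)
    multi_fams = [f for f, ms in fam_members.items() if len(ms) >= 2]
    host_rows = []
    for votu in votu_ids:
        if rng.random() >= config.host_link_rate:
            continue
        u = rng.random()
        if u < config.host_multi_class_rate and n_families >= 2:
            # two MAGs from families in different classes
            f1 = families[0]
            f2 = next(f for f in families if fam_class[f] != fam_class[f1])
            hosts = [fam_members[f1][0], fam_members[f2][0]]
        elif u < config.host_multi_class_rate + config.host_multi_family_rate and multi_fams:
            fam = multi_fams[int(rng.integers(0, len(multi_fams)))]
            members = fam_members[fam]
            k = min(len(members), 2 + int(rng.integers(0, 2)))
            hosts = list(rng.choice(members, size=k, replace=False))
        else:
            hosts = [mag_ids[int(rng.integers(0, len(mag_ids)))]]
        truth.hosts[votu] = frozenset(hosts)
        for mag in sorted(hosts):
            lin = truth.mag_lineages[mag]
            host_rows.append(
                {"votu_id": votu, "mag_id": mag, **lin, "source": "host_predictor"}
            )
        if rng.random() < config.host_decoy_rate:
            decoy = mag_ids[int(rng.integers(0, len(mag_ids)))]
            lin = truth.mag_lineages[decoy]
            host_rows.append(
                {"votu_id": votu, "mag_id": decoy, **lin, "source": "decoy"}
            )
    tables["host_predictions"] = pd.DataFrame(
        host_rows,
        columns=["votu_id", "mag_id", "domain", "phylum", "class", "family",
                 "genus", "species", "source"],
    )

    # --- QC tables
    cand_rows, votu_rows, life_rows = [], [], []
    for votu in votu_ids:
        length = int(rng.integers(4000, 60000))
        vs2 = float(np.round(rng.uniform(0.3, 1.0), 3))
        dvf = float(np.round(rng.uniform(0.5, 1.0), 3))
        cand_rows.append(
            {
                "contig_id": votu,
                "length": length,
                "vs2_score": vs2,
                "dvf_score": dvf,
                "dvf_p": float(np.round(rng.uniform(0.0, 0.2), 3)),
                "seeker_score": float(np.round(rng.uniform(0.5, 1.0), 3)),
                "vibrant_call": bool(rng.random() < 0.3),
            }
        )
        votu_rows.append(
            {
                "votu_id": votu,
                "length": length,
                "viral_genes": int(rng.poisson(2.0)),
                "host_genes": int(rng.poisson(0.5)),
                "vs2_score": vs2,
                "hallmark_genes": int(rng.poisson(1.0)),
            }
        )
        lifestyle = "virulent" if rng.random() < 0.9 else "temperate"
        truth.lifestyles[votu] = lifestyle
        win = float(np.round(rng.uniform(0.5, 1.0), 3))
        virulent = win if lifestyle == "virulent" else float(np.round(1 - win, 3))
        life_rows.append(
            {
                "votu_id": votu,
                "virulent_score": virulent,
                "temperate_score": float(np.round(1 - virulent, 3)),
            }
        )
    tables["qc_candidates"] = pd.DataFrame(cand_rows)
    tables["qc_votus"] = pd.DataFrame(votu_rows)
    tables["qc_lifestyle"] = pd.DataFrame(life_rows)
    tables["qc_mags"] = pd.DataFrame(
        [
            {
                "mag_id": mag,
                "completeness": float(np.round(rng.uniform(40.0, 100.0), 2)),
                "contamination": float(np.round(rng.exponential(3.0), 2)),
            }
            for mag in mag_ids
        ]
    )

    # --- AMG tables: interior truths plus planted end-located decoys
    amg_a, amg_b = [], []
    for votu in votu_ids:
        if rng.random() >= config.amg_votu_rate:
            continue
        total_genes = int(rng.integers(8, 30))
        n_true = 1 + int(rng.integers(0, 2))
        interior = rng.choice(
            np.arange(2, total_genes), size=min(n_true, total_genes - 2), replace=False
        )
        for idx in sorted(int(i) for i in interior):
            cog, cats = _COG_POOL[int(rng.integers(0, len(_COG_POOL)))]
            truth.amgs.append((votu, idx, cog))
            row = {
                "votu_id": votu, "gene_index": idx, "total_genes": total_genes,
                "cog_id": cog, "categories": cats,
            }
            # each caller sees the AMG independently; union recovers all
            seen_a = rng.random() < 0.8
            seen_b = rng.random() < 0.8
            if not (seen_a or seen_b):
                seen_a = True
            if seen_a:
                amg_a.append(row)
            if seen_b:
                amg_b.append(row)
        # end-located decoys that curation must remove
        for idx in (1, total_genes):
            cog, cats = _COG_POOL[int(rng.integers(0, len(_COG_POOL)))]
            row = {
                "votu_id": votu, "gene_index": idx, "total_genes": total_genes,
                "cog_id": cog, "categories": cats,
            }
            (amg_a if rng.random() < 0.5 else amg_b).append(row)
    cols = ["votu_id", "gene_index", "total_genes", "cog_id", "categories"]
    tables["amg_caller_a"] = pd.DataFrame(amg_a, columns=cols)
    tables["amg_caller_b"] = pd.DataFrame(amg_b, columns=cols)

    # --- CDS annotation (GFF3-shaped table) + emapper join for the genomes
    cds_rows, emapper_rows = [], []
    if genomes:
        for genome in genomes:
            for contig_id, length in genome.contigs:
                pos, k = 0, 0
                while pos + 300 <= length:
                    gene_len = 600 + 300 * int(rng.integers(0, 3))
                    end = min(pos + gene_len, length)
                    protein_id = f"{contig_id}_p{k + 1}"
                    n_cogs = 1 + int(rng.random() < 0.25)
                    picks = [
                        _COG_POOL[int(rng.integers(0, len(_COG_POOL)))]
                        for _ in range(n_cogs)
                    ]
                    cds_rows.append(
                        {
                            "contig_id": contig_id,
                            "start": pos,
                            "end": end,
                            "strand": "+" if rng.random() < 0.5 else "-",
                            "protein_id": protein_id,
                        }
                    )
                    emapper_rows.append(
                        {
                            "protein_id": protein_id,
                            "cog_ids": ",".join(c for c, _ in picks),
                            "categories": "".join(cat for _, cat in picks),
                        }
                    )
                    pos = end + 100
                    k += 1
    tables["cds"] = pd.DataFrame(
        cds_rows, columns=["contig_id", "start", "end", "strand", "protein_id"]
    )
    tables["emapper"] = pd.DataFrame(
        emapper_rows, columns=["protein_id", "cog_ids", "categories"]
    )

    # --- per-sample counts (idxstats-like wide matrix) over vOTUs
    count_rows = []
    sample_depth = rng.uniform(0.5, 2.0, size=config.n_samples)
    for votu, qc in zip(votu_ids, votu_rows):
        length = qc["length"]
        abundance = rng.lognormal(0.0, 1.0)
        row = {"contig_id": votu, "length": length}
        for s in range(config.n_samples):
            lam = abundance * sample_depth[s] * length / 1000.0
            row[f"S{s + 1}"] = int(rng.poisson(lam))
        count_rows.append(row)
    tables["counts"] = pd.DataFrame(count_rows)

    return tables


def evaluate_island_recovery(detected, truth_islands):
    """Recall, precision and boundary errors of detected vs planted islands.

    A planted island is recovered when any detected island overlaps it; the
    best-overlapping call supplies the two absolute boundary errors (start
    and end, in bases).  Precision is the fraction of detected islands that
    overlap any planted one.  Returns a dict with ``recall``, ``precision``
    and the flat ``boundary_errors`` list.
    """
    by_contig: dict[str, list] = {}
    for d in detected:
        by_contig.setdefault(d.contig_id, []).append(d)

    matched_truth = 0
    boundary_errors: list[int] = []
    for t in truth_islands:
        hits = [
            d for d in by_contig.get(t.contig_id, [])
            if d.start < t.end and t.start < d.end
        ]
        if hits:
            matched_truth += 1
            best = max(
                hits, key=lambda d: min(d.end, t.end) - max(d.start, t.start)
            )
            boundary_errors.append(abs(best.start - t.start))
            boundary_errors.append(abs(best.end - t.end))
    truth_by_contig: dict[str, list] = {}
    for t in truth_islands:
        truth_by_contig.setdefault(t.contig_id, []).append(t)
    matched_det = sum(
        1
        for d in detected
        if any(
            d.start < t.end and t.start < d.end
            for t in truth_by_contig.get(d.contig_id, [])
        )
    )
    recall = matched_truth / len(truth_islands) if truth_islands else float("nan")
    precision = matched_det / len(detected) if detected else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "boundary_errors": boundary_errors,
    }


def expected_named_rank_fraction(
    n_classifiers: int,
    agreement: float,
    n_decoys: int,
    rank_assign_probs: Sequence[float],
) -> float:
    """Closed-form probability that a rank gets a named consensus.

    Enumerates the number ``k`` of classifiers assigning at a rank
    (binomial with the rank's assignment probability).  Given ``k >= 1``
    assigners, the consensus is named when all agree: either all pick the
    true name (``a^k``) or all pick the same decoy out of ``m``
    (``(1-a)^k / m^(k-1)``).  Returns the mean over ranks, i.e. the
    expected fraction of named (rank, vOTU) cells.
    """
    a, m, n = agreement, n_decoys, n_classifiers
    per_rank = []
    for q in rank_assign_probs:
        p_named = 0.0
        for k in range(1, n + 1):
            p_k = math.comb(n, k) * q**k * (1 - q) ** (n - k)
            p_agree = a**k + ((1 - a) ** k) / (m ** (k - 1)) if m > 0 else a**k
            p_named += p_k * p_agree
        per_rank.append(p_named)
    return float(np.mean(per_rank))


def rank_assign_probs_uniform_depth(n_ranks: int = len(RANKS)) -> list[float]:
    """Assignment probability per rank under the uniform prefix-depth model.

    Depth is uniform over {0, ..., n_ranks}; rank i (0-based) is assigned
    iff depth > i, so P = (n_ranks - i) / (n_ranks + 1).
    """
    return [(n_ranks - i) / (n_ranks + 1) for i in range(n_ranks)]
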