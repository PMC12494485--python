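"""Synthetic-data generator: determinism, planted depth, truth consistency."""

import numpy as np
import pytest

from crust.coverage import compute_coverage, filter_alignments, genome_mean_coverage
from crust.errors import ConfigError
from crust.simulate import (
    SimConfig,
    expected_named_rank_fraction,
    rank_assign_probs_uniform_depth,
    simulate_recruitment,
    simulate_tables,
)
from crust.taxonomy import RANKS, UNCLASSIFIED, consensus_all, filter_calls
from crust.io import read_lineage_calls_tsv  # noqa: F401  (format shared with tables)


def lineage_calls_from_tables(tables):
    from crust.taxonomy import LineageCall

    calls = []
    for name, df in tables.items():
        if not name.startswith("taxonomy_"):
            continue
        classifier = name.removeprefix("taxonomy_")
        for row in df.to_dict("records"):
            ranks = {r: row[r] for r in RANKS if row[r]}
            calls.append(
                LineageCall(row["votu_id"], classifier, ranks,
                            row["score"], row["score_kind"])
            )
    return calls


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        cfg = SimConfig(seed=7, n_genomes=2)
        g1, r1, t1 = simulate_recruitment(cfg)
        g2, r2, t2 = simulate_recruitment(cfg)
        assert g1 == g2
        assert r1 == r2
        assert t1.islands == t2.islands

    def test_different_seeds_differ(self):
        _, r1, _ = simulate_recruitment(SimConfig(seed=1, n_genomes=1))
        _, r2, _ = simulate_recruitment(SimConfig(seed=2, n_genomes=1))
        assert r1 != r2

    def test_tables_deterministic(self):
        cfg = SimConfig(seed=3, n_genomes=1, n_votus=20)
        _, _, t1 = simulate_recruitment(cfg)
        _, _, t2 = simulate_recruitment(cfg)
        tables1 = simulate_tables(cfg, t1)
        tables2 = simulate_tables(cfg, t2)
        for name in tables1:
            assert tables1[name].equals(tables2[name]), name


class TestNoiselessMode:
    def test_planted_regions_exactly_at_fraction(self):
        cfg = SimConfig(
            seed=5, n_genomes=2, noiseless=True,
            mean_depth_range=(20.0, 20.0), island_depth_fraction=0.0,
        )
        genomes, records, truth = simulate_recruitment(cfg)
        for genome in genomes:
            recs = [r for r in records
                    if r.contig_id in {c for c, _ in genome.contigs}]
            tracks = {t.contig_id: t for t in compute_coverage(recs, genome)}
            for isl in truth.islands:
                if isl.genome_id != genome.genome_id:
                    continue
                depth = tracks[isl.contig_id].depth
                assert (depth[isl.start:isl.end] == 0).all()
                # flanks sit exactly at baseline
                assert depth[isl.start - 1] == 20
                assert depth[isl.end] == 20

    def test_all_reads_zero_mismatch(self):
        _, records, _ = simulate_recruitment(
            SimConfig(seed=5, n_genomes=1, noiseless=True)
        )
        assert all(r.mismatches == 0 for r in records)


class TestPoissonMode:
    def test_mean_depth_within_three_standard_errors(self):
        cfg = SimConfig(
            seed=11, n_genomes=1, contig_length_range=(10000, 10000),
            mean_depth_range=(20.0, 20.0), island_depth_fraction=0.5,
            n_islands_per_genome=2, island_length_range=(500, 500),
        )
        genomes, records, truth = simulate_recruitment(cfg)
        retained = filter_alignments(records)
        tracks = compute_coverage(retained, genomes[0])
        depth = tracks[0].depth
        inside = np.zeros(len(depth), dtype=bool)
        margin = cfg.read_length
        for isl in truth.islands:
            inside[isl.start:isl.end] = True
        # exclude read-length transition zones and contig-edge ramps
        core_out = ~inside.copy()
        for isl in truth.islands:
            core_out[max(0, isl.start - margin):isl.end + margin] = False
        core_out[:margin] = core_out[-margin:] = False
        core_in = inside.copy()
        for isl in truth.islands:
            core_in[isl.start:isl.start + margin] = False
            core_in[isl.end - margin:isl.end] = False

        for mask, target in ((core_out, 20.0), (core_in, 10.0)):
            observed = depth[mask].mean()
            # neighbouring bases share reads: ~n/read_length independent draws
            n_eff = mask.sum() / cfg.read_length
            se = np.sqrt(target / n_eff)
            assert abs(observed - target) <= 3 * se

    def test_mismatch_filter_preserves_target_depth(self):
        cfg = SimConfig(
            seed=13, n_genomes=1, contig_length_range=(20000, 20000),
            mean_depth_range=(20.0, 20.0), n_islands_per_genome=0,
        )
        genomes, records, _ = simulate_recruitment(cfg)
        retained = filter_alignments(records)
        mean = genome_mean_coverage(compute_coverage(retained, genomes[0]), genomes[0])
        assert mean == pytest.approx(20.0, rel=0.05)

    def test_mismatch_counts_follow_configured_mass(self):
        cfg = SimConfig(seed=17, n_genomes=1, contig_length_range=(20000, 20000),
                        mean_depth_range=(30.0, 30.0), n_islands_per_genome=0)
        _, records, _ = simulate_recruitment(cfg)
        observed = np.bincount([r.mismatches for r in records], minlength=4)
        freq = observed / observed.sum()
        assert np.allclose(freq, cfg.mismatch_rate, atol=0.02)

    def test_island_longer_than_contig_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(contig_length_range=(1000, 1000),
                      island_length_range=(1500, 1500))


class TestTables:
    def test_full_agreement_recovers_every_lineage(self):
        cfg = SimConfig(seed=23, n_votus=40, classifier_agreement=1.0)
        _, _, truth = simulate_recruitment(SimConfig(seed=23, n_genomes=0))
        tables = simulate_tables(cfg, truth)
        calls = filter_calls(lineage_calls_from_tables(tables))
        for cons in consensus_all(calls):
            assigned = {
                rank for c in calls if c.votu_id == cons.votu_id for rank in c.ranks
            }
            for rank in assigned:
                assert cons.ranks[rank] == truth.lineages[cons.votu_id][rank]

    def test_zero_agreement_with_conflicts_unclassifies(self):
        cfg = SimConfig(seed=29, n_votus=60, classifier_agreement=0.0,
                        n_decoy_names=8)
        _, _, truth = simulate_recruitment(SimConfig(seed=29, n_genomes=0))
        tables = simulate_tables(cfg, truth)
        calls = filter_calls(lineage_calls_from_tables(tables))
        from collections import defaultdict

        by_votu = defaultdict(list)
        for c in calls:
            by_votu[c.votu_id].append(c)
        for cons in consensus_all(calls):
            for rank in RANKS:
                names = {c.ranks[rank] for c in by_votu[cons.votu_id]
                         if rank in c.ranks}
                if len(names) >= 2:
                    assert cons.ranks[rank] == UNCLASSIFIED

    def test_host_truth_consistent_with_predictions(self):
        cfg = SimConfig(seed=31, n_votus=50)
        _, _, truth = simulate_recruitment(SimConfig(seed=31, n_genomes=0))
        tables = simulate_tables(cfg, truth)
        hosts = tables["host_predictions"]
        predicted = hosts[hosts.source == "host_predictor"]
        for votu, mags in truth.hosts.items():
            assert set(predicted[predicted.votu_id == votu].mag_id) == set(mags)

    def test_amg_truth_interior_and_decoys_terminal(self):
        cfg = SimConfig(seed=37, n_votus=50, amg_votu_rate=0.8)
        _, _, truth = simulate_recruitment(SimConfig(seed=37, n_genomes=0))
        tables = simulate_tables(cfg, truth)
        truth_keys = {(v, i) for v, i, _ in truth.amgs}
        import pandas as pd

        both = pd.concat([tables["amg_caller_a"], tables["amg_caller_b"]])
        totals = dict(
            both[["votu_id", "total_genes"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        for votu, idx in truth_keys:
            assert 1 < idx < totals[votu]
        planted_end = 0
        for name in ("amg_caller_a", "amg_caller_b"):
            for row in tables[name].to_dict("records"):
                if (row["votu_id"], row["gene_index"]) not in truth_keys:
                    assert row["gene_index"] in (1, row["total_genes"])
                    planted_end += 1
        assert planted_end > 0


class TestClosedFormAgreement:
    def test_enumeration_matches_monte_carlo(self, rng):
        """Closed-form named-rank probability vs direct simulation."""
        a, m, n = 0.85, 3, 4
        q = 0.6
        trials = 20000
        named = 0
        for _ in range(trials):
            k = rng.binomial(n, q)
            if k == 0:
                continue
            names = []
            for _ in range(k):
                if rng.random() < a:
                    names.append("true")
                else:
                    names.append(f"d{int(rng.integers(0, m))}")
            if len(set(names)) == 1:
                named += 1
        expected = expected_named_rank_fraction(n, a, m, [q])
        se = np.sqrt(expected * (1 - expected) / trials)
        assert abs(named / trials - expected) <= 4 * se

    def test_assign_probs_decrease_with_rank_depth(self):
        probs = rank_assign_probs_uniform_depth()
        assert len(probs) == len(RANKS)
        assert all(p1 > p2 for p1, p2 in zip(probs, probs[1:]))
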