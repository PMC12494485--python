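"""Match filtering, host-specificity typing and AMG curation."""

import pytest

from crust.errors import InvalidRecordError, NoAssociationError
from crust.hosts import (
    AmgCall,
    AssociationRecord,
    MatchRecord,
    association_spectrum,
    classify_association,
    curate_amgs,
    filter_matches,
)

from _oracles import curate_amgs_oracle, match_kept


def match(kind, identity, coverage):
    return MatchRecord("q", "s", identity, coverage, 100.0, kind)


def assoc(votu, mag, family="F", klass="C"):
    return AssociationRecord(votu, mag, {"family": family, "class": klass})


class TestFilterMatches:
    @pytest.mark.parametrize(
        "kind,identity,coverage,kept",
        [
            ("protein", 85, 82, True),
            ("protein", 85, 70, False),
            ("protein", 80, 80, True),   # inclusive boundary
            ("protein", 79.9, 80, False),
            ("gene", 91, 95, True),
            ("gene", 89, 95, False),
            ("gene", 90, 90, True),
            ("trna", 90, 89.9, False),
        ],
    )
    def test_thresholds(self, kind, identity, coverage, kept):
        assert (len(filter_matches([match(kind, identity, coverage)])) == 1) == kept
        assert kept == match_kept(kind, identity, coverage)

    def test_random_records_match_oracle(self, rng):
        records = [
            match(
                ["protein", "gene", "trna"][int(rng.integers(0, 3))],
                float(rng.uniform(60, 100)),
                float(rng.uniform(60, 100)),
            )
            for _ in range(300)
        ]
        kept = filter_matches(records)
        expected = [r for r in records if match_kept(r.kind, r.pct_identity, r.query_coverage)]
        assert kept == expected


class TestClassifyAssociation:
    def test_unique(self):
        assert classify_association("v1", [assoc("v1", "Ice1")]) == "unique"

    def test_repeated_same_mag_still_unique(self):
        linked = [assoc("v1", "Ice1"), assoc("v1", "Ice1")]
        assert classify_association("v1", linked) == "unique"

    def test_family_consensus(self):
        linked = [
            assoc("v1", "Ice1", family="Hymenobacteraceae"),
            assoc("v1", "Ice2", family="Hymenobacteraceae"),
            assoc("v1", "Ice3", family="Hymenobacteraceae"),
        ]
        assert classify_association("v1", linked) == "multiple_family_consensus"

    def test_cross_class(self):
        linked = [
            assoc("v1", "Ice1", family="F1", klass="C1"),
            assoc("v1", "Ice2", family="F2", klass="C2"),
        ]
        assert classify_association("v1", linked) == "multiple_class_or_higher"

    def test_missing_family_falls_through(self):
        linked = [
            AssociationRecord("v1", "Ice1", {}),
            AssociationRecord("v1", "Ice2", {}),
        ]
        assert classify_association("v1", linked) == "multiple_class_or_higher"

    def test_empty_rejected(self):
        with pytest.raises(NoAssociationError):
            classify_association("v1", [])

    def test_permutation_invariant_and_cardinality(self, rng):
        mags = [f"Ice{i}" for i in range(5)]
        for _ in range(50):
            chosen = [mags[int(rng.integers(0, 5))] for _ in range(4)]
            linked = [assoc("v1", m, family=f"F_{m}") for m in chosen]
            perm = [linked[i] for i in rng.permutation(4)]
            assert classify_association("v1", linked) == classify_association("v1", perm)
            if len(set(chosen)) == 1:
                assert classify_association("v1", linked) == "unique"


class TestAssociationSpectrum:
    def test_percentages(self):
        records = (
            [assoc("v1", "Ice1"), assoc("v2", "Ice2")]
            + [assoc("v3", "Ice1", family="F"), assoc("v3", "Ice2", family="F")]
            + [assoc("v4", "Ice1", klass="C1"), assoc("v4", "Ice3", family="G", klass="C2")]
        )
        table = association_spectrum(records).set_index("type")
        assert table.loc["unique", "percent"] == pytest.approx(50.0)
        assert table.loc["multiple_family_consensus", "percent"] == pytest.approx(25.0)
        assert table.loc["multiple_class_or_higher", "percent"] == pytest.approx(25.0)

    def test_all_unique(self):
        records = [assoc(f"v{i}", "Ice1") for i in range(5)]
        table = association_spectrum(records).set_index("type")
        assert table.loc["unique", "percent"] == pytest.approx(100.0)
        assert table.loc["multiple_family_consensus", "n_votus"] == 0

    def test_counts_match_recount(self, rng):
        records = []
        for i in range(60):
            n_mags = 1 + int(rng.integers(0, 3))
            for m in range(n_mags):
                records.append(
                    assoc(f"v{i}", f"Ice{m}", family=f"F{int(rng.integers(0, 2))}")
                )
        table = association_spectrum(records)
        assert table["n_votus"].sum() == 60
        assert table["percent"].sum() == pytest.approx(100.0)


def amg(votu, idx, total, cog="COG0001", callers=("caller_a",)):
    return AmgCall(votu, idx, total, cog, callers=frozenset(callers))


class TestCurateAmgs:
    def test_first_gene_removed(self):
        assert curate_amgs([amg("v1", 1, 10)]) == []

    def test_last_gene_removed(self):
        assert curate_amgs([amg("v1", 10, 10)]) == []

    def test_interior_kept(self):
        kept = curate_amgs([amg("v1", 5, 10)])
        assert [(c.votu_id, c.gene_index) for c in kept] == [("v1", 5)]

    def test_duplicate_callers_merged(self):
        calls = [
            amg("v1", 5, 10, callers=("caller_a",)),
            amg("v1", 5, 10, callers=("caller_b",)),
        ]
        merged = curate_amgs(calls)
        assert len(merged) == 1
        assert merged[0].callers == {"caller_a", "caller_b"}

    def test_union_idempotent(self):
        calls = [amg("v1", 5, 10), amg("v1", 5, 10), amg("v2", 3, 8)]
        once = curate_amgs(calls)
        assert curate_amgs(once) == once

    def test_intersection_mode(self):
        calls = [
            amg("v1", 5, 10, callers=("caller_a",)),
            amg("v1", 5, 10, callers=("caller_b",)),
            amg("v2", 4, 8, callers=("caller_a",)),
        ]
        both = curate_amgs(calls, combine="intersection")
        assert [(c.votu_id, c.gene_index) for c in both] == [("v1", 5)]

    def test_never_contains_terminal_genes(self, rng):
        calls = [
            amg(f"v{int(rng.integers(0, 5))}", int(rng.integers(1, 11)), 10)
            for _ in range(100)
        ]
        for c in curate_amgs(calls):
            assert 1 < c.gene_index < c.total_genes

    def test_random_sets_match_brute_force(self, rng):
        rows = []
        for _ in range(200):
            votu = f"v{int(rng.integers(0, 8))}"
            total = 10
            rows.append(
                (
                    votu,
                    int(rng.integers(1, total + 1)),
                    total,
                    f"COG{int(rng.integers(0, 5)):04d}",
                    "caller_a" if rng.random() < 0.5 else "caller_b",
                )
            )
        calls = [
            AmgCall(v, i, t, c, callers=frozenset([caller]))
            for v, i, t, c, caller in rows
        ]
        curated = curate_amgs(calls)
        got = {(c.votu_id, c.gene_index, c.cog_id): c.callers for c in curated}
        assert got == curate_amgs_oracle(rows)

    def test_bp_buffer_mode(self):
        calls = [amg("v1", 2, 10), amg("v1", 5, 10)]
        positions = {("v1", 2): (100, 400), ("v1", 5): (2000, 2500)}
        kept = curate_amgs(
            calls,
            edge_mode="bp_buffer",
            end_buffer_bp=500,
            gene_positions=positions,
            contig_lengths={"v1": 10000},
        )
        assert [c.gene_index for c in kept] == [5]

    def test_bp_buffer_requires_positions(self):
        with pytest.raises(InvalidRecordError):
            curate_amgs([amg("v1", 5, 10)], edge_mode="bp_buffer")
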