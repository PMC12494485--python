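"""Island-gene overlap and eggNOG category profiling."""

import pytest

from crust.annotate import (
    CdsFeature,
    overlap_islands_with_cds,
    summarize_categories,
    top_cogs,
)
from crust.islands import Island

from _oracles import quadratic_overlaps


def island(contig, start, end, genome="g"):
    return Island(genome, contig, start, end, "drop", 10.0, 5.0, False)


def cds(contig, start, end, pid, cogs=(), cats=""):
    return CdsFeature(contig, start, end, "+", pid, cogs, cats)


class TestOverlap:
    def test_partial_containment_reported(self):
        pairs = overlap_islands_with_cds(
            [island("c1", 450, 600)], [cds("c1", 200, 500, "p1")]
        )
        assert len(pairs) == 1

    def test_disjoint_not_reported(self):
        assert overlap_islands_with_cds(
            [island("c1", 100, 200)], [cds("c1", 600, 700, "p1")]
        ) == []

    def test_different_contigs_not_reported(self):
        assert overlap_islands_with_cds(
            [island("c1", 100, 200)], [cds("c2", 100, 200, "p1")]
        ) == []

    def test_abutting_intervals_not_reported(self):
        assert overlap_islands_with_cds(
            [island("c1", 100, 200)], [cds("c1", 200, 300, "p1")]
        ) == []

    def test_matches_quadratic_oracle(self, rng):
        islands, features = [], []
        for i in range(120):
            contig = f"c{int(rng.integers(0, 3))}"
            start = int(rng.integers(0, 5000))
            islands.append(island(contig, start, start + int(rng.integers(50, 600))))
        for j in range(120):
            contig = f"c{int(rng.integers(0, 3))}"
            start = int(rng.integers(0, 5000))
            features.append(
                cds(contig, start, start + int(rng.integers(50, 900)), f"p{j}")
            )
        pairs = overlap_islands_with_cds(islands, features)
        got = {
            (islands.index(i), features.index(f)) for i, f in pairs
        }
        expected = quadratic_overlaps(
            [(i.contig_id, i.start, i.end) for i in islands],
            [(f.contig_id, f.start, f.end) for f in features],
        )
        assert got == expected

    def test_each_pair_reported_once(self):
        pairs = overlap_islands_with_cds(
            [island("c1", 0, 1000)], [cds("c1", 100, 200, "p1")]
        )
        assert len(pairs) == 1

    def test_shuffle_invariant(self, rng):
        islands = [island("c1", i * 100, i * 100 + 150) for i in range(10)]
        features = [cds("c1", i * 120, i * 120 + 100, f"p{i}") for i in range(10)]
        a = overlap_islands_with_cds(islands, features)
        perm = list(rng.permutation(len(features)))
        b = overlap_islands_with_cds(islands[::-1], [features[i] for i in perm])
        key = lambda p: (p[0].start, p[0].end, p[1].protein_id)
        assert sorted(a, key=key) == sorted(b, key=key)


class TestSummarizeCategories:
    def test_multi_letter_expansion(self):
        profile = summarize_categories([cds("c", 0, 10, "p1", cats="EGP")])
        assert profile.counts == {"E": 1, "G": 1, "P": 1}

    def test_empty_input(self):
        profile = summarize_categories([])
        assert profile.counts == {} and profile.total_hits == 0

    def test_total_equals_category_string_lengths(self, rng):
        letters = "LMEKSTPUV"
        features = []
        for i in range(100):
            k = int(rng.integers(1, 4))
            cats = "".join(letters[int(rng.integers(0, len(letters)))] for _ in range(k))
            features.append(cds("c", i * 10, i * 10 + 5, f"p{i}", cats=cats))
        profile = summarize_categories(features)
        assert profile.total_hits == sum(len(f.categories) for f in features)
        # per-letter counts equal a brute-force expansion count
        from collections import Counter

        expected = Counter("".join(f.categories for f in features))
        assert profile.counts == dict(expected)

    def test_pairs_deduplicated_by_protein(self):
        feat = cds("c1", 100, 400, "p1", cats="L")
        pairs = [(island("c1", 0, 200), feat), (island("c1", 300, 500), feat)]
        profile = summarize_categories(pairs)
        assert profile.counts == {"L": 1}

    def test_others_bucket_below_threshold(self):
        features = [cds("c", i, i + 1, f"p{i}", cats="L") for i in range(98)]
        features.append(cds("c", 990, 991, "px", cats="K"))
        features.append(cds("c", 995, 996, "py", cats="K"))
        profile = summarize_categories(features, others_threshold=2.0)
        assert profile.others_bucket == []  # K has exactly 2% -> not below
        profile = summarize_categories(features, others_threshold=2.5)
        assert profile.others_bucket == ["K"]
        collapsed = profile.collapsed()
        assert collapsed["Others"] == pytest.approx(2.0)
        assert sum(collapsed.values()) == pytest.approx(100.0, abs=0.01)

    def test_exclude_S_removes_from_denominator(self):
        features = [
            cds("c", 0, 1, "p1", cats="S"),
            cds("c", 2, 3, "p2", cats="L"),
            cds("c", 4, 5, "p3", cats="L"),
        ]
        with_s = summarize_categories(features)
        assert with_s.relative["L"] == pytest.approx(200 / 3)
        without_s = summarize_categories(features, exclude_S=True)
        assert "S" not in without_s.counts
        assert without_s.relative["L"] == pytest.approx(100.0)

    def test_unknown_letter_warns(self):
        with pytest.warns(UserWarning, match="unknown eggNOG category"):
            summarize_categories([cds("c", 0, 1, "p1", cats="L!")])


class TestTopCogs:
    def test_ranking_and_truncation(self):
        features = []
        for cog, count in (("COG0582", 7), ("COG1961", 6), ("COG5410", 5)):
            for i in range(count):
                features.append(cds("c", i, i + 1, f"{cog}_{i}", cogs=(cog,)))
        table = top_cogs(features, n=2)
        assert table["cog_id"].tolist() == ["COG0582", "COG1961"]
        assert table["count"].tolist() == [7, 6]

    def test_n_larger_than_distinct(self):
        features = [cds("c", 0, 1, "p1", cogs=("COG0001",))]
        assert len(top_cogs(features, n=50)) == 1

    def test_ties_broken_lexicographically(self):
        features = [
            cds("c", 0, 1, "p1", cogs=("COG0002",)),
            cds("c", 2, 3, "p2", cogs=("COG0001",)),
        ]
        assert top_cogs(features, n=2)["cog_id"].tolist() == ["COG0001", "COG0002"]

    def test_matches_full_sort_oracle(self, rng):
        from collections import Counter

        features = []
        for i in range(200):
            cog = f"COG{int(rng.integers(0, 30)):04d}"
            features.append(cds("c", i, i + 1, f"p{i}", cogs=(cog,)))
        counts = Counter(f.cog_ids[0] for f in features)
        expected = [c for c, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
        assert top_cogs(features, n=len(counts))["cog_id"].tolist() == expected
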