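import numpy as np
import pytest

from crust.coverage import AlignmentRecord, GenomeSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def small_genome():
    return GenomeSet(genome_id="MAG1", contigs=(("c1", 100), ("c2", 300)))


def random_alignments(rng, contig_ids, contig_lengths, n, max_mm=5):
    """Random alignment records across the given contigs."""
    records = []
    for i in range(n):
        cid = contig_ids[int(rng.integers(0, len(contig_ids)))]
        length = contig_lengths[cid]
        span = int(rng.integers(1, min(200, length) + 1))
        start = int(rng.integers(0, length - span + 1))
        records.append(
            AlignmentRecord(
                query_id=f"q{i}",
                contig_id=cid,
                start=start,
                end=start + span,
                mismatches=int(rng.integers(0, max_mm + 1)),
                is_primary=bool(rng.random() < 0.9),
            )
        )
    return records
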