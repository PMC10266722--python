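import numpy as np
import pandas as pd
import pytest

from chromspace import (
    CoverageTrack,
    FragmentSet,
    PromoterRecord,
    SyntheticGenome,
)


@pytest.fixture
def toy_genome():
    return SyntheticGenome(("chrA", "chrB"), (10_000, 6_000))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_fragments(rng, genome, n, max_len=300, sample_id="s", spike=10_000):
    chroms, starts, ends = [], [], []
    names = list(genome.chrom_names)
    for _ in range(n):
        c = names[rng.integers(len(names))]
        clen = genome.length_of(c)
        length = int(rng.integers(1, max_len + 1))
        s = int(rng.integers(0, clen - length))
        chroms.append(c)
        starts.append(s)
        ends.append(s + length)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    return FragmentSet(df, sample_id=sample_id, spike_count=spike)


def random_track(rng, genome, scale=5.0):
    values = {c: rng.random(genome.length_of(c)) * scale for c in genome.chrom_names}
    return CoverageTrack(genome, values)


def random_promoters(rng, genome, n, prefix="p"):
    """Random promoter table with unique (chrom, tss, strand)."""
    recs, used = [], set()
    names = list(genome.chrom_names)
    i = 0
    while len(recs) < n:
        c = names[rng.integers(len(names))]
        tss = int(rng.integers(0, genome.length_of(c)))
        strand = "+" if rng.random() < 0.5 else "-"
        if (c, tss, strand) in used:
            continue
        used.add((c, tss, strand))
        recs.append(PromoterRecord(c, tss, strand, f"{prefix}{i:04d}"))
        i += 1
    return recs
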