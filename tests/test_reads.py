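"""Read simulation, coverage tracks and duplicate marking."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import mesasim as m
from mesasim.droplets import FragmentModel, FragmentSet, fragment_genome, pool_from_fragments
from mesasim.genome import decode_bases
from mesasim.reads import (
    CoverageTrack,
    ReadModel,
    ReadSet,
    coverage_from_intervals,
    coverage_track,
    mark_duplicates,
    simulate_reads,
)
from mesasim.variants import pileup


def _genome(length=10_000, seed=1):
    genome, _ = m.build_genome(chrom_sizes={"c": length}, n_loci=0,
                               window_sizes=(), seed=seed)
    return genome


def _manual_pool(genome, intervals, copies=None):
    n = len(intervals)
    fs = FragmentSet(
        chrom_names=list(genome.names),
        chrom_idx=np.zeros(n, dtype=np.int32),
        start=np.array([s for s, _ in intervals], dtype=np.int64),
        end=np.array([e for _, e in intervals], dtype=np.int64),
        copy_id=np.arange(n, dtype=np.int32),
    )
    fs.is_target = np.zeros(n, dtype=bool)
    fs.amplicon_id = np.full(n, -1, dtype=np.int32)
    pool = pool_from_fragments(fs)
    if copies is not None:
        pool.copy_number = np.asarray(copies, dtype=np.int64)
    return pool


def test_reads_stay_within_their_source_fragment():
    genome = _genome(1_000)
    pool = _manual_pool(genome, [(0, 100)])
    reads = simulate_reads(pool, genome, ReadModel(n_reads=500), rng=3)
    assert (reads.start >= 0).all() and (reads.end <= 100).all()


def test_strand_fractions_are_balanced():
    genome = _genome(100_000)
    pool = _manual_pool(genome, [(0, 100_000)])
    reads = simulate_reads(pool, genome, ReadModel(n_reads=100_000), rng=4)
    frac = (reads.strand == 0).mean()
    se = 0.5 / np.sqrt(reads.n)
    assert abs(frac - 0.5) < 3 * se


def test_error_free_reads_reproduce_genome_substring():
    genome = _genome(2_000)
    pool = _manual_pool(genome, [(0, 2_000)])
    reads = simulate_reads(pool, genome, ReadModel(n_reads=50, error_rate=0.0),
                           rng=5)
    for i in range(reads.n):
        s = reads.start[i]
        assert decode_bases(reads.bases[i]) == genome.substring("c", s, s + 50)


def test_error_rate_perturbs_expected_base_fraction():
    genome = _genome(5_000)
    pool = _manual_pool(genome, [(0, 5_000)])
    eps = 0.01
    reads = simulate_reads(pool, genome, ReadModel(n_reads=2_000, error_rate=eps),
                           rng=6)
    ref = np.stack([genome.seq["c"][s : s + 50] for s in reads.start])
    mism = (reads.bases != ref).mean()
    se = np.sqrt(eps * (1 - eps) / reads.bases.size)
    assert abs(mism - eps) < 4 * se


def test_short_molecules_are_skipped_and_counted():
    genome = _genome(1_000)
    pool = _manual_pool(genome, [(0, 30), (100, 400)])
    reads = simulate_reads(pool, genome, ReadModel(n_reads=200), rng=7)
    assert reads.n_skipped_short == 1
    assert (reads.start >= 100).all()


def test_planted_hom_and_het_variants_enter_reads():
    genome = _genome(4_000)
    # two haplotype copies of the same interval
    pool = _manual_pool(genome, [(0, 4_000), (0, 4_000)])
    ref = genome.base("c", 2_000)
    alt = "A" if ref != "A" else "G"
    hom = m.TruthVariant("c", 2_000, ref, alt, "hom")
    reads = simulate_reads(pool, genome, ReadModel(n_reads=4_000, error_rate=0.0),
                           rng=8, variants=[hom])
    cover = (reads.start <= 2_000) & (reads.end > 2_000)
    got = reads.bases[cover, (2_000 - reads.start[cover])]
    assert (decode_bases(got) == alt * cover.sum())  # hom: every haplotype

    het = m.TruthVariant("c", 2_000, ref, alt, "het")
    reads = simulate_reads(pool, genome, ReadModel(n_reads=4_000, error_rate=0.0),
                           rng=8, variants=[het])
    cover = (reads.start <= 2_000) & (reads.end > 2_000)
    got = decode_bases(reads.bases[cover, (2_000 - reads.start[cover])])
    frac_alt = np.mean([c == alt for c in got])
    assert abs(frac_alt - 0.5) < 3 * 0.5 / np.sqrt(cover.sum())


# --------------------------------------------------------------- coverage

def test_two_overlapping_reads_interval_arithmetic():
    genome = _genome(100)
    reads = ReadSet(
        chrom_names=["c"],
        chrom_idx=np.zeros(2, dtype=np.int32),
        start=np.array([0, 25], dtype=np.int64),
        strand=np.zeros(2, dtype=np.int8),
        hap=np.zeros(2, dtype=np.int8),
        frag_id=np.zeros(2, dtype=np.int64),
        bases=np.zeros((2, 50), dtype=np.uint8),
        read_length=50,
    )
    track = coverage_track(reads, genome)
    d = track["c"]
    assert (d[0:25] == 1).all() and (d[25:50] == 2).all() and (d[50:75] == 1).all()
    assert d[75:].sum() == 0
    assert d.sum() == 100  # conservation


def test_coverage_matches_bruteforce_counting_oracle():
    genome = _genome(5_000)
    rng = np.random.default_rng(11)
    n = 400
    starts = rng.integers(0, 5_000 - 50, size=n).astype(np.int64)
    reads = ReadSet(
        chrom_names=["c"],
        chrom_idx=np.zeros(n, dtype=np.int32),
        start=starts,
        strand=rng.integers(0, 2, n).astype(np.int8),
        hap=np.zeros(n, dtype=np.int8),
        frag_id=np.zeros(n, dtype=np.int64),
        bases=np.zeros((n, 50), dtype=np.uint8),
        read_length=50,
    )
    brute = np.zeros(5_000, dtype=np.int64)
    for s in starts:
        for p in range(s, s + 50):
            brute[p] += 1
    track = coverage_track(reads, genome)
    assert np.array_equal(track["c"], brute)


@given(
    starts=st.lists(st.integers(min_value=0, max_value=950), min_size=1,
                    max_size=60),
)
def test_coverage_conservation_property(starts):
    genome = _genome(1_000)
    n = len(starts)
    reads = ReadSet(
        chrom_names=["c"],
        chrom_idx=np.zeros(n, dtype=np.int32),
        start=np.array(starts, dtype=np.int64),
        strand=np.zeros(n, dtype=np.int8),
        hap=np.zeros(n, dtype=np.int8),
        frag_id=np.zeros(n, dtype=np.int64),
        bases=np.zeros((n, 50), dtype=np.uint8),
        read_length=50,
    )
    track = coverage_track(reads, genome)
    assert track["c"].sum() == 50 * n


def test_read_off_chromosome_errors():
    genome = _genome(100)
    reads = ReadSet(
        chrom_names=["c"],
        chrom_idx=np.zeros(1, dtype=np.int32),
        start=np.array([80], dtype=np.int64),
        strand=np.zeros(1, dtype=np.int8),
        hap=np.zeros(1, dtype=np.int8),
        frag_id=np.zeros(1, dtype=np.int64),
        bases=np.zeros((1, 50), dtype=np.uint8),
        read_length=50,
    )
    with pytest.raises(ValueError):
        coverage_track(reads, genome)


def test_whole_genome_pool_coverage_within_poisson_bounds():
    genome = _genome(200_000, seed=3)
    pool = _manual_pool(genome, [(0, 200_000)])
    depth_target = 20
    n_reads = depth_target * 200_000 // 50
    reads = simulate_reads(pool, genome, ReadModel(n_reads=n_reads), rng=13)
    d = np.asarray(coverage_track(reads, genome)["c"][50:-50])  # interior bases
    lo, hi = stats.poisson.ppf([0.0005, 0.9995], depth_target)
    frac_outside = ((d < lo) | (d > hi)).mean()
    assert frac_outside < 0.01  # 99.9% band, allow sampling slack


# -------------------------------------------------------------- duplicates

def _reads_from(starts, strands, genome):
    n = len(starts)
    return ReadSet(
        chrom_names=list(genome.names),
        chrom_idx=np.zeros(n, dtype=np.int32),
        start=np.array(starts, dtype=np.int64),
        strand=np.array(strands, dtype=np.int8),
        hap=np.zeros(n, dtype=np.int8),
        frag_id=np.arange(n, dtype=np.int64),
        bases=np.zeros((n, 50), dtype=np.uint8),
        read_length=50,
    )


def test_distinct_starts_zero_duplicates():
    genome = _genome(1_000)
    frac, dedup = mark_duplicates(_reads_from([0, 10, 20, 30], [0, 0, 0, 0], genome))
    assert frac == 0.0 and dedup.n == 4


def test_one_identical_pair_gives_fraction_one_over_n():
    genome = _genome(1_000)
    frac, dedup = mark_duplicates(_reads_from([0, 10, 10, 30], [0, 1, 1, 0], genome))
    assert frac == 0.25 and dedup.n == 3
    # opposite strands at the same start are NOT duplicates
    frac2, _ = mark_duplicates(_reads_from([10, 10], [0, 1], genome))
    assert frac2 == 0.0


def test_wga_dispersion_raises_duplicate_fraction():
    genome = _genome(100_000, seed=9)
    model = FragmentModel(mean_length=5_000, sd_length=500)
    frags = fragment_genome(genome, model, 5, rng=10)
    frags.is_target = np.zeros(frags.n, dtype=bool)
    frags.amplicon_id = np.full(frags.n, -1, dtype=np.int32)
    fracs = {}
    for sigma in (0.0, 1.5):
        pool = pool_from_fragments(frags)
        pool = m.wga_amplify(pool, sigma, rng=np.random.default_rng(14))
        reads = simulate_reads(pool, genome, ReadModel(n_reads=60_000), rng=15)
        fracs[sigma], _ = mark_duplicates(reads)
    assert fracs[1.5] > fracs[0.0]


def test_dedup_coverage_nowhere_exceeds_raw():
    genome = _genome(20_000)
    pool = _manual_pool(genome, [(0, 20_000)])
    reads = simulate_reads(pool, genome, ReadModel(n_reads=30_000), rng=16)
    _, dedup = mark_duplicates(reads)
    raw = coverage_track(reads, genome)["c"]
    dd = coverage_track(dedup, genome)["c"]
    assert (dd <= raw).all()


def test_pileup_depth_equals_coverage_track():
    genome = _genome(8_000)
    pool = _manual_pool(genome, [(0, 8_000)])
    reads = simulate_reads(pool, genome, ReadModel(n_reads=3_000), rng=17)
    track = coverage_track(reads, genome)
    pile = pileup(reads, genome)
    assert np.array_equal(pile.depth("c"), np.asarray(track["c"], dtype=np.int64))
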