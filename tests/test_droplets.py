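"""Fragmentation, Poisson encapsulation, fluorescence sorting and WGA."""

import numpy as np
import pytest
from scipy import stats

import mesasim as m
from mesasim.analytic import solve_false_sort_rate
from mesasim.droplets import (
    DropletConfig,
    FluorescenceModel,
    FragmentModel,
    SorterModel,
    classify_targets,
    encapsulate,
    fluoresce,
    fragment_genome,
    pool_from_fragments,
    remove_amplicons,
    sort_droplets,
    wga_amplify,
    wga_copy_factors,
)
from mesasim.reads import ReadModel, coverage_track, simulate_reads


def _tiny_genome(length=10_000, seed=0):
    genome, _ = m.build_genome(chrom_sizes={"c": length}, n_loci=0,
                               window_sizes=(), seed=seed)
    return genome


# ---------------------------------------------------------- fragmentation

def test_fixed_aligned_tiling_covers_every_base_exactly_once():
    genome = _tiny_genome(10_000)
    model = FragmentModel(mean_length=1000, sd_length=0, family="fixed",
                          phase="aligned")
    frags = fragment_genome(genome, model, n_copies=1, rng=0)
    assert frags.n == 10
    assert int((frags.end - frags.start).sum()) == 10_000
    cov = np.zeros(10_000, int)
    for s, e in zip(frags.start, frags.end):
        cov[s:e] += 1
    assert (cov == 1).all()


def test_random_phase_tiling_conserves_bases_per_copy():
    genome = _tiny_genome(50_000)
    model = FragmentModel(mean_length=7_000, sd_length=800)
    frags = fragment_genome(genome, model, n_copies=5, rng=1)
    assert int((frags.end - frags.start).sum()) == 5 * 50_000
    for copy in range(5):
        sel = frags.copy_id == copy
        order = np.argsort(frags.start[sel])
        s, e = frags.start[sel][order], frags.end[sel][order]
        assert s[0] == 0 and e[-1] == 50_000
        assert (s[1:] == e[:-1]).all()  # abutting, no overlap


def test_hmw_fragment_length_recovers_configured_mean():
    genome, _ = m.build_genome(chrom_sizes={"16": 5_000_000}, n_loci=0,
                               window_sizes=(), seed=2)
    model = FragmentModel(mean_length=52_400, sd_length=5_706)
    frags = fragment_genome(genome, model, n_copies=10, rng=3)
    interior = (frags.start > 0) & (frags.end < 5_000_000)  # not end-truncated
    lengths = (frags.end - frags.start)[interior]
    se = 5_706 / np.sqrt(len(lengths))
    assert abs(lengths.mean() - 52_400) < 3 * se


def test_same_seed_identical_fragments():
    genome = _tiny_genome(30_000)
    model = FragmentModel(mean_length=2_000, sd_length=300)
    a = fragment_genome(genome, model, 3, rng=9)
    b = fragment_genome(genome, model, 3, rng=9)
    assert np.array_equal(a.start, b.start) and np.array_equal(a.end, b.end)


def test_fragment_longer_than_chromosome_errors():
    genome = _tiny_genome(1_000)
    with pytest.raises(ValueError):
        fragment_genome(genome, FragmentModel(mean_length=5_000), 1, rng=0)


# ---------------------------------------------------------- encapsulation

def _target_setup(n_copies=30, seed=4):
    genome, loci = m.build_genome(chrom_sizes={"16": 1_000_000}, n_loci=1,
                                  window_sizes=(50_000,), seed=seed)
    amps = [l.assay for l in loci]
    frags = fragment_genome(genome, FragmentModel(), n_copies, rng=seed)
    classify_targets(frags, amps)
    return genome, loci, amps, frags


def test_zero_lambda_t_gives_zero_positive_droplets():
    _, _, amps, frags = _target_setup()
    cfg = DropletConfig(n_droplets=10_000, lambda_t=0.0, lambda_b=0.5)
    pop = encapsulate(frags, cfg, amps, rng=1)
    assert pop.taqman_positive.sum() == 0


def test_positive_fraction_follows_digital_pcr_law():
    _, _, amps, frags = _target_setup()
    lam = 0.013085
    N = 1_000_000
    cfg = DropletConfig(n_droplets=N, lambda_t=lam)
    pop = encapsulate(frags, cfg, amps, rng=2)
    p = -np.expm1(-lam)
    se = np.sqrt(p * (1 - p) / N)
    assert abs(pop.taqman_positive.mean() - p) < 3 * se


def test_occupancy_is_poisson_chi_square():
    _, _, amps, frags = _target_setup()
    lam_b = 2.0
    cfg = DropletConfig(n_droplets=100_000, lambda_t=0.0, lambda_b=lam_b)
    pop = encapsulate(frags, cfg, amps, rng=3)
    k = pop.k_background
    kmax = 9  # pool the tail so expected counts stay >= 5
    obs = np.bincount(np.minimum(k, kmax), minlength=kmax + 1)
    pmf = stats.poisson.pmf(np.arange(kmax), lam_b)
    probs = np.concatenate((pmf, [1 - pmf.sum()]))
    chi2, pval = stats.chisquare(obs, probs * len(k))
    assert pval > 0.01


def test_without_replacement_assigns_each_fragment_at_most_once():
    _, _, amps, frags = _target_setup(n_copies=50)
    cfg = DropletConfig(n_droplets=200, lambda_t=0.1, lambda_b=2.0,
                        with_replacement=False)
    pop = encapsulate(frags, cfg, amps, rng=4)
    used = np.concatenate((pop.target_ids, pop.background_ids))
    assert len(np.unique(used)) == len(used)
    assert len(pop.target_ids) == pop.k_target.sum()
    assert len(pop.background_ids) == pop.k_background.sum()


def test_empty_fragment_pool_with_positive_lambda_errors():
    genome, loci, amps, frags = _target_setup()
    empty = frags.subset(np.zeros(0, dtype=np.int64))
    empty.is_target = np.zeros(0, dtype=bool)
    empty.amplicon_id = np.zeros(0, dtype=np.int32)
    cfg = DropletConfig(n_droplets=100, lambda_t=0.1)
    with pytest.raises(ValueError):
        encapsulate(empty, cfg, amps, rng=0)


# ---------------------------------------------------------- fluorescence

def test_degenerate_sigmas_perfectly_separate_classes():
    _, _, amps, frags = _target_setup()
    cfg = DropletConfig(n_droplets=50_000, lambda_t=0.02, lambda_b=0.2)
    pop = encapsulate(frags, cfg, amps, rng=5)
    fl = FluorescenceModel(mu_neg=0.1, sd_neg=0.0, mu_pos=0.9, sd_pos=0.0,
                           width_sd=0.0)
    fld = fluoresce(pop, fl, rng=6)
    assert set(np.round(fld.amplitude, 6)) <= {0.1, 0.9}
    assert (fld.amplitude[fld.taqman_positive] == 0.9).all()


def test_merged_droplet_fraction_matches_merge_rate():
    _, _, amps, frags = _target_setup()
    cfg = DropletConfig(n_droplets=200_000, lambda_t=0.01, merge_rate=0.02)
    pop = encapsulate(frags, cfg, amps, rng=7)
    fld = fluoresce(pop, FluorescenceModel(), rng=8)
    frac = fld.merged.mean()
    se = np.sqrt(0.02 * 0.98 / fld.n)
    assert abs(frac - 0.02) < 3 * se
    # merged droplets carry doubled width
    assert fld.width[fld.merged].mean() > 1.5 * fld.width[~fld.merged].mean()


def test_pcr_failed_positive_draws_negative_amplitude():
    _, _, amps, frags = _target_setup()
    cfg = DropletConfig(n_droplets=20_000, lambda_t=0.05, pcr_failure_rate=1.0)
    pop = encapsulate(frags, cfg, amps, rng=9)
    fl = FluorescenceModel(mu_neg=0.1, sd_neg=0.0, mu_pos=0.9, sd_pos=0.0)
    fld = fluoresce(pop, fl, rng=10)
    assert pop.contains_target.any()
    assert (fld.amplitude[fld.contains_target] == 0.1).all()


# ---------------------------------------------------------------- sorting

def test_perfect_separation_yields_unit_purity_and_full_recovery():
    _, _, amps, frags = _target_setup()
    cfg = DropletConfig(n_droplets=100_000, lambda_t=0.013)
    pop = encapsulate(frags, cfg, amps, rng=11)
    fld = fluoresce(pop, FluorescenceModel(), rng=12)
    pool = sort_droplets(fld, SorterModel(threshold=0.45), amps, rng=13)
    assert pool.stats.droplet_purity == 1.0
    assert pool.stats.n_sorted == int(fld.taqman_positive.sum())
    assert pool.stats.n_target_molecules == int(pop.k_target.sum())


def test_tuned_false_sort_rate_reaches_target_droplet_purity():
    """2.3% positives enriched to ~87.6% collected purity via false sorts."""
    _, _, amps, frags = _target_setup()
    lam = -np.log1p(-0.023)
    N = 400_000
    cfg = DropletConfig(n_droplets=N, lambda_t=lam)
    pop = encapsulate(frags, cfg, amps, rng=14)
    fld = fluoresce(pop, FluorescenceModel(), rng=15)
    q = solve_false_sort_rate(0.023, 0.876)
    pool = sort_droplets(fld, SorterModel(threshold=0.45, false_sort_rate=q),
                         amps, rng=16)
    n = pool.stats.n_sorted
    se = np.sqrt(0.876 * 0.124 / n)
    assert abs(pool.stats.droplet_purity - 0.876) < 3 * se


def test_threshold_above_all_amplitudes_warns_and_returns_empty_pool():
    _, _, amps, frags = _target_setup()
    cfg = DropletConfig(n_droplets=1_000, lambda_t=0.05)
    pop = encapsulate(frags, cfg, amps, rng=17)
    fld = fluoresce(pop, FluorescenceModel(), rng=18)
    with pytest.warns(UserWarning):
        pool = sort_droplets(fld, SorterModel(threshold=1e9), amps, rng=19)
    assert pool.stats.n_sorted == 0 and pool.n_fragments == 0


def test_purity_nonincreasing_in_false_sort_rate():
    _, _, amps, frags = _target_setup()
    lam = 0.02
    purities = []
    for q in (0.0, 0.005, 0.05):
        vals = []
        for seed in range(5):
            cfg = DropletConfig(n_droplets=50_000, lambda_t=lam)
            pop = encapsulate(frags, cfg, amps, rng=100 + seed)
            fld = fluoresce(pop, FluorescenceModel(), rng=200 + seed)
            pool = sort_droplets(
                fld, SorterModel(threshold=0.45, false_sort_rate=q), amps,
                rng=300 + seed,
            )
            vals.append(pool.stats.droplet_purity)
        purities.append(np.mean(vals))
    assert purities[0] >= purities[1] >= purities[2]


def test_recovery_nonincreasing_in_pcr_failure_rate():
    _, _, amps, frags = _target_setup()
    recov = []
    for fail in (0.0, 0.3, 0.8):
        vals = []
        for seed in range(5):
            cfg = DropletConfig(n_droplets=50_000, lambda_t=0.02,
                                pcr_failure_rate=fail)
            pop = encapsulate(frags, cfg, amps, rng=400 + seed)
            fld = fluoresce(pop, FluorescenceModel(), rng=500 + seed)
            pool = sort_droplets(fld, SorterModel(threshold=0.45), amps,
                                 rng=600 + seed)
            vals.append(pool.stats.n_target_molecules)
        recov.append(np.mean(vals))
    assert recov[0] >= recov[1] >= recov[2]


def test_same_seed_bit_identical_sorted_pool():
    _, _, amps, frags = _target_setup()
    pools = []
    for _ in range(2):
        cfg = DropletConfig(n_droplets=20_000, lambda_t=0.02, lambda_b=0.3,
                            merge_rate=0.02)
        pop = encapsulate(frags, cfg, amps, rng=21)
        fld = fluoresce(pop, FluorescenceModel(), rng=22)
        pools.append(sort_droplets(fld, SorterModel(threshold=0.45), amps, rng=23))
    a, b = pools
    assert np.array_equal(a.frag_ids, b.frag_ids)
    assert a.stats == b.stats


# --------------------------------------------------- amplicon removal, WGA

def _sorted_pool(residual_pref=None, seed=30):
    genome, loci, amps, frags = _target_setup(seed=31)
    cfg = DropletConfig(n_droplets=100_000, lambda_t=0.013, lambda_b=0.1,
                        amplicon_copies=500)
    pop = encapsulate(frags, cfg, amps, rng=seed)
    fld = fluoresce(pop, FluorescenceModel(), rng=seed + 1)
    pool = sort_droplets(fld, SorterModel(threshold=0.45), amps, rng=seed + 2)
    return genome, loci, pool


def test_udg_removal_zeroes_amplicon_molecules_keeps_fragments():
    genome, loci, pool = _sorted_pool()
    assert pool.amplicon_molecules.sum() > 0
    cleaned = remove_amplicons(pool, residual_fraction=0.0)
    assert cleaned.amplicon_molecules.sum() == 0
    assert cleaned.n_fragments == pool.n_fragments


def test_residual_amplicons_show_as_coverage_spike():
    genome, loci, pool = _sorted_pool()
    assay = loci[0].assay
    model = ReadModel(n_reads=100_000, error_rate=0.0)
    depths = {}
    for residual in (0.0, 1.0):
        p = remove_amplicons(pool, residual_fraction=residual)
        reads = simulate_reads(p, genome, model, rng=55)
        track = coverage_track(reads, genome)
        depths[residual] = track["16"][assay.start : assay.end].mean()
    assert depths[1.0] > 3 * depths[0.0]


def test_wga_sigma_zero_is_identity():
    genome, loci, pool = _sorted_pool()
    out = wga_amplify(pool, sigma=0.0, rng=1)
    assert np.array_equal(out.copy_number, np.ones(pool.n_fragments, dtype=np.int64))


def test_wga_copy_factor_moments_match_lognormal():
    sigma, n = 1.0, 100_000
    x = wga_copy_factors(n, sigma, np.random.default_rng(77))
    v = np.exp(sigma**2) - 1  # variance of a mean-1 lognormal
    mu4c = np.exp(6 * sigma**2) - 4 * np.exp(3 * sigma**2) + 6 * np.exp(sigma**2) - 3
    se_mean = np.sqrt(v / n)
    se_var = np.sqrt((mu4c - v**2) / n)
    assert abs(x.mean() - 1.0) < 3 * se_mean
    assert abs(x.var() - v) < 3 * se_var


def test_wga_copies_at_least_one_and_total_at_least_count():
    genome, loci, pool = _sorted_pool()
    out = wga_amplify(pool, sigma=1.2, rng=5)
    assert (out.copy_number >= 1).all()
    assert out.copy_number.sum() >= out.n_fragments


def test_unsorted_pool_wraps_all_fragments():
    genome, loci, amps, frags = _target_setup()
    pool = pool_from_fragments(frags)
    assert pool.n_fragments == frags.n
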