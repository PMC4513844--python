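"""Droplet encapsulation, TaqMan detection and dielectrophoretic sorting.

Models the physical workflow: high-molecular-weight genomic fragments are
Poisson-loaded into millions of picoliter droplets, TaqMan PCR lights up
droplets whose fragment pool fully contains a probe amplicon, and a
fluorescence/width-gated sorter collects the positive cluster. Emulsion
instability merges a small fraction of droplets pre-sort; gate-negative
droplets can be collected by false sorts. Downstream, TaqMan amplicons are
enzymatically removed and the pool can be whole-genome amplified, which
spreads per-fragment copy numbers.

Everything is vectorised over struct-of-array containers so millions of
droplets fit in a laptop-scale run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GenomeModel, ProbeAssay

__all__ = [
    "FragmentModel",
    "FragmentSet",
    "fragment_genome",
    "classify_targets",
    "target_fragments_over_point",
    "DropletConfig",
    "DropletPopulation",
    "encapsulate",
    "FluorescenceModel",
    "DropletField",
    "fluoresce",
    "SorterModel",
    "SortStats",
    "SortedPool",
    "sort_droplets",
    "pool_from_fragments",
    "remove_amplicons",
    "wga_amplify",
    "wga_copy_factors",
]


# ------------------------------------------------------------ fragments

@dataclass
class FragmentModel:
    """Fragment length model for the encapsulated genomic DNA.

    Defaults follow a high-molecular-weight prep: ~52.4 kb mean with ~5.7 kb
    spread. ``family`` is "normal" (truncated at ``min_length``) or "fixed";
    ``phase`` controls whether per-copy fragmentation starts at a random
    offset ("random", realistic — sheared DNA has no genome-aligned phase) or
    at coordinate zero ("aligned", which tiles a chromosome into exactly
    length/L pieces).
    """

    mean_length: float = 52_400.0
    sd_length: float = 5_706.0
    min_length: int = 100
    family: str = "normal"
    phase: str = "random"

    def __post_init__(self) -> None:
        if self.mean_length <= 0:
            raise ValueError("mean_length must be > 0")
        if self.sd_length < 0:
            raise ValueError("sd_length must be >= 0")
        if self.family not in ("normal", "fixed"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.phase not in ("random", "aligned"):
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class FragmentSet:
    """Genomic fragments as parallel arrays (one row per fragment)."""

    chrom_names: list[str]
    chrom_idx: np.ndarray  # int32
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    copy_id: np.ndarray  # int32, source genome copy
    is_target: np.ndarray | None = None  # bool, fully contains some amplicon
    amplicon_id: np.ndarray | None = None  # int32, -1 where not a target

    @property
    def n(self) -> int:
        return len(self.start)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def subset(self, idx: np.ndarray) -> "FragmentSet":
        return FragmentSet(
            chrom_names=self.chrom_names,
            chrom_idx=self.chrom_idx[idx],
            start=self.start[idx],
            end=self.end[idx],
            copy_id=self.copy_id[idx],
            is_target=None if self.is_target is None else self.is_target[idx],
            amplicon_id=None if self.amplicon_id is None else self.amplicon_id[idx],
        )


def _draw_lengths(model: FragmentModel, n: int, rng: np.random.Generator) -> np.ndarray:
    if model.family == "fixed":
        return np.full(n, int(round(model.mean_length)), dtype=np.int64)
    raw = rng.normal(model.mean_length, model.sd_length, size=n)
    return np.maximum(np.round(raw), model.min_length).astype(np.int64)


def fragment_genome(
    genome: GenomeModel,
    model: FragmentModel,
    n_copies: int = 1,
    rng: np.random.Generator | int | None = None,
) -> FragmentSet:
    """Break ``n_copies`` of the genome into non-overlapping tiling fragments.

    Per copy and chromosome, random breakpoints partition every base exactly
    once (end fragments truncated), so total fragment bases equal
    n_copies x G.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for name in genome.names:
        if model.mean_length > len(genome.seq[name]):
            raise ValueError(
                f"mean fragment length {model.mean_length} exceeds chromosome "
                f"{name} length {len(genome.seq[name])}"
            )

    chrom_idx_l, start_l, end_l, copy_l = [], [], [], []
    for copy in range(n_copies):
        for ci, name in enumerate(genome.names):
            clen = len(genome.seq[name])
            pieces: list[np.ndarray] = []
            if model.phase == "random":
                offset = int(rng.integers(0, int(round(model.mean_length))))
            else:
                offset = 0
            total = -offset  # first breakpoint sits at -offset < boundary <= 0
            while total < clen:
                need = int(np.ceil((clen - total) / max(model.mean_length, 1.0))) + 4
                pieces.append(_draw_lengths(model, need, rng))
                total += int(pieces[-1].sum())
            lengths = np.concatenate(pieces)
            bounds = np.cumsum(lengths) - offset
            starts = np.concatenate(([0], bounds[:-1]))
            keep = starts < clen
            starts = np.maximum(starts[keep], 0)
            ends = np.minimum(bounds[keep], clen)
            ok = ends > starts
            starts, ends = starts[ok], ends[ok]
            chrom_idx_l.append(np.full(len(starts), ci, dtype=np.int32))
            start_l.append(starts.astype(np.int64))
            end_l.append(ends.astype(np.int64))
            copy_l.append(np.full(len(starts), copy, dtype=np.int32))

    return FragmentSet(
        chrom_names=list(genome.names),
        chrom_idx=np.concatenate(chrom_idx_l),
        start=np.concatenate(start_l),
        end=np.concatenate(end_l),
        copy_id=np.concatenate(copy_l),
    )


def classify_targets(frags: FragmentSet, amplicons: list[ProbeAssay]) -> FragmentSet:
    """Mark fragments that fully contain an amplicon (both primer sites)."""
    is_target = np.zeros(frags.n, dtype=bool)
    amp_id = np.full(frags.n, -1, dtype=np.int32)
    for i, a in enumerate(amplicons):
        ci = frags.chrom_names.index(a.chrom)
        hit = (
            (frags.chrom_idx == ci)
            & (frags.start <= a.start)
            & (frags.end >= a.end)
            & (amp_id == -1)
        )
        is_target |= hit
        amp_id[hit] = i
    frags.is_target = is_target
    frags.amplicon_id = amp_id
    return frags


def target_fragments_over_point(
    chrom_names: list[str],
    chrom: str,
    point: int,
    length: int,
    n: int,
    rng: np.random.Generator | int | None = None,
    chrom_length: int | None = None,
) -> FragmentSet:
    """n fixed-length fragments whose span covers ``point``, uniform placement.

    The construction behind the triangular coverage kernel: a fragment of
    length L covering a point has its start uniform on (point - L, point].
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    starts = point - rng.integers(0, length, size=n).astype(np.int64)
    ends = starts + length
    if chrom_length is not None:
        if (starts < 0).any() or (ends > chrom_length).any():
            raise ValueError("fragments extend beyond the chromosome")
    ci = chrom_names.index(chrom)
    fs = FragmentSet(
        chrom_names=list(chrom_names),
        chrom_idx=np.full(n, ci, dtype=np.int32),
        start=starts,
        end=ends,
        copy_id=np.arange(n, dtype=np.int32),
    )
    fs.is_target = np.ones(n, dtype=bool)
    fs.amplicon_id = np.zeros(n, dtype=np.int32)
    return fs


# ------------------------------------------------------------- droplets

@dataclass
class DropletConfig:
    """Poisson loading of droplets.

    ``lambda_t``/``lambda_b`` are the mean target/background fragments per
    droplet; the per-droplet total is Poisson(lambda_t + lambda_b) with
    multinomial type labels, equivalent to two independent Poisson streams.
    ``merge_rate`` is the fraction of final droplets that are pairwise merges
    of two emulsion droplets; ``pcr_failure_rate`` is the chance a
    target-containing droplet fails to fluoresce.
    """

    n_droplets: int
    lambda_t: float
    lambda_b: float = 0.0
    merge_rate: float = 0.0
    pcr_failure_rate: float = 0.0
    with_replacement: bool | None = None  # None: decide from pool sizes
    amplicon_copies: int = 200  # TaqMan amplicon molecules per detected droplet

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.lambda_t < 0 or self.lambda_b < 0:
            raise ValueError("lambda values must be >= 0")
        for r in (self.merge_rate, self.pcr_failure_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class DropletPopulation:
    """Pre-merge droplets: per-droplet counts plus CSR-style fragment lists."""

    fragments: FragmentSet
    config: DropletConfig
    k_target: np.ndarray  # int32 (N,)
    k_background: np.ndarray  # int32 (N,)
    target_ids: np.ndarray  # flat fragment indices, grouped by droplet
    t_offsets: np.ndarray  # int64 (N+1,)
    background_ids: np.ndarray
    b_offsets: np.ndarray
    pcr_failed: np.ndarray  # bool (N,)
    with_replacement: bool

    @property
    def n(self) -> int:
        return len(self.k_target)

    @property
    def contains_target(self) -> np.ndarray:
        return self.k_target > 0

    @property
    def taqman_positive(self) -> np.ndarray:
        """Detected: holds a fragment fully containing an amplicon and PCR worked."""
        return self.contains_target & ~self.pcr_failed


def _sample_pool(
    pool: np.ndarray, n_needed: int, with_replacement: bool, rng: np.random.Generator,
    kind: str,
) -> np.ndarray:
    if n_needed == 0:
        return np.empty(0, dtype=np.int64)
    if len(pool) == 0:
        raise ValueError(f"no {kind} fragments available but lambda > 0")
    if with_replacement:
        return pool[rng.integers(0, len(pool), size=n_needed)]
    if n_needed > len(pool):
        raise ValueError(
            f"need {n_needed} {kind} fragments without replacement, have {len(pool)}"
        )
    return rng.permutation(pool)[:n_needed]


def encapsulate(
    fragments: FragmentSet,
    config: DropletConfig,
    amplicons: list[ProbeAssay],
    rng: np.random.Generator | int | None = None,
) -> DropletPopulation:
    """Poisson-load fragments into droplets and run in-droplet TaqMan PCR.

    In without-replacement mode each physical fragment lands in at most one
    droplet; with replacement (for huge droplet counts over desk-scale pools)
    the flag is recorded on the output.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if fragments.is_target is None:
        classify_targets(fragments, amplicons)

    pool_t = np.flatnonzero(fragments.is_target)
    pool_b = np.flatnonzero(~fragments.is_target)
    N = config.n_droplets

    k_t = rng.poisson(config.lambda_t, size=N).astype(np.int32)
    k_b = rng.poisson(config.lambda_b, size=N).astype(np.int32)
    n_t, n_b = int(k_t.sum()), int(k_b.sum())

    wr = config.with_replacement
    if wr is None:
        wr = n_t > len(pool_t) or n_b > len(pool_b)
    ids_t = _sample_pool(pool_t, n_t, wr, rng, "target")
    ids_b = _sample_pool(pool_b, n_b, wr, rng, "background")

    pcr_failed = rng.random(N) < config.pcr_failure_rate

    return DropletPopulation(
        fragments=fragments,
        config=config,
        k_target=k_t,
        k_background=k_b,
        target_ids=ids_t,
        t_offsets=np.concatenate(([0], np.cumsum(k_t, dtype=np.int64))),
        background_ids=ids_b,
        b_offsets=np.concatenate(([0], np.cumsum(k_b, dtype=np.int64))),
        pcr_failed=pcr_failed,
        with_replacement=bool(wr),
    )


# ------------------------------------------------------- fluorescence

@dataclass
class FluorescenceModel:
    """Class-conditional FAM amplitude and droplet width (size proxy).

    Amplitudes are in arbitrary detector units; detected (TaqMan-positive)
    droplets draw from the positive distribution, everything else — including
    positives whose PCR failed — from the negative one.
    """

    mu_neg: float = 0.1
    sd_neg: float = 0.03
    mu_pos: float = 0.8
    sd_pos: float = 0.08
    width_mean: float = 1.0
    width_sd: float = 0.02

    def __post_init__(self) -> None:
        if min(self.sd_neg, self.sd_pos, self.width_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class DropletField:
    """Post-merge droplets as screened by the sorter."""

    population: DropletPopulation
    group_of: np.ndarray  # original droplet -> final droplet index
    amplitude: np.ndarray  # (n_final,)
    width: np.ndarray
    taqman_positive: np.ndarray  # bool
    contains_target: np.ndarray  # bool
    merged: np.ndarray  # bool
    k_target: np.ndarray
    k_background: np.ndarray

    @property
    def n(self) -> int:
        return len(self.amplitude)


def fluoresce(
    pop: DropletPopulation,
    fluor: FluorescenceModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> DropletField:
    """Draw amplitudes/widths and merge a fraction of droplets pairwise.

    A merged droplet carries the union of both parents' contents, the max of
    their amplitudes and the sum of their widths; merging a positive with a
    background-only droplet is the mechanism that dilutes sorted purity.
    Each droplet is chosen for merging with probability
    merge_rate/(1+merge_rate) so the merged fraction of *final* droplets is
    ~merge_rate.
    """
    if fluor is None:
        fluor = FluorescenceModel()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    N = pop.n

    amp = np.where(
        pop.taqman_positive,
        rng.normal(fluor.mu_pos, fluor.sd_pos, size=N),
        rng.normal(fluor.mu_neg, fluor.sd_neg, size=N),
    )
    width = rng.normal(fluor.width_mean, fluor.width_sd, size=N)

    group = np.arange(N, dtype=np.int64)
    mr = pop.config.merge_rate
    if mr > 0 and N >= 2:
        p_pick = mr / (1.0 + mr)
        m = min(int(rng.binomial(N, p_pick)), N // 2)
        if m > 0:
            chosen = rng.choice(N, size=2 * m, replace=False)
            pairs = chosen.reshape(m, 2)
            group[pairs[:, 1]] = group[pairs[:, 0]]

    _, ginv = np.unique(group, return_inverse=True)
    nf = int(ginv.max()) + 1 if N else 0

    amp_f = np.full(nf, -np.inf)
    np.maximum.at(amp_f, ginv, amp)
    width_f = np.bincount(ginv, weights=width, minlength=nf)
    k_t_f = np.bincount(ginv, weights=pop.k_target, minlength=nf).astype(np.int64)
    k_b_f = np.bincount(ginv, weights=pop.k_background, minlength=nf).astype(np.int64)
    taq_f = np.bincount(ginv, weights=pop.taqman_positive, minlength=nf) > 0
    tgt_f = k_t_f > 0
    merged_f = np.bincount(ginv, minlength=nf) > 1

    return DropletField(
        population=pop,
        group_of=ginv,
        amplitude=amp_f,
        width=width_f,
        taqman_positive=taq_f,
        contains_target=tgt_f,
        merged=merged_f,
        k_target=k_t_f,
        k_background=k_b_f,
    )


# --------------------------------------------------------------- sorting

@dataclass
class SorterModel:
    """Amplitude threshold plus width gate; false sorts collect gate-negatives."""

    threshold: float = 0.45
    width_min: float = 0.0
    width_max: float = float("inf")
    false_sort_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.false_sort_rate <= 1:
            raise ValueError("false_sort_rate must be in [0, 1]")
        if self.width_min > self.width_max:
            raise ValueError("width_min > width_max")


@dataclass
class SortStats:
    n_screened: int
    n_sorted: int
    n_merged_sorted: int
    n_taqman_positive: int
    droplet_purity: float  # fraction of collected droplets containing target
    n_target_molecules: int
    n_background_molecules: int
    amplicon_molecules_removed: float = 0.0

    @property
    def molecule_purity(self) -> float:
        tot = self.n_target_molecules + self.n_background_molecules
        return self.n_target_molecules / tot if tot else float("nan")


@dataclass
class SortedPool:
    """Fragments recovered from collected droplets, plus TaqMan amplicon load."""

    fragments: FragmentSet  # the full fragment universe
    frag_ids: np.ndarray  # indices into ``fragments``
    copy_number: np.ndarray  # int64, >= 1, set by WGA
    amplicon_molecules: np.ndarray  # float (n_amplicons,)
    amplicons: list[ProbeAssay]
    stats: SortStats
    with_replacement: bool = False

    @property
    def n_fragments(self) -> int:
        return len(self.frag_ids)

    def summary_frame(self):
        import pandas as pd

        s = self.stats
        return pd.DataFrame(
            [
                {
                    "n_screened": s.n_screened,
                    "n_positive": s.n_taqman_positive,
                    "n_sorted": s.n_sorted,
                    "n_merged_sorted": s.n_merged_sorted,
                    "droplet_purity": s.droplet_purity,
                    "molecule_purity": s.molecule_purity,
                    "n_target_molecules": s.n_target_molecules,
                    "n_background_molecules": s.n_background_molecules,
                    "amplicon_molecules": float(self.amplicon_molecules.sum()),
                    "with_replacement": self.with_replacement,
                }
            ]
        )


def sort_droplets(
    field: DropletField,
    sorter: SorterModel,
    amplicons: list[ProbeAssay],
    rng: np.random.Generator | int | None = None,
) -> SortedPool:
    """Collect droplets passing the amplitude/width gates plus false sorts."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pop = field.population

    gate = (
        (field.amplitude >= sorter.threshold)
        & (field.width >= sorter.width_min)
        & (field.width <= sorter.width_max)
    )
    false = ~gate & (rng.random(field.n) < sorter.false_sort_rate)
    collected = gate | false

    n_sorted = int(collected.sum())
    if n_sorted == 0:
        warnings.warn("sorter gates excluded every droplet; returning empty pool")

    orig_collected = collected[field.group_of]
    flat_t = np.repeat(orig_collected, pop.k_target)
    flat_b = np.repeat(orig_collected, pop.k_background)
    retained = np.concatenate(
        (pop.target_ids[flat_t], pop.background_ids[flat_b])
    ).astype(np.int64)

    # TaqMan amplicons are produced only where PCR actually ran (detected droplets)
    detected_orig = pop.taqman_positive
    flat_det = np.repeat(orig_collected & detected_orig, pop.k_target)
    amp_frag_ids = pop.target_ids[flat_det]
    amp_counts = np.zeros(len(amplicons), dtype=np.float64)
    if len(amp_frag_ids) and pop.fragments.amplicon_id is not None:
        ids = pop.fragments.amplicon_id[amp_frag_ids]
        ids = ids[ids >= 0]
        amp_counts += np.bincount(ids, minlength=len(amplicons)) * float(
            pop.config.amplicon_copies
        )

    purity = float(field.contains_target[collected].mean()) if n_sorted else float("nan")
    stats = SortStats(
        n_screened=field.n,
        n_sorted=n_sorted,
        n_merged_sorted=int(field.merged[collected].sum()),
        n_taqman_positive=int(field.taqman_positive.sum()),
        droplet_purity=purity,
        n_target_molecules=int(field.k_target[collected].sum()),
        n_background_molecules=int(field.k_background[collected].sum()),
    )
    return SortedPool(
        fragments=pop.fragments,
        frag_ids=retained,
        copy_number=np.ones(len(retained), dtype=np.int64),
        amplicon_molecules=amp_counts,
        amplicons=list(amplicons),
        stats=stats,
        with_replacement=pop.with_replacement,
    )


def pool_from_fragments(fragments: FragmentSet) -> SortedPool:
    """Wrap an unsorted fragment set as a pool (the non-enriched reference)."""
    n = fragments.n
    stats = SortStats(
        n_screened=0,
        n_sorted=0,
        n_merged_sorted=0,
        n_taqman_positive=0,
        droplet_purity=float("nan"),
        n_target_molecules=int(fragments.is_target.sum())
        if fragments.is_target is not None
        else 0,
        n_background_molecules=n
        - (int(fragments.is_target.sum()) if fragments.is_target is not None else 0),
    )
    return SortedPool(
        fragments=fragments,
        frag_ids=np.arange(n, dtype=np.int64),
        copy_number=np.ones(n, dtype=np.int64),
        amplicon_molecules=np.zeros(0, dtype=np.float64),
        amplicons=[],
        stats=stats,
    )


# ------------------------------------------------- post-sort chemistry

def remove_amplicons(pool: SortedPool, residual_fraction: float = 0.0) -> SortedPool:
    """UDG treatment: scale amplicon molecules by ``residual_fraction``.

    Genomic fragments are untouched; the default removes every amplicon.
    """
    if not 0 <= residual_fraction <= 1:
        raise ValueError("residual_fraction must be in [0, 1]")
    removed = float(pool.amplicon_molecules.sum()) * (1.0 - residual_fraction)
    stats = replace(pool.stats, amplicon_molecules_removed=pool.stats.amplicon_molecules_removed + removed)
    return replace(
        pool,
        amplicon_molecules=pool.amplicon_molecules * residual_fraction,
        stats=stats,
    )


def wga_copy_factors(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Continuous lognormal copy factors rescaled to mean 1 (CV = sqrt(e^s^2-1))."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.ones(n)
    return rng.lognormal(0.0, sigma, size=n) * np.exp(-0.5 * sigma**2)


def wga_amplify(
    pool: SortedPool, sigma: float, rng: np.random.Generator | int | None = None
) -> SortedPool:
    """Multiple-displacement amplification as lognormal copy-number dispersion.

    Per-fragment copy number = max(1, round(lognormal factor with mean 1));
    sigma = 0 is the identity.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    factors = wga_copy_factors(pool.n_fragments, sigma, rng)
    copies = np.maximum(np.round(pool.copy_number * factors), 1).astype(np.int64)
    return replace(pool, copy_number=copies)
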