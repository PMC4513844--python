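"""Short-read simulation, per-base coverage tracks and duplicate marking.

Reads (default 50 bp, single-end) are drawn from a sorted fragment pool —
or from an unsorted whole-genome pool for the non-enriched reference — with
truth coordinates attached, so no aligner is involved. Source molecules are
chosen proportional to copy_number x eligible start positions (which is
proportional to copy number alone when fragments share a length, and gives
uniform per-base sampling over the genome for a whole-genome pool). Planted
variants are written into the read bases haplotype-aware (hom on both
haplotypes, het on haplotype 1; a fragment's haplotype is its genome copy
id mod 2), then i.i.d. substitution errors are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import BASES, GenomeModel, TruthVariant
from .droplets import SortedPool

__all__ = [
    "ReadModel",
    "ReadSet",
    "simulate_reads",
    "CoverageTrack",
    "coverage_from_intervals",
    "coverage_track",
    "mark_duplicates",
    "write_fastq",
    "reads_to_bed_frame",
]


@dataclass
class ReadModel:
    """Sequencing model: read length, error rate, and how many reads to draw.

    Give either ``n_reads`` or ``mean_depth`` (reads are then sized to hit
    that genome-wide mean).
    """

    read_length: int = 50
    error_rate: float = 0.001
    n_reads: int | None = None
    mean_depth: float | None = None

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")

    def resolve_n_reads(self, genome_size: int) -> int:
        if self.n_reads is not None:
            return int(self.n_reads)
        if self.mean_depth is not None:
            return int(round(self.mean_depth * genome_size / self.read_length))
        raise ValueError("set n_reads or mean_depth")


@dataclass
class ReadSet:
    """Simulated reads as parallel arrays plus an (n, L) base-code matrix."""

    chrom_names: list[str]
    chrom_idx: np.ndarray  # int32
    start: np.ndarray  # int64
    strand: np.ndarray  # int8, 0 = '+', 1 = '-'
    hap: np.ndarray  # int8
    frag_id: np.ndarray  # int64, -1 for amplicon-derived reads
    bases: np.ndarray  # uint8 (n, L)
    read_length: int
    n_skipped_short: int = 0

    @property
    def n(self) -> int:
        return len(self.start)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.read_length

    def subset(self, idx: np.ndarray) -> "ReadSet":
        return ReadSet(
            chrom_names=self.chrom_names,
            chrom_idx=self.chrom_idx[idx],
            start=self.start[idx],
            strand=self.strand[idx],
            hap=self.hap[idx],
            frag_id=self.frag_id[idx],
            bases=self.bases[idx],
            read_length=self.read_length,
            n_skipped_short=self.n_skipped_short,
        )


def _apply_variants(
    reads: "ReadSet", genome: GenomeModel, variants: list[TruthVariant]
) -> None:
    """Write alt alleles into read bases, haplotype-aware. In-place."""
    from .genome import encode_bases

    if not variants:
        return
    L = reads.read_length
    for ci, chrom in enumerate(genome.names):
        mask = reads.chrom_idx == ci
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        order = idx[np.argsort(reads.start[idx], kind="stable")]
        starts_sorted = reads.start[order]
        for v in variants:
            if v.chrom != chrom:
                continue
            lo = np.searchsorted(starts_sorted, v.pos - L + 1, side="left")
            hi = np.searchsorted(starts_sorted, v.pos, side="right")
            if hi <= lo:
                continue
            hit = order[lo:hi]
            if v.zygosity == "het":
                hit = hit[reads.hap[hit] == 1]
            if len(hit) == 0:
                continue
            offs = (v.pos - reads.start[hit]).astype(np.int64)
            reads.bases[hit, offs] = encode_bases(v.alt)[0]


def simulate_reads(
    pool: SortedPool,
    genome: GenomeModel,
    model: ReadModel,
    rng: np.random.Generator | int | None = None,
    variants: list[TruthVariant] | None = None,
) -> ReadSet:
    """Draw reads from a pool: uniform start within the source molecule,
    uniform strand, bases from the genome with variants then errors applied.

    Residual TaqMan amplicon molecules participate weighted by their copy
    count, so carry-over shows up as a coverage spike over the amplicon.
    Molecules shorter than the read length are skipped and counted.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L = model.read_length

    frags = pool.fragments
    f_chrom = frags.chrom_idx[pool.frag_ids]
    f_start = frags.start[pool.frag_ids]
    f_end = frags.end[pool.frag_ids]
    f_copy = pool.copy_number.astype(np.float64)
    f_hap = (frags.copy_id[pool.frag_ids] % 2).astype(np.int8)
    f_id = pool.frag_ids

    # append residual amplicon molecules as extra source intervals (hap 0)
    if pool.amplicon_molecules.size and pool.amplicon_molecules.sum() > 0:
        keep = np.flatnonzero(pool.amplicon_molecules > 0)
        a_chrom = np.array(
            [frags.chrom_names.index(pool.amplicons[i].chrom) for i in keep],
            dtype=np.int32,
        )
        a_start = np.array([pool.amplicons[i].start for i in keep], dtype=np.int64)
        a_end = np.array([pool.amplicons[i].end for i in keep], dtype=np.int64)
        f_chrom = np.concatenate((f_chrom, a_chrom))
        f_start = np.concatenate((f_start, a_start))
        f_end = np.concatenate((f_end, a_end))
        f_copy = np.concatenate((f_copy, pool.amplicon_molecules[keep]))
        f_hap = np.concatenate((f_hap, np.zeros(len(keep), dtype=np.int8)))
        f_id = np.concatenate((f_id, np.full(len(keep), -1, dtype=np.int64)))

    if len(f_start) == 0:
        raise ValueError("cannot simulate reads from an empty pool")

    positions = np.maximum(f_end - f_start - L + 1, 0).astype(np.float64)
    n_short = int((positions == 0).sum())
    weights = f_copy * positions
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("no pool molecule is long enough to yield a read")

    n_reads = model.resolve_n_reads(genome.size)
    src = rng.choice(len(weights), size=n_reads, p=weights / wsum)
    npos = positions[src].astype(np.int64)
    starts = f_start[src] + (rng.random(n_reads) * npos).astype(np.int64)
    strand = rng.integers(0, 2, size=n_reads).astype(np.int8)

    # gather reference bases
    bases = np.empty((n_reads, L), dtype=np.uint8)
    offs = np.arange(L, dtype=np.int64)
    chrom_idx = f_chrom[src].astype(np.int32)
    for ci, chrom in enumerate(genome.names):
        m = np.flatnonzero(chrom_idx == ci)
        if len(m) == 0:
            continue
        bases[m] = genome.seq[chrom][starts[m, None] + offs[None, :]]

    reads = ReadSet(
        chrom_names=list(genome.names),
        chrom_idx=chrom_idx,
        start=starts,
        strand=strand,
        hap=f_hap[src],
        frag_id=f_id[src],
        bases=bases,
        read_length=L,
        n_skipped_short=n_short,
    )
    if variants:
        _apply_variants(reads, genome, variants)

    if model.error_rate > 0:
        err = rng.random((n_reads, L)) < model.error_rate
        n_err = int(err.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            reads.bases[err] = (reads.bases[err] + shift) % 4
    return reads


# ------------------------------------------------------------- coverage

@dataclass
class CoverageTrack:
    """Per-base depth over a genome; the substrate for all window statistics."""

    chrom_names: list[str]
    depth: list[np.ndarray]

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.depth[self.chrom_names.index(chrom)]

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(d) for n, d in zip(self.chrom_names, self.depth)}

    @property
    def genome_size(self) -> int:
        return sum(len(d) for d in self.depth)

    @property
    def total_bases(self) -> float:
        return float(sum(d.sum() for d in self.depth))

    @property
    def mean(self) -> float:
        return self.total_bases / self.genome_size

    def same_layout(self, other: "CoverageTrack") -> bool:
        return self.chrom_names == other.chrom_names and self.lengths == other.lengths

    def scaled(self, c: float) -> "CoverageTrack":
        return CoverageTrack(self.chrom_names, [d * c for d in self.depth])


def coverage_from_intervals(
    chrom_names: list[str],
    chrom_lengths: dict[str, int],
    chrom_idx: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    weights: np.ndarray | None = None,
) -> CoverageTrack:
    """Depth track from weighted intervals via difference arrays (exact)."""
    depth: list[np.ndarray] = []
    flt = weights is not None and not np.issubdtype(np.asarray(weights).dtype, np.integer)
    dtype = np.float64 if flt else np.int64
    for ci, name in enumerate(chrom_names):
        clen = chrom_lengths[name]
        m = np.flatnonzero(chrom_idx == ci)
        diff = np.zeros(clen + 1, dtype=dtype)
        if len(m):
            s, e = start[m], end[m]
            if (s < 0).any() or (e > clen).any():
                raise ValueError(f"interval outside chromosome {name}")
            w = np.ones(len(m), dtype=dtype) if weights is None else np.asarray(weights)[m]
            np.add.at(diff, s, w)
            np.add.at(diff, e, -w)
        depth.append(np.cumsum(diff[:-1], dtype=dtype))
    return CoverageTrack(chrom_names=list(chrom_names), depth=depth)


def coverage_track(reads: ReadSet, genome: GenomeModel) -> CoverageTrack:
    """Per-base depth from reads; sum of depths equals sum of read lengths."""
    return coverage_from_intervals(
        list(genome.names),
        genome.lengths,
        reads.chrom_idx,
        reads.start,
        reads.end,
    )


def fragment_coverage(pool: SortedPool, genome: GenomeModel) -> CoverageTrack:
    """Copy-number-weighted fragment depth (before sequencing)."""
    frags = pool.fragments
    return coverage_from_intervals(
        list(genome.names),
        genome.lengths,
        frags.chrom_idx[pool.frag_ids],
        frags.start[pool.frag_ids],
        frags.end[pool.frag_ids],
        weights=pool.copy_number,
    )


# ------------------------------------------------------------ duplicates

def mark_duplicates(reads: ReadSet) -> tuple[float, ReadSet]:
    """Single-end duplicate criterion: same (chromosome, 5' start, strand).

    Keep-first after a stable sort; returns (duplicate fraction, dedup reads).
    """
    if reads.n == 0:
        return 0.0, reads
    order = np.lexsort((reads.strand, reads.start, reads.chrom_idx))
    c, s, st = reads.chrom_idx[order], reads.start[order], reads.strand[order]
    same = np.zeros(reads.n, dtype=bool)
    same[1:] = (c[1:] == c[:-1]) & (s[1:] == s[:-1]) & (st[1:] == st[:-1])
    dup_idx = order[same]
    frac = len(dup_idx) / reads.n
    keep = np.ones(reads.n, dtype=bool)
    keep[dup_idx] = False
    return frac, reads.subset(np.flatnonzero(keep))


# ---------------------------------------------------------------- export

def write_fastq(reads: ReadSet, path) -> None:
    qual = "I" * reads.read_length
    with open(path, "w") as fh:
        for i in range(reads.n):
            seq = BASES[reads.bases[i]].tobytes().decode("ascii")
            chrom = reads.chrom_names[reads.chrom_idx[i]]
            strand = "+" if reads.strand[i] == 0 else "-"
            fh.write(f"@read{i}:{chrom}:{reads.start[i]}:{strand}\n{seq}\n+\n{qual}\n")


def reads_to_bed_frame(reads: ReadSet):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [reads.chrom_names[i] for i in reads.chrom_idx],
            "start": reads.start,
            "end": reads.end,
            "name": [f"read{i}" for i in range(reads.n)],
            "score": 0,
            "strand": np.where(reads.strand == 0, "+", "-"),
        }
    )
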