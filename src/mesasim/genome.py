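"""Synthetic reference genomes, TaqMan probe panels and planted variants.

A desk-scale stand-in for the targeted-enrichment experiment: a small
multi-chromosome genome with a handful of probe-targeted loci on one
chromosome, ~100-bp TaqMan amplicons centred in each locus, and planted
single-nucleotide variants with known zygosity for concordance evaluation.

Coordinates are 0-based half-open everywhere in memory and in BED output;
VCF output converts to 1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeModel",
    "ProbeAssay",
    "TargetLocus",
    "TruthVariant",
    "SizingError",
    "build_genome",
    "plant_variants",
    "encode_bases",
    "decode_bases",
]

_BASE_BYTES = b"ACGT"
BASES = np.frombuffer(_BASE_BYTES, dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASE_BYTES):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case

#: default panel names mirroring a multiplexed three-assay / five-locus design
DEFAULT_LOCUS_NAMES = ("NFAT5", "CLEC18A", "CLEC18C", "COG4", "CLEC18B")

DEFAULT_WINDOW_SIZES = (50_000, 100_000, 150_000, 200_000)


class SizingError(ValueError):
    """Requested loci cannot be placed on the requested genome."""


def encode_bases(s: str) -> np.ndarray:
    """A/C/G/T string -> uint8 codes 0..3."""
    a = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    codes = _CODE[a]
    if (codes == 255).any():
        bad = chr(a[codes == 255][0])
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return codes


def decode_bases(codes: np.ndarray) -> str:
    return BASES[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


@dataclass(frozen=True)
class ProbeAssay:
    """A TaqMan assay: a short (~100 bp) amplicon that identifies a locus.

    The amplicon is the only prior sequence information the workflow needs;
    fragments are scored positive only if they fully contain it (a partial
    fragment lacks a primer site and cannot amplify).
    """

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        length = self.end - self.start
        if not 40 <= length <= 500:
            raise ValueError(f"amplicon length {length} outside [40, 500] bp")
        if self.start < 0:
            raise ValueError("amplicon start < 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TruthVariant:
    """A planted SNP with known zygosity ('hom' or 'het')."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    zygosity: str = "hom"

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt equals ref")
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"zygosity {self.zygosity!r} not in ('hom', 'het')")


@dataclass
class TargetLocus:
    """A probe-targeted locus and the analysis window sizes centred on it."""

    assay: ProbeAssay
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    variants: list[TruthVariant] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.assay.chrom

    @property
    def midpoint(self) -> int:
        return self.assay.midpoint

    def window(self, size: int) -> tuple[int, int]:
        """Probe-centred window [mid - size/2, mid + size/2)."""
        half = size // 2
        return self.midpoint - half, self.midpoint - half + size


@dataclass
class GenomeModel:
    """A small reference genome held as per-chromosome uint8 code arrays."""

    names: list[str]
    seq: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name in self.names:
            if len(self.seq[name]) == 0:
                raise ValueError(f"chromosome {name} has length 0")

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(self.seq[n]) for n in self.names}

    @property
    def size(self) -> int:
        """Total genome size G in bp — the denominator of genome-wide means."""
        return sum(len(self.seq[n]) for n in self.names)

    def chrom_index(self, name: str) -> int:
        return self.names.index(name)

    def base(self, chrom: str, pos: int) -> str:
        return decode_bases(self.seq[chrom][pos : pos + 1])

    def substring(self, chrom: str, start: int, end: int) -> str:
        return decode_bases(self.seq[chrom][start:end])

    def same_layout(self, other: "GenomeModel") -> bool:
        return self.names == other.names and self.lengths == other.lengths


def _place_loci(
    chrom_len: int, n_loci: int, margin: int, spacing: int, rng: np.random.Generator
) -> np.ndarray:
    """n sorted midpoints in [margin, chrom_len - margin) separated by >= spacing."""
    free = chrom_len - 2 * margin - (n_loci - 1) * spacing
    if n_loci < 1 or free < 0:
        raise SizingError(
            f"cannot place {n_loci} loci with spacing {spacing} and margin {margin} "
            f"on a {chrom_len} bp chromosome"
        )
    u = np.sort(rng.integers(0, free + 1, size=n_loci))
    return margin + u + spacing * np.arange(n_loci)


def build_genome(
    chrom_sizes: dict[str, int] | None = None,
    n_loci: int = 5,
    target_chrom: str | None = None,
    amplicon_length: int = 100,
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES,
    locus_spacing: int | None = None,
    seed: int = 0,
) -> tuple[GenomeModel, list[TargetLocus]]:
    """Generate an i.i.d. uniform A/C/G/T genome and a probe panel on one chromosome.

    Defaults give the desk-scale stand-in: two chromosomes (5 Mb "16" carrying
    five loci, plus a 1 Mb "1" of pure background), 100-bp amplicons, analysis
    windows of 50-200 kb. Deterministic for a fixed seed.
    """
    if chrom_sizes is None:
        chrom_sizes = {"16": 5_000_000, "1": 1_000_000}
    names = list(chrom_sizes)
    if target_chrom is None:
        target_chrom = max(names, key=lambda n: chrom_sizes[n])
    if target_chrom not in chrom_sizes:
        raise ValueError(f"target chromosome {target_chrom!r} not in chrom_sizes")

    max_win = max(window_sizes) if window_sizes else 0
    spacing = max_win if locus_spacing is None else locus_spacing
    margin = max(max_win // 2, amplicon_length)
    if n_loci >= 1 and chrom_sizes[target_chrom] < 2 * max_win:
        raise SizingError(
            f"target chromosome ({chrom_sizes[target_chrom]} bp) shorter than "
            f"2x the largest analysis window ({max_win} bp)"
        )

    rng = np.random.default_rng(seed)
    seq = {n: rng.integers(0, 4, size=chrom_sizes[n], dtype=np.uint8).astype(np.uint8)
           for n in names}
    genome = GenomeModel(names=names, seq=seq)

    loci: list[TargetLocus] = []
    if n_loci >= 1:
        mids = _place_loci(chrom_sizes[target_chrom], n_loci, margin, spacing, rng)
        for i, mid in enumerate(mids):
            name = (
                DEFAULT_LOCUS_NAMES[i]
                if n_loci <= len(DEFAULT_LOCUS_NAMES)
                else f"locus{i + 1:02d}"
            )
            start = int(mid) - amplicon_length // 2
            assay = ProbeAssay(name=name, chrom=target_chrom, start=start,
                               end=start + amplicon_length)
            loci.append(TargetLocus(assay=assay, window_sizes=tuple(window_sizes)))
    return genome, loci


def plant_variants(
    genome: GenomeModel,
    density: float,
    het_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
    max_retries: int = 10,
) -> list[TruthVariant]:
    """Plant SNPs at the given per-bp density, unique positions, sorted output.

    Each variant's alternate allele is one of the three non-reference bases;
    zygosity is het with probability ``het_fraction`` (het alleles live on
    haplotype 1, hom alleles on both haplotypes downstream).
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if not 0 <= het_fraction <= 1:
        raise ValueError("het_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    out: list[TruthVariant] = []
    for chrom in genome.names:
        length = len(genome.seq[chrom])
        n = int(rng.binomial(length, min(density, 1.0)))
        if n == 0:
            continue
        if n > length:
            raise ValueError("variant density too high for chromosome length")
        pos = None
        for _ in range(max_retries):
            cand = np.unique(rng.integers(0, length, size=n))
            if len(cand) == n:
                pos = cand
                break
        if pos is None:  # fall back: sample without replacement outright
            pos = np.sort(rng.choice(length, size=n, replace=False))
        ref_codes = genome.seq[chrom][pos]
        alt_codes = (ref_codes + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
        het = rng.random(n) < het_fraction
        for p, rc, ac, h in zip(pos, ref_codes, alt_codes, het):
            out.append(
                TruthVariant(
                    chrom=chrom,
                    pos=int(p),
                    ref=decode_bases(np.array([rc])),
                    alt=decode_bases(np.array([ac])),
                    zygosity="het" if h else "hom",
                )
            )
    out.sort(key=lambda v: (genome.chrom_index(v.chrom), v.pos))
    return out
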