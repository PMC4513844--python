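"""Minimal pileup-based SNP calling with depth/quality filters.

The caller is deliberately simple — candidate sites need >= 2 non-reference
bases, the phred-scaled quality is the binomial tail probability of seeing
that many errors by chance, and a call PASSes only with read depth >= 10 and
quality >= 10. The point is the filter thresholds and the enrichment effect
on sensitivity, not genotyping sophistication. Duplicate reads are removed
before counting by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel, TruthVariant, decode_bases
from .reads import ReadSet, mark_duplicates

__all__ = [
    "Pileup",
    "pileup",
    "VariantCallSet",
    "call_variants",
    "ConcordanceReport",
    "concordance",
]

MAX_QUAL = 3000.0


@dataclass
class Pileup:
    """Per-position base counts (4 x chromosome length) per chromosome."""

    chrom_names: list[str]
    counts: dict[str, np.ndarray]  # (4, L) int32
    ref_codes: dict[str, np.ndarray]

    def depth(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].sum(axis=0)


def pileup(
    reads: ReadSet, genome: GenomeModel, chunk_size: int = 200_000
) -> Pileup:
    """Count A/C/G/T per genome position from read base matrices."""
    counts = {
        name: np.zeros((4, len(genome.seq[name])), dtype=np.int32)
        for name in genome.names
    }
    L = reads.read_length
    offs = np.arange(L, dtype=np.int64)
    for ci, name in enumerate(genome.names):
        idx = np.flatnonzero(reads.chrom_idx == ci)
        clen = len(genome.seq[name])
        flat = counts[name].reshape(-1)
        for a in range(0, len(idx), chunk_size):
            sel = idx[a : a + chunk_size]
            pos = (reads.start[sel, None] + offs[None, :]).reshape(-1)
            base = reads.bases[sel].reshape(-1).astype(np.int64)
            flat += np.bincount(base * clen + pos, minlength=4 * clen).astype(np.int32)
    return Pileup(
        chrom_names=list(genome.names),
        counts=counts,
        ref_codes={n: genome.seq[n] for n in genome.names},
    )


@dataclass
class VariantCallSet:
    """Called SNPs as a DataFrame (chrom, pos, ref, alt, depth, alt_count,
    qual, genotype, filter)."""

    df: pd.DataFrame
    chrom_names: list[str] = field(default_factory=list)

    @property
    def passed(self) -> pd.DataFrame:
        return self.df[self.df["filter"] == "PASS"]

    def to_vcf(self, path, chrom_lengths: dict[str, int] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt base count">\n')
            fh.write('##INFO=<ID=GT,Number=1,Type=String,Description="Simple genotype">\n')
            fh.write('##FILTER=<ID=LowDepth,Description="Depth below threshold">\n')
            fh.write('##FILTER=<ID=LowQual,Description="Quality below threshold">\n')
            fh.write('##FILTER=<ID=LowAF,Description="Alt fraction below het range">\n')
            if chrom_lengths:
                for n, l in chrom_lengths.items():
                    fh.write(f"##contig=<ID={n},length={l}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in self.df.itertuples():
                fh.write(
                    f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t{r.qual:.2f}\t"
                    f"{r.filter}\tDP={r.depth};AC={r.alt_count};GT={r.genotype}\n"
                )


def call_variants(
    pile: Pileup,
    min_depth: int = 10,
    min_qual: float = 10.0,
    error_rate: float = 1e-3,
    min_alt_count: int = 2,
    het_range: tuple[float, float] = (0.2, 0.8),
    hom_min: float = 0.8,
) -> VariantCallSet:
    """Call SNPs from a pileup.

    Quality is -10*log10 P(X >= alt_count), X ~ Binomial(depth, error_rate):
    how surprising the alternate support would be under errors alone. A site
    PASSes iff depth >= min_depth and quality >= min_qual; sub-threshold
    sites are reported with LowDepth/LowQual/LowAF filter labels.
    """
    if not 0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    rows = []
    for chrom in pile.chrom_names:
        c = pile.counts[chrom]
        depth = c.sum(axis=0)
        ref = pile.ref_codes[chrom].astype(np.int64)
        pos_all = np.arange(c.shape[1])
        nonref = c.copy()
        nonref[ref, pos_all] = 0
        alt_code = np.argmax(nonref, axis=0)
        alt_count = nonref[alt_code, pos_all]
        cand = np.flatnonzero(alt_count >= min_alt_count)
        if len(cand) == 0:
            continue
        d = depth[cand].astype(np.int64)
        ac = alt_count[cand].astype(np.int64)
        sf = stats.binom.sf(ac - 1, d, error_rate)
        qual = np.where(sf > 0, -10.0 * np.log10(np.maximum(sf, 1e-300)), MAX_QUAL)
        qual = np.minimum(qual, MAX_QUAL)
        af = ac / d
        genotype = np.where(af >= hom_min, "1/1", np.where(af >= het_range[0], "0/1", "./."))
        filt = np.full(len(cand), "PASS", dtype=object)
        low_af = af < het_range[0]
        low_d = d < min_depth
        low_q = qual < min_qual
        for i in range(len(cand)):
            tags = []
            if low_d[i]:
                tags.append("LowDepth")
            if low_q[i]:
                tags.append("LowQual")
            if low_af[i]:
                tags.append("LowAF")
            if tags:
                filt[i] = ";".join(tags)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": cand,
                    "ref": [decode_bases(np.array([r])) for r in ref[cand]],
                    "alt": [decode_bases(np.array([a])) for a in alt_code[cand]],
                    "depth": d,
                    "alt_count": ac,
                    "qual": qual,
                    "genotype": genotype,
                    "filter": filt,
                }
            )
        )
    cols = ["chrom", "pos", "ref", "alt", "depth", "alt_count", "qual", "genotype", "filter"]
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=cols)
    )
    return VariantCallSet(df=df, chrom_names=list(pile.chrom_names))


def call_variants_from_reads(
    reads: ReadSet,
    genome: GenomeModel,
    dedup: bool = True,
    **kwargs,
) -> VariantCallSet:
    """Convenience wrapper: optional duplicate removal, pileup, then calling."""
    if dedup:
        _, reads = mark_duplicates(reads)
    return call_variants(pileup(reads, genome), **kwargs)


@dataclass
class ConcordanceReport:
    """PASS-call concordance against planted truth, overall and in windows."""

    n_calls_pass: int
    tp: int
    fp: int
    fn: int
    precision: float  # nan when no PASS calls
    recall: float
    n_truth: int
    calls_pass_in_windows: int = 0
    tp_in_windows: int = 0
    truth_in_windows: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _in_windows(chrom: np.ndarray, pos: np.ndarray, windows) -> np.ndarray:
    m = np.zeros(len(pos), dtype=bool)
    for c, s, e in windows:
        m |= (chrom == c) & (pos >= s) & (pos < e)
    return m


def concordance(
    calls: VariantCallSet,
    truth: list[TruthVariant],
    windows=None,
) -> ConcordanceReport:
    """Exact (chrom, pos, alt) matching of PASS calls against truth.

    ``windows`` is an optional list of (chrom, start, end) target regions —
    the probe-centred 50-kb windows in the standard analysis.
    """
    for v in truth:
        if calls.chrom_names and v.chrom not in calls.chrom_names:
            raise ValueError(f"truth chromosome {v.chrom!r} unknown to the call set")
    passed = calls.passed
    call_keys = set(zip(passed["chrom"], passed["pos"], passed["alt"]))
    truth_keys = {(v.chrom, v.pos, v.alt) for v in truth}
    tp = len(call_keys & truth_keys)
    fp = len(call_keys - truth_keys)
    fn = len(truth_keys - call_keys)
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")

    rep = ConcordanceReport(
        n_calls_pass=len(passed),
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        n_truth=len(truth_keys),
    )
    if windows:
        chrom = passed["chrom"].to_numpy()
        pos = passed["pos"].to_numpy()
        inw = _in_windows(chrom, pos, windows)
        rep.calls_pass_in_windows = int(inw.sum())
        keys_in = set(zip(chrom[inw], pos[inw], passed["alt"].to_numpy()[inw]))
        rep.tp_in_windows = len(keys_in & truth_keys)
        t_chrom = np.array([v.chrom for v in truth], dtype=object)
        t_pos = np.array([v.pos for v in truth], dtype=np.int64)
        if len(truth):
            rep.truth_in_windows = int(_in_windows(t_chrom, t_pos, windows).sum())
    return rep
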