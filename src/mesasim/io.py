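"""Readers and writers for the plain-text interchange formats.

FASTA through Bio.SeqIO, VCF reading through pysam, BED/TSV through pandas.
VCF output is a minimal hand-written v4.2 emitter (CHROM POS ID REF ALT QUAL
FILTER INFO) because only that subset is part of the interface. Depth tracks
are stored as bedGraph run-length text covering every base (zero runs
included) so chromosome lengths round-trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeModel, TruthVariant, decode_bases, encode_bases

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_truth_vcf",
    "read_truth_vcf",
    "write_bedgraph",
    "read_bedgraph",
]


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: GenomeModel, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(decode_bases(genome.seq[name])), id=name, description="")
        for name in genome.names
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> GenomeModel:
    names: list[str] = []
    seq: dict[str, np.ndarray] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seq[rec.id] = encode_bases(str(rec.seq))
    if not names:
        raise ValueError(f"no sequences in {path}")
    return GenomeModel(names=names, seq=seq)


# ------------------------------------------------------------------ BED

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write BED6 (0-based half-open). Missing optional columns are filled."""
    out = df.copy()
    if "name" not in out:
        out["name"] = "."
    if "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "."
    out[_BED_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = _BED_COLS[: df.shape[1]]
    return df


# ------------------------------------------------------------------ VCF

def write_truth_vcf(
    genome: GenomeModel, variants: list[TruthVariant], path: str | Path
) -> None:
    """Minimal VCF v4.2 with a ZYG INFO key; positions converted to 1-based."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ZYG,Number=1,Type=String,Description="Planted zygosity">\n')
        for name in genome.names:
            fh.write(f"##contig=<ID={name},length={len(genome.seq[name])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tZYG={v.zygosity}\n"
            )


def read_truth_vcf(path: str | Path) -> list[TruthVariant]:
    out: list[TruthVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            zyg = rec.info.get("ZYG", "hom")
            out.append(
                TruthVariant(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    zygosity=str(zyg),
                )
            )
    return out


# ------------------------------------------------------------- bedGraph

def write_bedgraph(track, path: str | Path) -> None:
    """Run-length encode a CoverageTrack, including zero runs."""
    with open(path, "w") as fh:
        for name, depth in zip(track.chrom_names, track.depth):
            d = np.asarray(depth)
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(d)]))
            vals = d[starts]
            for s, e, v in zip(starts, ends, vals):
                val = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{name}\t{s}\t{e}\t{val}\n")


def read_bedgraph(path: str | Path):
    from .reads import CoverageTrack  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "depth"], dtype={0: str})
    names: list[str] = []
    arrays: list[np.ndarray] = []
    for chrom, grp in df.groupby("chrom", sort=False):
        length = int(grp["end"].max())
        arr = np.zeros(length, dtype=np.float64)
        for s, e, v in zip(grp["start"], grp["end"], grp["depth"]):
            arr[s:e] = v
        if np.allclose(arr, np.round(arr)):
            arr = arr.astype(np.int64)
        names.append(str(chrom))
        arrays.append(arr)
    return CoverageTrack(chrom_names=names, depth=arrays)
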