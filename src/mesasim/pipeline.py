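"""Seeded end-to-end runs: genome -> droplets -> sort -> reads -> analyses.

A run builds the synthetic genome and probe panel, simulates droplet
enrichment (or skips it for the non-enriched reference sample), sequences
the pool, and produces every downstream report: droplet statistics, window
tables, fold enrichments, FWHM fragment-size estimates, uniformity,
variant calls and truth concordance. All stages draw from named substreams
of one global seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from ._rng import spawn_seed, substream
from .analytic import whole_genome_background_ratio
from .droplets import (
    DropletConfig,
    FluorescenceModel,
    FragmentModel,
    SorterModel,
    SortedPool,
    encapsulate,
    fluoresce,
    fragment_genome,
    classify_targets,
    pool_from_fragments,
    remove_amplicons,
    sort_droplets,
    wga_amplify,
)
from .enrichment import (
    background_threshold,
    coverage_uniformity,
    fold_enrichment,
    fwhm_fragment_size,
    specificity_scan,
    window_means,
)
from .genome import GenomeModel, TargetLocus, build_genome, plant_variants
from .reads import ReadModel, coverage_track, mark_duplicates, simulate_reads
from .variants import VariantCallSet, call_variants, concordance, pileup

log = logging.getLogger("mesasim")

__all__ = ["RunConfig", "RunResult", "run_pipeline", "compare_runs"]


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run.

    ``lambda_b=None`` derives the background load from whole-genome input
    DNA at the configured dilution (fixed molar composition). ``mode`` is
    "enriched" (full droplet workflow) or "reference" (unsorted DNA,
    equal read count).
    """

    seed: int = 0
    mode: str = "enriched"
    # genome / panel
    chrom_sizes: dict = field(default_factory=lambda: {"16": 5_000_000, "1": 1_000_000})
    n_loci: int = 5
    target_chrom: str | None = None
    amplicon_length: int = 100
    window_sizes: tuple = (50_000, 100_000, 150_000, 200_000)
    variant_density: float = 1e-3
    het_fraction: float = 0.5
    # fragments
    fragment_mean: float = 52_400.0
    fragment_sd: float = 5_706.0
    n_genome_copies: int = 20
    # droplets / sorting
    n_droplets: int = 1_000_000
    lambda_t: float = 0.013085
    lambda_b: float | None = None
    merge_rate: float = 0.02
    pcr_failure_rate: float = 0.02
    false_sort_rate: float = 0.0005
    sort_threshold: float = 0.45
    amplicon_copies: int = 200
    residual_amplicon: float = 0.0
    sigma_wga: float = 0.8
    # sequencing
    n_reads: int = 300_000
    read_length: int = 50
    error_rate: float = 1e-3
    dedup_for_calling: bool = True
    # analysis
    window: int = 20_000
    step: int = 2_000
    min_depth: int = 10
    min_qual: float = 10.0
    uniformity_depths: tuple = (10, 30)

    @classmethod
    def preset(cls, name: str, seed: int = 0, **overrides) -> "RunConfig":
        """'test' (2.5 Mb genome, 1e5 droplets) or 'desk' (6 Mb, 1e6)."""
        if name == "test":
            base = dict(
                chrom_sizes={"16": 2_000_000, "1": 500_000},
                n_droplets=100_000,
                n_reads=150_000,
            )
        elif name == "desk":
            base = dict(
                chrom_sizes={"16": 5_000_000, "1": 1_000_000},
                n_droplets=1_000_000,
                n_reads=300_000,
            )
        else:
            raise ValueError(f"unknown preset {name!r}")
        base.update(overrides)
        return cls(seed=seed, **base)

    def validate(self) -> None:
        bad = []
        if self.mode not in ("enriched", "reference"):
            bad.append("mode")
        if self.n_droplets < 1:
            bad.append("n_droplets")
        if self.lambda_t < 0 or (self.lambda_b is not None and self.lambda_b < 0):
            bad.append("lambda_t/lambda_b")
        for key in ("merge_rate", "pcr_failure_rate", "false_sort_rate",
                    "residual_amplicon"):
            v = getattr(self, key)
            if not 0 <= v <= 1:
                bad.append(key)
        if self.n_reads < 1:
            bad.append("n_reads")
        if self.step > self.window:
            bad.append("step")
        if bad:
            raise ValueError(f"invalid configuration keys: {', '.join(sorted(set(bad)))}")

    def resolved_lambda_b(self, genome_size: int) -> float:
        if self.lambda_b is not None:
            return self.lambda_b
        r = whole_genome_background_ratio(
            genome_size, self.fragment_mean, max(self.n_loci, 1)
        )
        return r * self.lambda_t

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_sizes"] = list(self.window_sizes)
        d["uniformity_depths"] = list(self.uniformity_depths)
        return d


@dataclass
class RunResult:
    config: RunConfig
    genome: GenomeModel
    loci: list[TargetLocus]
    truth: list
    pool: SortedPool
    track: "object"  # CoverageTrack
    calls: VariantCallSet
    summary: dict
    windows: pd.DataFrame
    enrichment: pd.DataFrame
    outdir: Path | None = None


def _locus_windows(loci: list[TargetLocus], size: int):
    return [(l.chrom, *l.window(size)) for l in loci]


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute the full workflow; write artifacts if ``outdir`` is given."""
    cfg.validate()
    seed = cfg.seed
    log.info("building genome (%s)", cfg.chrom_sizes)
    genome, loci = build_genome(
        chrom_sizes=dict(cfg.chrom_sizes),
        n_loci=cfg.n_loci,
        target_chrom=cfg.target_chrom,
        amplicon_length=cfg.amplicon_length,
        window_sizes=tuple(cfg.window_sizes),
        seed=spawn_seed(seed, "genome"),
    )
    amplicons = [l.assay for l in loci]
    truth = plant_variants(
        genome, cfg.variant_density, cfg.het_fraction, substream(seed, "variants")
    )

    frag_model = FragmentModel(mean_length=cfg.fragment_mean, sd_length=cfg.fragment_sd)
    frags = fragment_genome(genome, frag_model, cfg.n_genome_copies,
                            substream(seed, "fragments"))
    classify_targets(frags, amplicons)
    log.info("fragmented %d copies -> %d fragments (%d target)",
             cfg.n_genome_copies, frags.n, int(frags.is_target.sum()))

    lam_b = cfg.resolved_lambda_b(genome.size)
    if cfg.mode == "enriched":
        dcfg = DropletConfig(
            n_droplets=cfg.n_droplets,
            lambda_t=cfg.lambda_t,
            lambda_b=lam_b,
            merge_rate=cfg.merge_rate,
            pcr_failure_rate=cfg.pcr_failure_rate,
            amplicon_copies=cfg.amplicon_copies,
        )
        pop = encapsulate(frags, dcfg, amplicons, substream(seed, "encapsulate"))
        fld = fluoresce(pop, FluorescenceModel(), substream(seed, "fluoresce"))
        sorter = SorterModel(threshold=cfg.sort_threshold,
                             false_sort_rate=cfg.false_sort_rate)
        pool = sort_droplets(fld, sorter, amplicons, substream(seed, "sort"))
        log.info("sorted %d/%d droplets, droplet purity %.3f",
                 pool.stats.n_sorted, pool.stats.n_screened, pool.stats.droplet_purity)
        pool = remove_amplicons(pool, cfg.residual_amplicon)
        pool = wga_amplify(pool, cfg.sigma_wga, substream(seed, "wga"))
    else:
        pool = pool_from_fragments(frags)

    rmodel = ReadModel(read_length=cfg.read_length, error_rate=cfg.error_rate,
                       n_reads=cfg.n_reads)
    reads = simulate_reads(pool, genome, rmodel, substream(seed, f"reads:{cfg.mode}"),
                           variants=truth)
    dup_frac, dedup = mark_duplicates(reads)
    track = coverage_track(reads, genome)
    log.info("%d reads, duplicate fraction %.4f, mean depth %.2f",
             reads.n, dup_frac, track.mean)

    windows = window_means(track, cfg.window, cfg.step)
    target_chrom = loci[0].chrom if loci else genome.names[0]
    excl = _locus_windows(loci, max(cfg.window_sizes)) if loci else None
    bg_thresh = background_threshold(track, cfg.window, cfg.step, exclude=excl,
                                     chroms=[target_chrom])

    enr_rows = []
    for locus in loci:
        for s in cfg.window_sizes:
            enr_rows.append(
                {
                    "locus": locus.assay.name,
                    "window_size": s,
                    "fold_enrichment": fold_enrichment(track, locus.chrom,
                                                       locus.midpoint, s),
                }
            )
    enrichment = pd.DataFrame(enr_rows,
                              columns=["locus", "window_size", "fold_enrichment"])

    fwhm = {}
    for locus in loci:
        try:
            fwhm[locus.assay.name] = fwhm_fragment_size(
                track, locus.chrom, locus.midpoint, window=cfg.window
            )
        except ValueError:
            fwhm[locus.assay.name] = float("nan")

    uni_regions = _locus_windows(loci, 50_000) if loci else None
    if uni_regions:
        uni, _ = coverage_uniformity(track, uni_regions, cfg.uniformity_depths)
    else:
        uni = {}

    call_reads = dedup if cfg.dedup_for_calling else reads
    calls = call_variants(pileup(call_reads, genome), min_depth=cfg.min_depth,
                          min_qual=cfg.min_qual, error_rate=cfg.error_rate)
    conc = concordance(calls, truth, windows=uni_regions)

    mean_folds = (
        enrichment.groupby("window_size")["fold_enrichment"].mean().to_dict()
        if len(enrichment)
        else {}
    )
    summary = {
        "mode": cfg.mode,
        "seed": seed,
        "genome_size": genome.size,
        "lambda_t": cfg.lambda_t,
        "lambda_b": lam_b,
        "n_screened": pool.stats.n_screened,
        "n_taqman_positive": pool.stats.n_taqman_positive,
        "n_sorted": pool.stats.n_sorted,
        "droplet_purity": pool.stats.droplet_purity,
        "molecule_purity": pool.stats.molecule_purity,
        "n_merged_sorted": pool.stats.n_merged_sorted,
        "n_reads": reads.n,
        "duplicate_fraction": dup_frac,
        "mean_depth": track.mean,
        "background_threshold": bg_thresh,
        **{f"fold_{s}": mean_folds.get(s, float("nan")) for s in cfg.window_sizes},
        **{f"fwhm_{k}": v for k, v in fwhm.items()},
        **{f"uniformity_ge{d}": uni.get(d, float("nan"))
           for d in cfg.uniformity_depths},
        "calls_pass": conc.n_calls_pass,
        "calls_pass_in_windows": conc.calls_pass_in_windows,
        "tp": conc.tp,
        "fp": conc.fp,
        "fn": conc.fn,
        "precision": conc.precision,
        "recall": conc.recall,
    }

    result = RunResult(
        config=cfg, genome=genome, loci=loci, truth=truth, pool=pool,
        track=track, calls=calls, summary=summary, windows=windows,
        enrichment=enrichment,
    )
    if outdir is not None:
        result.outdir = _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(res: RunResult, outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    genome, loci, cfg = res.genome, res.loci, res.config
    mio.write_fasta(genome, outdir / "genome.fa")
    if loci:
        mio.write_bed(
            pd.DataFrame(
                [
                    {"chrom": l.chrom, "start": l.assay.start, "end": l.assay.end,
                     "name": l.assay.name, "score": 0, "strand": "+"}
                    for l in loci
                ]
            ),
            outdir / "amplicons.bed",
        )
        mio.write_bed(
            pd.DataFrame(
                [
                    {"chrom": l.chrom, "start": l.window(50_000)[0],
                     "end": l.window(50_000)[1], "name": l.assay.name,
                     "score": 0, "strand": "+"}
                    for l in loci
                ]
            ),
            outdir / "target_windows.bed",
        )
    mio.write_truth_vcf(genome, res.truth, outdir / "truth.vcf")
    res.pool.summary_frame().to_csv(outdir / "droplet_summary.tsv", sep="\t",
                                    index=False)
    mio.write_bedgraph(res.track, outdir / "coverage.bedgraph")
    res.windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)
    res.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    res.calls.to_vcf(outdir / "calls.vcf", genome.lengths)
    pd.DataFrame([res.summary]).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(res.config.to_dict(), fh, sort_keys=True)
    return outdir


def compare_runs(
    enriched_dir: str | Path,
    reference_dir: str | Path,
    threshold: float | None = None,
    window: int = 20_000,
    step: int = 2_000,
    out: str | Path | None = None,
) -> dict:
    """Differential comparison of two run directories sharing a genome.

    Runs the specificity scan between the two coverage tracks and tallies
    PASS calls inside the 50-kb target windows for each sample. The default
    scan threshold is twice the reference track's mean+3SD background
    ceiling: by construction a ~3SD ceiling is grazed by occasional
    background windows, so the differential scan uses a level no background
    fluctuation can reach while enriched loci still clear it by a wide
    margin.
    """
    e_dir, r_dir = Path(enriched_dir), Path(reference_dir)
    enriched = mio.read_bedgraph(e_dir / "coverage.bedgraph")
    reference = mio.read_bedgraph(r_dir / "coverage.bedgraph")
    if not enriched.same_layout(reference):
        raise ValueError("runs cover different genomes")
    if threshold is None:
        threshold = 2.0 * background_threshold(reference, window, step)
    scan = specificity_scan(enriched, reference, threshold, window, step)

    windows_bed = e_dir / "target_windows.bed"
    tallies = {}
    if windows_bed.exists():
        wdf = mio.read_bed(windows_bed)
        wins = list(zip(wdf["chrom"], wdf["start"], wdf["end"]))
        for label, d in (("enriched", e_dir), ("reference", r_dir)):
            calls = _read_pass_calls(d / "calls.vcf")
            inw = sum(
                any(c == wc and ws <= p < we for wc, ws, we in wins)
                for c, p in calls
            )
            tallies[f"{label}_pass_calls"] = len(calls)
            tallies[f"{label}_pass_in_windows"] = inw

    report = {
        "threshold": threshold,
        "n_differential_enriched": int((scan["direction"] == "enriched_only").sum()),
        "n_differential_reference": int((scan["direction"] == "reference_only").sum()),
        **tallies,
    }
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        scan.to_csv(out / "differential_regions.tsv", sep="\t", index=False)
        pd.DataFrame([report]).to_csv(out / "compare_report.tsv", sep="\t", index=False)
    return report


def _read_pass_calls(path: Path) -> list[tuple[str, int]]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if "PASS" in rec.filter.keys():
                out.append((rec.chrom, rec.pos - 1))
    return out


def configure_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
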