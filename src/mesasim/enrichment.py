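"""Coverage-based enrichment statistics.

The analyses a targeted-enrichment experiment is judged by: 20-kb/2-kb-step
sliding-window means, a mean+3SD background threshold, a differential
specificity scan between enriched and reference tracks, probe-centred fold
enrichment versus window size, an FWHM fragment-size estimate from the
coverage peak, and the cumulative coverage-uniformity distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .reads import CoverageTrack

__all__ = [
    "AnalysisConfig",
    "window_means",
    "background_threshold",
    "specificity_scan",
    "fold_enrichment",
    "fwhm_fragment_size",
    "coverage_uniformity",
]


@dataclass
class AnalysisConfig:
    """Window/threshold defaults for the coverage analyses."""

    window: int = 20_000
    step: int = 2_000
    specificity_threshold: float = 56.0
    fold_window_sizes: tuple[int, ...] = (50_000, 100_000, 150_000, 200_000)
    uniformity_depths: tuple[int, ...] = (10, 30)

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must be <= window")
        if self.specificity_threshold <= 0:
            raise ValueError("specificity threshold must be > 0")


def window_means(track: CoverageTrack, window: int = 20_000, step: int = 2_000) -> pd.DataFrame:
    """Sliding-window mean depth; window k covers [k*step, k*step + window).

    Tail windows shorter than ``window`` are dropped (count recorded in
    ``df.attrs['n_dropped_tail']``), not rescaled.
    """
    if step < 1 or window < 1:
        raise ValueError("window and step must be >= 1")
    rows = []
    dropped = 0
    for name, depth in zip(track.chrom_names, track.depth):
        clen = len(depth)
        if window > clen:
            raise ValueError(f"window {window} exceeds chromosome {name} ({clen} bp)")
        csum = np.concatenate(([0.0], np.cumsum(depth, dtype=np.float64)))
        starts = np.arange(0, clen - window + 1, step, dtype=np.int64)
        dropped += int(clen > starts[-1] + window or (clen - window) % step != 0)
        means = (csum[starts + window] - csum[starts]) / window
        rows.append(
            pd.DataFrame(
                {"chrom": name, "start": starts, "end": starts + window, "mean_depth": means}
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["n_dropped_tail"] = dropped
    return out


def _windows_overlapping(df: pd.DataFrame, intervals) -> np.ndarray:
    mask = np.zeros(len(df), dtype=bool)
    for chrom, s, e in intervals:
        mask |= (df["chrom"] == chrom) & (df["start"] < e) & (df["end"] > s)
    return mask


def background_threshold(
    track: CoverageTrack,
    window: int = 20_000,
    step: int = 2_000,
    exclude=None,
    chroms: list[str] | None = None,
) -> float:
    """Mean + 3 x sample SD of sliding-window means, optionally excluding
    intervals (e.g. the targeted loci) and restricting to given chromosomes."""
    df = window_means(track, window, step)
    if chroms is not None:
        df = df[df["chrom"].isin(chroms)]
    if exclude:
        df = df[~_windows_overlapping(df, exclude)]
    if len(df) < 2:
        raise ValueError("fewer than 2 windows remain after exclusion")
    m = df["mean_depth"].to_numpy()
    return float(m.mean() + 3.0 * m.std(ddof=1))


def _merge_runs(df: pd.DataFrame, step: int, direction: str) -> list[dict]:
    out = []
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        means = grp["mean_depth"].to_numpy()
        brk = np.flatnonzero(np.diff(starts) != step)
        run_starts = np.concatenate(([0], brk + 1))
        run_ends = np.concatenate((brk, [len(starts) - 1]))
        for a, b in zip(run_starts, run_ends):
            out.append(
                {
                    "chrom": chrom,
                    "start": int(starts[a]),
                    "end": int(ends[b]),
                    "direction": direction,
                    "n_windows": int(b - a + 1),
                    "max_mean": float(means[a : b + 1].max()),
                }
            )
    return out


def specificity_scan(
    enriched: CoverageTrack,
    reference: CoverageTrack,
    threshold: float = 56.0,
    window: int = 20_000,
    step: int = 2_000,
) -> pd.DataFrame:
    """Windows >= threshold in one track and < threshold in the other,
    merged into maximal runs of consecutive qualifying windows.

    ``direction`` is 'enriched_only' or 'reference_only'. Comparing a track
    with itself yields an empty frame.
    """
    if not enriched.same_layout(reference):
        raise ValueError("tracks cover different genomes")
    we = window_means(enriched, window, step)
    wr = window_means(reference, window, step)
    me = we["mean_depth"].to_numpy()
    mr = wr["mean_depth"].to_numpy()
    rows: list[dict] = []
    rows += _merge_runs(we[(me >= threshold) & (mr < threshold)], step, "enriched_only")
    rows += _merge_runs(we[(mr >= threshold) & (me < threshold)], step, "reference_only")
    cols = ["chrom", "start", "end", "direction", "n_windows", "max_mean"]
    return pd.DataFrame(rows, columns=cols)


def fold_enrichment(
    track: CoverageTrack, chrom: str, center: int, size: int
) -> float:
    """Mean depth over the probe-centred window divided by the genome mean.

    Windows clipped at a chromosome end raise a warning and use the clipped
    span. Scale-invariant: multiplying the track by c > 0 leaves it unchanged.
    """
    if size <= 0:
        raise ValueError("window size must be > 0")
    gmean = track.mean
    if gmean == 0:
        raise ValueError("genome-wide mean depth is zero")
    depth = track[chrom]
    half = size // 2
    lo, hi = center - half, center - half + size
    clo, chi = max(lo, 0), min(hi, len(depth))
    if (clo, chi) != (lo, hi):
        warnings.warn(f"window [{lo}, {hi}) clipped to [{clo}, {chi}) on {chrom}")
    if chi <= clo:
        raise ValueError("window entirely off the chromosome")
    return float(depth[clo:chi].mean() / gmean)


def fwhm_fragment_size(
    track: CoverageTrack,
    chrom: str,
    center: int,
    span: int = 250_000,
    window: int = 20_000,
    smooth: bool = True,
    correct_smoothing: bool = True,
    background: float | None = None,
) -> float:
    """Full width at half maximum of the coverage peak around a probe, in bp.

    For fixed-length fragments that all cover the probe point the mean
    coverage profile is a triangle of base 2L, so FWHM = L: the estimator is
    a fragment-size proxy. The profile over ``span`` is smoothed with a
    moving average of ``window`` bp (the sliding-window default); a box of
    width w widens a triangular peak's FWHM by exactly w/4, which
    ``correct_smoothing`` subtracts. The genome-wide mean (or ``background``)
    is removed before taking the half maximum; crossings are located by
    linear interpolation and a missing crossing raises with the side named.
    """
    depth = track[chrom]
    half_span = span // 2
    lo = max(center - half_span, 0)
    hi = min(center + half_span, len(depth))
    prof = depth[lo:hi].astype(np.float64)
    if smooth and window > 1:
        prof = uniform_filter1d(prof, size=window, mode="nearest")
    bg = track.mean if background is None else float(background)
    prof = prof - bg

    peak_idx = int(np.argmax(prof))
    peak = prof[peak_idx]
    if peak <= 0 or np.all(prof == prof[0]):
        raise ValueError("no coverage peak above background within the span")
    half = peak / 2.0

    def cross(side: str) -> float:
        if side == "left":
            below = np.flatnonzero(prof[:peak_idx] <= half)
            if len(below) == 0:
                raise ValueError("no half-maximum crossing on the left side")
            i = below[-1]
            return i + (half - prof[i]) / (prof[i + 1] - prof[i])
        below = np.flatnonzero(prof[peak_idx:] <= half)
        if len(below) == 0:
            raise ValueError("no half-maximum crossing on the right side")
        j = peak_idx + below[0]
        return j - 1 + (half - prof[j - 1]) / (prof[j] - prof[j - 1])

    width = cross("right") - cross("left")
    if smooth and correct_smoothing:
        width -= window / 4.0
    return float(width)


def coverage_uniformity(
    track: CoverageTrack,
    regions,
    depths=(10, 30),
    at_or_above: bool = True,
) -> tuple[dict[int, float], pd.DataFrame]:
    """Fraction of region bases covered at (or above) each depth, plus the
    full survival CDF.

    ``regions`` is a list of (chrom, start, end). ``at_or_above=True`` counts
    depth >= d; False counts depth > d. The fraction at depth 0 is 1.0 and
    the curve is non-increasing in d.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    vals = np.concatenate(
        [np.asarray(track[c][s:e]) for c, s, e in regions]
    ).astype(np.int64)
    if len(vals) == 0:
        raise ValueError("regions cover zero bases")
    n = len(vals)
    counts = np.bincount(vals)
    cum_lt = np.concatenate(([0], np.cumsum(counts)))  # cum_lt[d] = #bases < d

    def frac(d: int) -> float:
        if at_or_above:
            return 1.0 if d <= 0 else float((n - cum_lt[min(d, len(counts))]) / n)
        return float((n - cum_lt[min(d + 1, len(counts))]) / n)

    table = {int(d): frac(int(d)) for d in depths}
    dmax = len(counts) - 1
    cdf = pd.DataFrame(
        {"depth": np.arange(dmax + 1), "fraction": [frac(d) for d in range(dmax + 1)]}
    )
    return table, cdf
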