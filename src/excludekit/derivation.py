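"""Gold-standard exclusion-region derivation.

High Signal regions come from a fold-enrichment scan of input ChIP-seq
coverage (input libraries are expected to be near-uniform, so strong local
enrichment marks alignment artifacts), followed by a fold-change-range
selection, merging within 1 kb, a 1 kb width filter, and union with
centromeres. Low Mappability regions come from inverting the "mappable
universe" of a per-base mappability track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .intervals import (Region, RegionSet, complement, filter_min_width,
                        merge_within)
from .io import five_prime_positions

__all__ = [
    "PeakRecord", "ScanParams",
    "fold_enrichment_scan", "select_high_signal",
    "combine_with_centromeres", "derive_low_mappability",
]

HIGH_SIGNAL = "High Signal"
LOW_MAPPABILITY = "Low Mappability"


@dataclass(frozen=True)
class PeakRecord:
    """A candidate enriched window run with its maximum fold change."""

    chrom: str
    start: int
    end: int
    fold_change: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty peak interval")
        if not np.isfinite(self.fold_change) or self.fold_change < 0:
            raise ValueError("fold change must be finite and non-negative")


@dataclass(frozen=True)
class ScanParams:
    """Sliding-window scan parameters.

    window: scan window width in bp (step = window/2).
    slocal/llocal: short/long local background window widths in bp.
    min_fold_emit: minimum fold change for a window to enter a peak run.
    """

    window: int = 300
    slocal: int = 10_000
    llocal: int = 100_000
    min_fold_emit: float = 1.5

    def __post_init__(self):
        if not (0 < self.window <= self.slocal <= self.llocal):
            raise ValueError("require 0 < window <= slocal <= llocal")
        if self.min_fold_emit <= 0:
            raise ValueError("min_fold_emit must be positive")


def _masked_cumlen(mask_starts, mask_ends, x):
    """Total masked bases below each position x (mask intervals disjoint, sorted)."""
    if len(mask_starts) == 0:
        return np.zeros_like(np.asarray(x), dtype=float)
    bounds = np.empty(2 * len(mask_starts))
    bounds[0::2] = mask_starts
    bounds[1::2] = mask_ends
    cum = np.empty_like(bounds)
    cum[0::2] = np.concatenate(([0.0], np.cumsum(mask_ends - mask_starts)[:-1]))
    cum[1::2] = np.cumsum(mask_ends - mask_starts)
    return np.interp(x, bounds, cum, left=0.0, right=cum[-1])


def fold_enrichment_scan(reads: pd.DataFrame, genome: GenomeSpec,
                         params: ScanParams = ScanParams()) -> list[PeakRecord]:
    """Scan read coverage for locally enriched windows.

    Windows of `window` bp advance in steps of window/2. The expected count
    of a window is its width times the largest of the genome-wide read rate
    and the slocal/llocal local rates; local rates are estimated from bases
    outside provisionally enriched windows (a first pass against the
    genome-wide rate), so broad artifact pileups do not inflate their own
    background. Windows at or above min_fold_emit are merged into contiguous
    peak runs carrying the maximum window fold change; all reads count
    (duplicates retained).
    """
    if len(reads) == 0:
        raise ValueError("empty read table")
    if genome.total_size <= 0:
        raise ValueError("zero-length genome")
    pos5 = five_prime_positions(reads)
    for chrom in pos5["chrom"].unique():
        if chrom not in genome:
            raise ValueError(f"read chrom {chrom!r} not in genome")
    n_total = len(reads)
    genome_rate = n_total / genome.total_size
    step = max(params.window // 2, 1)
    peaks: list[PeakRecord] = []

    for chrom, length in genome.chromosomes:
        pos = np.sort(pos5.loc[pos5["chrom"] == chrom, "pos"].to_numpy())
        if len(pos) == 0:
            continue
        ws = np.arange(0, length, step)
        we = np.minimum(ws + params.window, length)
        keep = we > ws
        ws, we = ws[keep], we[keep]
        obs = np.searchsorted(pos, we) - np.searchsorted(pos, ws)
        widths = (we - ws).astype(float)

        # pass 1: provisional enrichment mask against the genome-wide rate
        fold0 = obs / (genome_rate * widths)
        hot = fold0 >= params.min_fold_emit
        mask_s, mask_e = _merge_runs(ws, we, hot)

        # cumulative masked-read count at each sorted read index
        masked_flag = np.zeros(len(pos), dtype=bool)
        for a, b in zip(mask_s, mask_e):
            lo, hi = np.searchsorted(pos, [a, b])
            masked_flag[lo:hi] = True
        cum_masked = np.concatenate(([0], np.cumsum(masked_flag)))
        cum_all = np.arange(len(pos) + 1)

        def local_rate(half_width):
            centers = (ws + we) / 2.0
            a = np.clip(centers - half_width, 0, length)
            b = np.clip(centers + half_width, 0, length)
            ia = np.searchsorted(pos, a)
            ib = np.searchsorted(pos, b)
            count = (cum_all[ib] - cum_all[ia]) - (cum_masked[ib] - cum_masked[ia])
            unmasked = (b - a) - (_masked_cumlen(mask_s, mask_e, b)
                                  - _masked_cumlen(mask_s, mask_e, a))
            rate = np.full(len(ws), genome_rate)
            ok = unmasked >= params.window  # enough unmasked bases to estimate
            rate[ok] = count[ok] / unmasked[ok]
            return rate

        lam = widths * np.maximum.reduce([
            np.full(len(ws), genome_rate),
            local_rate(params.slocal / 2.0),
            local_rate(params.llocal / 2.0),
        ])
        fold = obs / lam
        hot = fold >= params.min_fold_emit
        run_s, run_e, run_fc = _merge_runs(ws, we, hot, fold)
        for a, b, fc in zip(run_s, run_e, run_fc):
            peaks.append(PeakRecord(chrom, int(a), int(b), float(fc)))
    return peaks


def _merge_runs(ws, we, hot, fold=None):
    """Merge consecutive hot windows into runs; optionally track max fold."""
    starts, ends, fcs = [], [], []
    idx = np.flatnonzero(hot)
    if len(idx) == 0:
        return (np.array(starts), np.array(ends), np.array(fcs)) if fold is not None \
            else (np.array(starts), np.array(ends))
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_bounds = np.split(idx, breaks + 1)
    for run in run_bounds:
        starts.append(ws[run[0]])
        ends.append(we[run[-1]])
        if fold is not None:
            fcs.append(fold[run].max())
    if fold is not None:
        return np.array(starts), np.array(ends), np.array(fcs)
    return np.array(starts), np.array(ends)


def select_high_signal(peaks: list[PeakRecord], fraction: float = 0.99,
                       merge_gap: int = 1000, min_width: int = 1000,
                       genome: GenomeSpec | None = None) -> RegionSet:
    """Keep peaks whose fold change exceeds `fraction` of the fold-change range.

    The threshold is anchored at the minimum: min_fc + fraction*(max_fc -
    min_fc), with a strict ">". Survivors are merged within merge_gap and
    regions narrower than min_width are discarded. A degenerate range
    (all fold changes equal) selects nothing.
    """
    if not peaks:
        raise ValueError("empty peak list")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    fcs = np.array([p.fold_change for p in peaks])
    lo, hi = fcs.min(), fcs.max()
    threshold = lo + fraction * (hi - lo)
    if hi == lo:
        warnings.warn("degenerate fold-change range: no peak selected")
    kept = [Region(p.chrom, p.start, p.end, HIGH_SIGNAL, p.fold_change)
            for p in peaks if p.fold_change > threshold]
    s = RegionSet("High Signal", kept, genome)
    return filter_min_width(merge_within(s, merge_gap), min_width)


def combine_with_centromeres(hs: RegionSet, centromeres: RegionSet) -> RegionSet:
    """Union of the High Signal set with centromeres, merging overlaps only."""
    if hs.genome is not None and centromeres.genome is not None \
            and hs.genome != centromeres.genome:
        raise ValueError("genome mismatch between High Signal set and centromeres")
    combined = RegionSet(hs.name or "High Signal + Centromeres",
                         list(hs.regions) + list(centromeres.regions),
                         hs.genome or centromeres.genome)
    return merge_within(combined, 0)


def derive_low_mappability(mappability: pd.DataFrame, genome: GenomeSpec,
                           threshold: float = 0.01, merge_gap: int = 1000,
                           min_width: int = 1000) -> RegionSet:
    """Derive Low Mappability regions from a per-base mappability track.

    Five steps: (1) the mappable universe is every base with mappability
    strictly above `threshold`; (2) universe regions within merge_gap are
    merged, absorbing short unmappable gaps; (3) the merged universe is
    inverted against the genome; (4) the inverted regions are merged within
    merge_gap; (5) regions narrower than min_width are discarded. Every
    output base has mappability <= threshold.
    """
    vals = mappability["value"].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("mappability values must lie in [0, 1]")
    mappable = mappability[mappability["value"] > threshold]
    universe = RegionSet("mappable universe",
                         [Region(str(c), int(s), int(e))
                          for c, s, e in zip(mappable["chrom"], mappable["start"],
                                             mappable["end"])],
                         genome)
    universe = merge_within(universe, merge_gap)
    low = merge_within(complement(universe, genome), merge_gap)
    low = filter_min_width(low, min_width)
    return RegionSet("Low Mappability",
                     [Region(r.chrom, r.start, r.end, LOW_MAPPABILITY)
                      for r in low.regions],
                     genome)
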