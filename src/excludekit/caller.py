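"""Multi-class exclusion-region caller.

Input ChIP-seq libraries (no antibody enrichment) should yield roughly
uniform coverage, so bins with extreme aggregate signal mark pileup
artifacts, and bins with low mappability mark regions where short reads
cannot be placed uniquely. Flagged bins are projected to base intervals,
bridged across a fixed distance, and annotated with one of three classes:
"High Signal", "Low Mappability", or — when a bridged region contains both
flag types — the combined "High Signal, Low Mappability". A region carrying
both classes is never silently collapsed to a bare "High Signal" call.

Because the upstream tool this reworks left its normalization and
thresholds undocumented, every threshold here is an explicit, exposed
parameter: RPM normalization, median cross-sample aggregation, a
95th-percentile plus 3x-median high-signal rule (the percentile caps how
much of the genome can ever be flagged; the fold guard does the
discriminating), and a mappability <= 0.1 low-mappability rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .intervals import Region, RegionSet, filter_min_width, merge_within
from .io import five_prime_positions
from .derivation import HIGH_SIGNAL, LOW_MAPPABILITY

COMBINED = "High Signal, Low Mappability"

__all__ = [
    "BinGrid", "BinTable", "SampleBins", "CallerParams", "BinFlags",
    "bin_counts", "bin_mappability", "aggregate_bins", "classify_bins",
    "call_exclusion_regions", "run_caller", "COMBINED",
]


@dataclass(frozen=True)
class BinGrid:
    """Genome tiling with overlapping bins (step = bin_size - bin_overlap)."""

    bin_size: int = 1000
    bin_overlap: int = 500

    def __post_init__(self):
        if not 0 <= self.bin_overlap < self.bin_size:
            raise ValueError("require 0 <= bin_overlap < bin_size")

    @property
    def step(self) -> int:
        return self.bin_size - self.bin_overlap


@dataclass
class BinTable:
    """Materialized bins for a genome: parallel chrom/start/end arrays.

    Bins never cross chromosome ends; terminal bins may be partial and
    participate with their true width.
    """

    grid: BinGrid
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    @classmethod
    def from_genome(cls, grid: BinGrid, genome: GenomeSpec) -> "BinTable":
        cs, ss, es = [], [], []
        for chrom, length in genome.chromosomes:
            starts = np.arange(0, length, grid.step)
            ends = np.minimum(starts + grid.bin_size, length)
            cs.append(np.full(len(starts), chrom, dtype=object))
            ss.append(starts)
            es.append(ends)
        return cls(grid, np.concatenate(cs), np.concatenate(ss), np.concatenate(es))

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def is_partial(self) -> np.ndarray:
        return self.widths < self.grid.bin_size

    def same_layout(self, other: "BinTable") -> bool:
        return (self.grid == other.grid and len(self) == len(other)
                and bool(np.all(self.chroms == other.chroms))
                and bool(np.all(self.starts == other.starts)))


@dataclass
class SampleBins:
    """Per-bin read counts for one sample (raw and reads-per-million)."""

    sample_id: str
    table: BinTable
    raw: np.ndarray
    n_reads: int

    @property
    def rpm(self) -> np.ndarray:
        return self.raw * (1e6 / self.n_reads)


@dataclass(frozen=True)
class CallerParams:
    bin_size: int = 1000
    bin_overlap: int = 500
    bridge: int = 20_000
    kmer: int = 36  # provenance of the user-supplied mappability track
    aggregate_stat: str | float = "median"
    hs_percentile: float = 0.95
    hs_min_fold_over_median: float = 3.0
    lm_mappability_max: float = 0.1
    min_region: int = 1000

    def __post_init__(self):
        if self.bridge < 0:
            raise ValueError("bridge must be >= 0")
        if not 0 < self.hs_percentile < 1:
            raise ValueError("hs_percentile must be in (0, 1)")
        if not 0 <= self.lm_mappability_max <= 1:
            raise ValueError("lm_mappability_max must be in [0, 1]")

    @property
    def grid(self) -> BinGrid:
        return BinGrid(self.bin_size, self.bin_overlap)


@dataclass
class BinFlags:
    """Independent per-bin flags; a bin may carry both."""

    high_signal: np.ndarray
    low_mappability: np.ndarray


def bin_counts(reads: pd.DataFrame, grid: BinGrid, genome: GenomeSpec,
               sample_id: str = "") -> SampleBins:
    """Count read 5' starts into every (possibly overlapping) bin containing them."""
    if len(reads) == 0:
        raise ValueError(f"empty read table for sample {sample_id!r}")
    table = BinTable.from_genome(grid, genome)
    pos5 = five_prime_positions(reads)
    raw = np.zeros(len(table), dtype=np.int64)
    offset = 0
    for chrom, length in genome.chromosomes:
        n_bins = int(np.sum(table.chroms == chrom))
        pos = np.sort(pos5.loc[pos5["chrom"] == chrom, "pos"].to_numpy())
        if len(pos):
            s = table.starts[offset:offset + n_bins]
            e = table.ends[offset:offset + n_bins]
            raw[offset:offset + n_bins] = (np.searchsorted(pos, e)
                                           - np.searchsorted(pos, s))
        offset += n_bins
    return SampleBins(sample_id, table, raw, len(reads))


def bin_mappability(mappability: pd.DataFrame, table: BinTable) -> np.ndarray:
    """Per-bin mean mappability; bases absent from the track count as 0."""
    vals = mappability["value"].to_numpy()
    if len(vals) and ((vals < 0) | (vals > 1)).any():
        raise ValueError("mappability values must lie in [0, 1]")
    out = np.zeros(len(table))
    for chrom in pd.unique(table.chroms):
        sel = table.chroms == chrom
        trk = mappability[mappability["chrom"] == chrom].sort_values("start")
        if len(trk) == 0:
            continue
        # piecewise-linear cumulative integral of the step-function track
        s = trk["start"].to_numpy(dtype=float)
        e = trk["end"].to_numpy(dtype=float)
        v = trk["value"].to_numpy()
        xs = np.empty(2 * len(s))
        xs[0::2], xs[1::2] = s, e
        seg = v * (e - s)
        cum = np.empty_like(xs)
        cum[1::2] = np.cumsum(seg)
        cum[0::2] = cum[1::2] - seg
        bs = table.starts[sel].astype(float)
        be = table.ends[sel].astype(float)
        integral = (np.interp(be, xs, cum, left=0.0, right=cum[-1])
                    - np.interp(bs, xs, cum, left=0.0, right=cum[-1]))
        out[sel] = integral / (be - bs)
    return out


def aggregate_bins(samples: list[SampleBins], stat: str | float = "median") -> np.ndarray:
    """Cross-sample per-bin signal: median (default) or a quantile of RPM."""
    if not samples:
        raise ValueError("need at least one sample")
    first = samples[0].table
    for s in samples[1:]:
        if not s.table.same_layout(first):
            raise ValueError(f"bin grid mismatch for sample {s.sample_id!r}")
    mat = np.vstack([s.rpm for s in samples])
    if stat == "median":
        return np.median(mat, axis=0)
    q = float(stat)
    if not 0 <= q <= 1:
        raise ValueError("quantile must be in [0, 1]")
    return np.quantile(mat, q, axis=0)


def classify_bins(signal: np.ndarray, mappability_bins: np.ndarray,
                  params: CallerParams) -> BinFlags:
    """Flag bins as high-signal and/or low-mappability (flags independent).

    high_signal: signal at or above the empirical hs_percentile of all bins
    AND strictly above hs_min_fold_over_median times the genome-wide median
    (the fold guard keeps flat coverage from being flagged).
    low_mappability: mean bin mappability <= lm_mappability_max.
    """
    signal = np.asarray(signal, dtype=float)
    mappability_bins = np.asarray(mappability_bins, dtype=float)
    if signal.shape != mappability_bins.shape:
        raise ValueError("signal and mappability vectors are not aligned")
    if np.all(signal == 0):
        warnings.warn("all-zero signal: no high-signal flags")
        hs = np.zeros(len(signal), dtype=bool)
    else:
        cut = np.quantile(signal, params.hs_percentile)
        med = np.median(signal)
        hs = (signal >= cut) & (signal > params.hs_min_fold_over_median * med)
    lm = mappability_bins <= params.lm_mappability_max
    return BinFlags(hs, lm)


def call_exclusion_regions(flags: BinFlags, table: BinTable, params: CallerParams,
                           signal: np.ndarray | None = None) -> RegionSet:
    """Project flagged bins to intervals, bridge, annotate, width-filter.

    A merged region containing only high-signal bins is "High Signal"; only
    low-mappability bins, "Low Mappability"; both kinds, the combined
    "High Signal, Low Mappability".
    """
    hs, lm = flags.high_signal, flags.low_mappability
    regions = []
    for flag, label in ((hs, HIGH_SIGNAL), (lm, LOW_MAPPABILITY)):
        idx = np.flatnonzero(flag)
        for i in idx:
            score = float(signal[i]) if signal is not None else None
            regions.append(Region(str(table.chroms[i]), int(table.starts[i]),
                                  int(table.ends[i]), label, score))
    if not regions:
        return RegionSet("exclusion")
    merged = merge_within(RegionSet("exclusion", regions), params.bridge)
    out = []
    for r in merged.regions:
        has_hs = HIGH_SIGNAL in r.label
        has_lm = LOW_MAPPABILITY in r.label
        label = COMBINED if (has_hs and has_lm) else (
            HIGH_SIGNAL if has_hs else LOW_MAPPABILITY)
        out.append(Region(r.chrom, r.start, r.end, label, r.score))
    return filter_min_width(RegionSet("exclusion", out), params.min_region)


def run_caller(samples: dict[str, pd.DataFrame], mappability: pd.DataFrame,
               genome: GenomeSpec, params: CallerParams = CallerParams()) -> RegionSet:
    """End-to-end caller: bin, normalize, aggregate, classify, bridge, annotate.

    Deterministic given its inputs. The returned set carries a provenance
    block (parameters, sample ids, k-mer metadata of the mappability track)
    in its metadata.
    """
    if not samples:
        raise ValueError("need at least one sample")
    grid = params.grid
    bins = [bin_counts(reads, grid, genome, sid) for sid, reads in samples.items()]
    signal = aggregate_bins(bins, params.aggregate_stat)
    mapp = bin_mappability(mappability, bins[0].table)
    flags = classify_bins(signal, mapp, params)
    result = call_exclusion_regions(flags, bins[0].table, params, signal)
    result.genome = genome
    result.metadata = {
        "params": asdict(params),
        "samples": list(samples),
        "kmer": params.kmer,
        "n_bins": len(bins[0].table),
    }
    return result
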