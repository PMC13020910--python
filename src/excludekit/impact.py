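"""Downstream impact of exclusion sets on transcripts and ChIP-seq correlation.

Two assessments: (1) how many transcripts (by biotype) have a non-zero sum
of exon bases covered by an exclusion set, and how many bases; (2) how the
between-sample Pearson correlation of binned read counts changes when reads
overlapping an exclusion set are removed. Shared artifact pileups inflate
between-sample correlation, so removing them should drive the correlation
delta negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .intervals import Region, RegionSet, intersection_width
from .io import five_prime_positions
from .metrics import DistanceMatrix, linkage
from .transcripts import BIOTYPES, TranscriptModel

__all__ = [
    "CountsMatrix", "CorrelationReport",
    "exon_coverage", "impact_report", "binned_counts_matrix",
    "filter_reads_by_regions", "pearson_matrix", "correlation_delta",
]


@dataclass
class CountsMatrix:
    """Raw read counts per non-overlapping genomic bin, per sample."""

    bins: pd.DataFrame  # chrom, start, end
    counts: pd.DataFrame  # one column per sample
    bin_size: int


@dataclass
class CorrelationReport:
    sample_labels: list[str]
    r_before: np.ndarray
    r_after: np.ndarray
    order: list[int]  # row order from clustering the delta rows

    @property
    def delta(self) -> np.ndarray:
        return self.r_after - self.r_before

    def mean_offdiagonal_delta(self) -> float:
        d = self.delta
        n = d.shape[0]
        mask = ~np.eye(n, dtype=bool)
        return float(d[mask].mean())


def exon_coverage(t: TranscriptModel, exclusion: RegionSet) -> int:
    """Sum over exons of bases covered by the exclusion footprint."""
    exons = RegionSet("exons", [Region(t.chrom, a, b) for a, b in t.exons])
    return intersection_width(exons, exclusion)


def impact_report(transcripts: list[TranscriptModel],
                  sets: list[RegionSet]) -> pd.DataFrame:
    """Per (exclusion set, biotype): transcripts affected and exonic bases covered.

    A transcript is affected when its exon coverage by the set is non-zero.
    """
    if not transcripts:
        raise ValueError("need at least one transcript")
    rows = []
    for s in sets:
        cov = {t.transcript_id: exon_coverage(t, s) for t in transcripts}
        for biotype in BIOTYPES:
            sub = [t for t in transcripts if t.biotype == biotype]
            rows.append({
                "set_name": s.name,
                "biotype": biotype,
                "n_transcripts_affected": sum(cov[t.transcript_id] > 0 for t in sub),
                "exonic_bases_covered": sum(cov[t.transcript_id] for t in sub),
            })
    return pd.DataFrame(rows)


def _tile_bins(genome: GenomeSpec, bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom, length in genome.chromosomes:
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def binned_counts_matrix(read_tables: dict[str, pd.DataFrame], genome: GenomeSpec,
                         bin_size: int = 10_000) -> CountsMatrix:
    """Count reads per sample into a non-overlapping genome tiling.

    A read is assigned to the single bin containing its 5' start (half-open
    bins, so a read starting exactly on a boundary falls in the right bin).
    """
    if len(read_tables) < 2:
        raise ValueError("need at least 2 samples")
    bins = _tile_bins(genome, bin_size)
    cols = {}
    for sid, reads in read_tables.items():
        if len(reads) == 0:
            raise ValueError(f"empty read table for sample {sid!r}")
        counts = np.zeros(len(bins), dtype=np.int64)
        offset = 0
        pos5 = five_prime_positions(reads)
        for chrom, length in genome.chromosomes:
            n_bins = int(np.ceil(length / bin_size))
            pos = pos5.loc[pos5["chrom"] == chrom, "pos"].to_numpy()
            if len(pos):
                idx = (pos // bin_size).astype(int)
                counts[offset:offset + n_bins] = np.bincount(idx, minlength=n_bins)
            offset += n_bins
        cols[sid] = counts
    return CountsMatrix(bins, pd.DataFrame(cols), bin_size)


def filter_reads_by_regions(reads: pd.DataFrame, exclusion: RegionSet) -> pd.DataFrame:
    """Keep reads whose [start, end) shares no base with the exclusion footprint."""
    if len(exclusion) == 0 or len(reads) == 0:
        return reads.copy()
    fp = exclusion.footprint().by_chrom()
    keep = np.ones(len(reads), dtype=bool)
    chrom_arr = reads["chrom"].to_numpy()
    start_arr = reads["start"].to_numpy()
    end_arr = reads["end"].to_numpy()
    for chrom, regs in fp.items():
        starts = np.array([r.start for r in regs])
        ends = np.array([r.end for r in regs])
        sel = chrom_arr == chrom
        if not sel.any():
            continue
        j = np.searchsorted(starts, end_arr[sel], side="left")
        hit = (j > 0) & (ends[np.maximum(j - 1, 0)] > start_arr[sel])
        keep[np.flatnonzero(sel)[hit]] = False
    return reads[keep].copy()


def pearson_matrix(counts: CountsMatrix) -> np.ndarray:
    """Pearson correlation of raw bin counts between samples (unit diagonal)."""
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 bins")
    sd = mat.std(axis=0)
    for name, s in zip(counts.counts.columns, sd):
        if s == 0:
            raise ValueError(f"zero-variance sample {name!r}: correlation undefined")
    r = np.corrcoef(mat, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return r


def correlation_delta(read_tables: dict[str, pd.DataFrame], genome: GenomeSpec,
                      exclusion: RegionSet, bin_size: int = 10_000) -> CorrelationReport:
    """Correlation matrices before/after removing reads in the exclusion set.

    delta = r_after - r_before. Rows are ordered by complete-linkage
    clustering of the Euclidean distances between delta rows.
    """
    labels = list(read_tables)
    before = binned_counts_matrix(read_tables, genome, bin_size)
    filtered = {sid: filter_reads_by_regions(df, exclusion)
                for sid, df in read_tables.items()}
    after = binned_counts_matrix(filtered, genome, bin_size)
    r_before = pearson_matrix(before)
    r_after = pearson_matrix(after)
    delta = r_after - r_before
    n = len(labels)
    if n > 2 and not np.allclose(delta, 0):
        dd = np.sqrt(((delta[:, None, :] - delta[None, :, :]) ** 2).sum(axis=2))
        tree = linkage(DistanceMatrix(labels, dd), method="complete")
        order = _leaf_order(tree.merges, n)
    else:
        order = list(range(n))
    return CorrelationReport(labels, r_before, r_after, order)


def _leaf_order(merges: np.ndarray, n: int) -> list[int]:
    members = {i: [i] for i in range(n)}
    for step, (i, j, _, _) in enumerate(merges):
        members[n + step] = members.pop(int(i)) + members.pop(int(j))
    (last,) = members
    return members[last]
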