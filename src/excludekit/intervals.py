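"""Interval data model and set algebra for exclusion regions.

All coordinates are 0-based, half-open (BED convention). Strand is ignored:
exclusion sets are unstranded catalogues of problematic bases. Region sets
are kept sorted lexicographically by chromosome name, then (start, end).

The footprint width W(S) of a set is the number of distinct bases covered,
i.e. the total width after self-merging, so internally overlapping inputs
never double count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeSpec

__all__ = [
    "Region",
    "RegionSet",
    "merge_within",
    "filter_min_width",
    "complement",
    "overlap_count",
    "intersection_width",
    "union_unique_count",
]


@dataclass(frozen=True)
class Region:
    """A half-open genomic interval with an optional annotation label."""

    chrom: str
    start: int
    end: int
    label: str = ""
    score: float | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval [{self.start},{self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class RegionSet:
    """A named, sorted collection of labeled regions, optionally bound to a genome."""

    name: str = ""
    regions: list[Region] = field(default_factory=list)
    genome: GenomeSpec | None = None
    metadata: dict | None = None

    def __post_init__(self):
        self.regions = sorted(self.regions, key=Region.key)
        if self.genome is not None:
            for r in self.regions:
                if r.chrom not in self.genome:
                    raise ValueError(f"region chrom {r.chrom!r} not in genome")
                if r.end > self.genome.length(r.chrom):
                    raise ValueError(
                        f"region {r.chrom}:{r.start}-{r.end} exceeds chromosome length"
                    )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    @property
    def total_raw_width(self) -> int:
        return sum(r.width for r in self.regions)

    @property
    def footprint_width(self) -> int:
        """W(S): distinct bases covered (computed on the self-merged footprint)."""
        return merge_within(self, 0, _footprint=True).total_raw_width

    def footprint(self) -> "RegionSet":
        """Self-merged base footprint (labels merged, gap 0)."""
        return merge_within(self, 0)

    def by_chrom(self) -> dict[str, list[Region]]:
        out: dict[str, list[Region]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        return out

    def with_name(self, name: str) -> "RegionSet":
        return RegionSet(name, list(self.regions), self.genome, self.metadata)


def _merge_labels(labels) -> str:
    """Distinct non-empty labels in first-appearance order, joined by ', '."""
    seen: list[str] = []
    for lab in labels:
        if lab and lab not in seen:
            seen.append(lab)
    return ", ".join(seen)


def merge_within(s: RegionSet, gap: int, _footprint: bool = False) -> RegionSet:
    """Merge regions whose inter-region distance (next.start - prev.end) is <= gap.

    gap=0 merges overlapping and bookended regions only. Labels of merged
    regions are the ordered union of distinct input labels. Idempotent.
    """
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    out: list[Region] = []
    for _, regs in sorted(s.by_chrom().items()):
        cur_s, cur_e = regs[0].start, regs[0].end
        labs = [regs[0].label]
        scores = [regs[0].score] if regs[0].score is not None else []
        for r in regs[1:]:
            if r.start - cur_e <= gap:
                cur_e = max(cur_e, r.end)
                labs.append(r.label)
                if r.score is not None:
                    scores.append(r.score)
            else:
                out.append(
                    Region(regs[0].chrom, cur_s, cur_e,
                           "" if _footprint else _merge_labels(labs),
                           max(scores) if scores else None)
                )
                cur_s, cur_e = r.start, r.end
                labs = [r.label]
                scores = [r.score] if r.score is not None else []
        out.append(
            Region(regs[0].chrom, cur_s, cur_e,
                   "" if _footprint else _merge_labels(labs),
                   max(scores) if scores else None)
        )
    return RegionSet(s.name, out, s.genome)


def filter_min_width(s: RegionSet, min_width: int) -> RegionSet:
    """Drop regions strictly narrower than min_width ("smaller than" is strict)."""
    if min_width < 0:
        raise ValueError(f"min_width must be >= 0, got {min_width}")
    return RegionSet(s.name, [r for r in s.regions if r.width >= min_width], s.genome)


def complement(s: RegionSet, genome: GenomeSpec) -> RegionSet:
    """Regions of the genome not covered by s; tiles the genome with merged(s)."""
    for r in s.regions:
        if r.chrom not in genome or r.end > genome.length(r.chrom):
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} outside genome bounds")
    merged = merge_within(s, 0, _footprint=True) if len(s) else s
    cov = merged.by_chrom()
    out: list[Region] = []
    for chrom, length in genome.chromosomes:
        pos = 0
        for r in cov.get(chrom, []):
            if r.start > pos:
                out.append(Region(chrom, pos, r.start))
            pos = max(pos, r.end)
        if pos < length:
            out.append(Region(chrom, pos, length))
    return RegionSet(s.name, out, genome)


def _footprint_arrays(s: RegionSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    fp = merge_within(s, 0, _footprint=True) if len(s) else s
    out = {}
    for chrom, regs in fp.by_chrom().items():
        out[chrom] = (np.array([r.start for r in regs]), np.array([r.end for r in regs]))
    return out


def overlap_count(a: RegionSet, b: RegionSet) -> int:
    """Number of regions in a sharing >= 1 base with the footprint of b."""
    fb = _footprint_arrays(b)
    n = 0
    for r in a.regions:
        if r.chrom not in fb:
            continue
        starts, ends = fb[r.chrom]
        # footprint intervals are disjoint & sorted: the only candidate is the
        # last interval starting before r.end
        j = int(np.searchsorted(starts, r.end, side="left"))
        if j > 0 and ends[j - 1] > r.start:
            n += 1
    return n


def intersection_width(a: RegionSet, b: RegionSet) -> int:
    """W(A ∩ B): bases covered by both footprints."""
    fa = _footprint_arrays(a)
    fb = _footprint_arrays(b)
    total = 0
    for chrom in set(fa) & set(fb):
        sa, ea = fa[chrom]
        sb, eb = fb[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += int(hi - lo)
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return total


def union_unique_count(a: RegionSet, b: RegionSet) -> int:
    """Number of distinct (chrom, start, end) tuples in the union of a and b."""
    return len({r.key() for r in a.regions} | {r.key() for r in b.regions})
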