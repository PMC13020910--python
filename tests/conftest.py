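"""Shared fixtures and a per-base boolean-mask oracle for interval algebra."""

import numpy as np
import pytest

from excludekit import GenomeSpec, Region, RegionSet


@pytest.fixture
def toy_genome():
    return GenomeSpec([("chr1", 5000), ("chr2", 3000)])


def regions_to_masks(rs: RegionSet, genome: GenomeSpec) -> dict:
    masks = {c: np.zeros(l, dtype=bool) for c, l in genome.chromosomes}
    for r in rs:
        masks[r.chrom][r.start:r.end] = True
    return masks


def mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) pairs."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def brute_merge_within(rs: RegionSet, gap: int, genome: GenomeSpec) -> list:
    """Coordinates of merge_within via masks: merge runs separated by <= gap."""
    out = []
    masks = regions_to_masks(rs, genome)
    for chrom, _ in genome.chromosomes:
        runs = mask_runs(masks[chrom])
        if not runs:
            continue
        cur_s, cur_e = runs[0]
        for s, e in runs[1:]:
            if s - cur_e <= gap:
                cur_e = e
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def brute_complement(rs: RegionSet, genome: GenomeSpec) -> list:
    out = []
    masks = regions_to_masks(rs, genome)
    for chrom, _ in genome.chromosomes:
        out.extend((chrom, s, e) for s, e in mask_runs(~masks[chrom]))
    return out


def brute_overlap_count(a: RegionSet, b: RegionSet, genome: GenomeSpec) -> int:
    masks_b = regions_to_masks(b, genome)
    return sum(bool(masks_b[r.chrom][r.start:r.end].any()) for r in a)


def brute_intersection_width(a: RegionSet, b: RegionSet, genome: GenomeSpec) -> int:
    ma = regions_to_masks(a, genome)
    mb = regions_to_masks(b, genome)
    return int(sum((ma[c] & mb[c]).sum() for c, _ in genome.chromosomes))


def random_region_set(rng: np.random.Generator, genome: GenomeSpec,
                      max_regions: int = 12, name: str = "S") -> RegionSet:
    regions = []
    n = int(rng.integers(0, max_regions + 1))
    for _ in range(n):
        chrom, length = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
        start = int(rng.integers(0, length - 1))
        width = int(rng.integers(1, min(400, length - start) + 1))
        regions.append(Region(chrom, start, start + width))
    return RegionSet(name, regions, genome)
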