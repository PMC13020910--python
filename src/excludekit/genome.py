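"""Genome declarations (chromosome names and lengths)."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of chromosomes with their lengths in base pairs.

    The total size is the denominator-side "genome size" of width-normalized
    overlap statistics (e.g. 2,875,001,522 bp for hg38).
    """

    chromosomes: tuple[tuple[str, int], ...]
    _lengths: dict = field(init=False, repr=False, compare=False)

    def __init__(self, chromosomes):
        chromosomes = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(not n for n in names):
            raise ValueError("empty chromosome name")
        if any(l <= 0 for _, l in chromosomes):
            raise ValueError("chromosome lengths must be strictly positive")
        object.__setattr__(self, "chromosomes", chromosomes)
        object.__setattr__(self, "_lengths", dict(chromosomes))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def total_size(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths


def read_chrom_sizes(path) -> GenomeSpec:
    """Read a UCSC-style chrom.sizes file (name<TAB>length)."""
    chroms = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i}: expected 2 tab-separated columns")
            try:
                chroms.append((parts[0], int(parts[1])))
            except ValueError:
                raise ValueError(f"{path}:{i}: non-integer length {parts[1]!r}") from None
    return GenomeSpec(chroms)


def write_chrom_sizes(genome: GenomeSpec, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")
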