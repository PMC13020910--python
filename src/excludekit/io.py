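"""Readers and writers for the plain-text formats the toolkit consumes.

BED3/BED6 exclusion sets (annotation string kept verbatim in column 4),
bedGraph tracks, tagAlign-like read tables, and a minimal GTF subset for
transcript models. A BAM adapter is provided for convenience but nothing
in the package requires it.
"""

from __future__ import annotations

import pandas as pd

from .genome import GenomeSpec
from .intervals import Region, RegionSet

READ_COLUMNS = ["chrom", "start", "end", "strand"]


class BedParseError(ValueError):
    pass


def read_regions(path, format: str = "bed6", genome: GenomeSpec | None = None,
                 name: str | None = None) -> RegionSet:
    """Read a BED3/BED6 file into a RegionSet.

    Column 4, when present, is preserved verbatim as the region label
    (annotations such as "High Signal, Low Mappability" may contain commas).
    """
    if format not in ("bed3", "bed6"):
        raise ValueError(f"unknown format {format!r}")
    regions: list[Region] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{i}: expected >=3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError(f"{path}:{i}: non-integer coordinates") from None
            if start >= end or start < 0:
                raise BedParseError(f"{path}:{i}: invalid interval [{start},{end})")
            label = parts[3] if len(parts) > 3 and format == "bed6" else ""
            score = None
            if len(parts) > 4 and format == "bed6" and parts[4] not in ("", "."):
                try:
                    score = float(parts[4])
                except ValueError:
                    raise BedParseError(f"{path}:{i}: non-numeric score") from None
            regions.append(Region(parts[0], start, end, label, score))
    return RegionSet(name if name is not None else str(path), regions, genome)


def write_regions(s: RegionSet, path, format: str = "bed6") -> None:
    """Write a RegionSet as headerless BED; round-trips through read_regions."""
    if format not in ("bed3", "bed6"):
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        for r in s.regions:
            if format == "bed3":
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            else:
                score = 0 if r.score is None else r.score
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t{score:g}\t.\n")


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph file (chrom, start, end, value)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str, "start": int, "end": int, "value": float})
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise BedParseError(f"{path}: invalid bedGraph intervals")
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])


def read_reads(path) -> pd.DataFrame:
    """Read a tagAlign/BED-like read table (chrom, start, end[, strand])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise BedParseError(f"{path}: expected >=3 columns")
    df = df.iloc[:, : min(4, df.shape[1])]
    df.columns = READ_COLUMNS[: df.shape[1]]
    if "strand" not in df.columns:
        df["strand"] = "+"
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_reads(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=READ_COLUMNS)


def reads_from_bam(path) -> pd.DataFrame:
    """Adapter: load aligned reads from a BAM file (requires pysam)."""
    import pysam  # optional dependency, I/O boundary only

    rows = []
    with pysam.AlignmentFile(path, "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            rows.append((aln.reference_name, aln.reference_start,
                         aln.reference_end, "-" if aln.is_reverse else "+"))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def five_prime_positions(reads: pd.DataFrame) -> pd.DataFrame:
    """5' base of each read: start on the + strand, end-1 on the - strand."""
    pos = reads["start"].to_numpy().copy()
    rev = (reads["strand"] == "-").to_numpy()
    pos[rev] = reads["end"].to_numpy()[rev] - 1
    return pd.DataFrame({"chrom": reads["chrom"], "pos": pos})
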