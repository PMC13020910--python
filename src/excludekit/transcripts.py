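"""Transcript models with biotypes, plus a minimal GTF exon-line reader/writer."""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

BIOTYPES = ("protein_coding", "lncRNA", "other")

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


@dataclass
class TranscriptModel:
    """A transcript as a set of sorted, disjoint exons on one chromosome."""

    transcript_id: str
    gene_id: str
    biotype: str
    chrom: str
    exons: list[tuple[int, int]]

    def __post_init__(self):
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for a, b in self.exons:
            if a >= b or a < 0:
                raise ValueError(f"{self.transcript_id}: invalid exon [{a},{b})")
            if a < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = b
        if self.biotype not in BIOTYPES:
            warnings.warn(
                f"{self.transcript_id}: unknown biotype {self.biotype!r} mapped to 'other'"
            )
            self.biotype = "other"

    @property
    def exonic_width(self) -> int:
        return sum(b - a for a, b in self.exons)


def read_gtf(path) -> list[TranscriptModel]:
    """Read transcript models from the exon lines of a GTF file.

    Only `exon` features are used; required attributes are transcript_id and
    gene_id, with the biotype taken from transcript_biotype/gene_biotype
    (missing biotypes become "other"). GTF coordinates are 1-based inclusive
    and are converted to 0-based half-open.
    """
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{i}: expected 9 GTF columns")
            if parts[2] != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(parts[8]))
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}:{i}: exon without transcript_id")
            rec = exons.setdefault(tid, {
                "gene_id": attrs.get("gene_id", tid),
                "biotype": attrs.get("transcript_biotype",
                                     attrs.get("gene_biotype", "other")),
                "chrom": parts[0],
                "exons": [],
            })
            rec["exons"].append((int(parts[3]) - 1, int(parts[4])))
    return [
        TranscriptModel(tid, rec["gene_id"], rec["biotype"], rec["chrom"], rec["exons"])
        for tid, rec in exons.items()
    ]


def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for a, b in t.exons:
                attrs = (f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                         f'transcript_biotype "{t.biotype}";')
                fh.write(f"{t.chrom}\texcludekit\texon\t{a + 1}\t{b}\t.\t+\t.\t{attrs}\n")
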