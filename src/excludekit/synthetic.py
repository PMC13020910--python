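"""Seeded synthetic fixtures: toy genomes, planted truth, reads, transcripts.

The generator emulates the study conditions of input ChIP-seq exclusion-set
calling: multi-sample uniform (Poisson) background coverage with planted
high-pileup artifact regions (background rate times an enrichment factor),
low-mappability stretches with suppressed coverage, a matching per-base
mappability track (exactly <= 0.01 on planted low-mappability truth, 1.0
elsewhere), and transcript models for exon-impact reports. Everything is
bit-reproducible under a fixed seed; reads are emitted as tagAlign-like
tables so no alignment toolchain is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .intervals import Region, RegionSet
from .transcripts import TranscriptModel

__all__ = ["TruthBundle", "make_genome", "plant_truth", "simulate_reads",
           "simulate_transcripts", "recovery_metrics"]

LM_MAPPABILITY_VALUE = 0.005  # track value on planted low-mappability truth


@dataclass
class TruthBundle:
    genome: GenomeSpec
    hs_truth: RegionSet
    lm_truth: RegionSet
    mappability: pd.DataFrame
    params: dict
    seed: int


def make_genome(n_chrom: int, lengths: list[int], seed: int = 0) -> GenomeSpec:
    """Toy genome with chromosomes chr1..chrN of the given lengths."""
    if n_chrom != len(lengths):
        raise ValueError(f"n_chrom={n_chrom} but {len(lengths)} lengths given")
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    return GenomeSpec([(f"chr{i + 1}", int(l)) for i, l in enumerate(lengths)])


def _pack_intervals(rng, genome: GenomeSpec, widths: list[int],
                    min_separation: int, max_tries: int = 10_000):
    """Place intervals uniformly at random, pairwise separated by > min_separation."""
    placed: list[tuple[str, int, int]] = []
    chrom_lengths = list(genome.chromosomes)
    total = genome.total_size
    for w in widths:
        ok = False
        for _ in range(max_tries):
            u = rng.integers(0, total)
            acc = 0
            for chrom, length in chrom_lengths:
                if u < acc + length:
                    start = int(u - acc)
                    break
                acc += length
            if start + w > length:
                continue
            cand = (chrom, start, start + w)
            if all(c != chrom or start - e > min_separation or s - (start + w) > min_separation
                   for c, s, e in placed):
                placed.append(cand)
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place a {w} bp interval with separation {min_separation}: "
                "requested footprint does not fit the genome")
    return placed


def plant_truth(genome: GenomeSpec, n_hs: int = 8,
                hs_width_range: tuple[int, int] = (5_000, 50_000),
                n_lm: int = 5,
                lm_width_range: tuple[int, int] = (10_000, 100_000),
                min_separation: int = 25_000, seed: int = 1) -> TruthBundle:
    """Plant disjoint high-signal and low-mappability truth regions.

    All planted regions (of either kind) are pairwise separated by more than
    min_separation so that, with min_separation above the caller's bridge,
    every truth region maps to exactly one called region. The mappability
    track is 1.0 everywhere except the low-mappability truth.
    """
    rng = np.random.default_rng(seed)
    hs_widths = [int(rng.integers(*hs_width_range, endpoint=True)) for _ in range(n_hs)]
    lm_widths = [int(rng.integers(*lm_width_range, endpoint=True)) for _ in range(n_lm)]
    placed = _pack_intervals(rng, genome, hs_widths + lm_widths, min_separation)
    hs = RegionSet("hs_truth",
                   [Region(c, s, e, "High Signal") for c, s, e in placed[:n_hs]],
                   genome)
    lm = RegionSet("lm_truth",
                   [Region(c, s, e, "Low Mappability") for c, s, e in placed[n_hs:]],
                   genome)
    rows = []
    lm_by_chrom = lm.by_chrom()
    for chrom, length in genome.chromosomes:
        pos = 0
        for r in lm_by_chrom.get(chrom, []):
            if r.start > pos:
                rows.append((chrom, pos, r.start, 1.0))
            rows.append((chrom, r.start, r.end, LM_MAPPABILITY_VALUE))
            pos = r.end
        if pos < length:
            rows.append((chrom, pos, length, 1.0))
    mappability = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    params = dict(n_hs=n_hs, hs_width_range=hs_width_range, n_lm=n_lm,
                  lm_width_range=lm_width_range, min_separation=min_separation)
    return TruthBundle(genome, hs, lm, mappability, params, seed)


def simulate_reads(bundle: TruthBundle, n_samples: int = 5, depth: int = 500_000,
                   enrichment: float = 20.0, lm_retention: float = 0.05,
                   sponge_absorption: float = 0.0, read_len: int = 100,
                   seed: int = 1) -> dict[str, pd.DataFrame]:
    """Simulate per-sample read tables over the planted truth.

    Reads start Poisson-uniformly at the background rate depth/genome_size;
    the rate is multiplied by `enrichment` inside high-signal truth and by
    `lm_retention` inside low-mappability truth. A fraction
    `sponge_absorption` of the artifact reads (the excess above background in
    high-signal regions) is deleted before output, emulating decoy/sponge
    sequences absorbing artifact-prone reads at the alignment step. Samples
    draw from independent streams derived from the seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    for nm, v in (("enrichment", enrichment), ("lm_retention", lm_retention)):
        if v < 0:
            raise ValueError(f"{nm} must be non-negative")
    if not 0 <= sponge_absorption <= 1:
        raise ValueError("sponge_absorption must be in [0, 1]")
    genome = bundle.genome
    rate = depth / genome.total_size
    # segment the genome into (chrom, start, end, class) pieces
    special = sorted(
        [(r.chrom, r.start, r.end, "hs") for r in bundle.hs_truth]
        + [(r.chrom, r.start, r.end, "lm") for r in bundle.lm_truth])
    segments = []
    by_chrom: dict[str, list] = {}
    for item in special:
        by_chrom.setdefault(item[0], []).append(item)
    for chrom, length in genome.chromosomes:
        pos = 0
        for _, s, e, kind in sorted(by_chrom.get(chrom, [])):
            if s > pos:
                segments.append((chrom, pos, s, "bg"))
            segments.append((chrom, s, e, kind))
            pos = e
        if pos < length:
            segments.append((chrom, pos, length, "bg"))

    out = {}
    for k in range(n_samples):
        rng = np.random.default_rng([seed, k])
        chroms, starts = [], []
        for chrom, s, e, kind in segments:
            w = e - s
            if kind == "bg":
                n = rng.poisson(rate * w)
            elif kind == "lm":
                n = rng.poisson(rate * w * lm_retention)
            else:  # hs: background component + thinned artifact excess
                n_bg = rng.poisson(rate * w)
                excess = rate * w * max(enrichment - 1.0, 0.0)
                n = n_bg + rng.poisson(excess * (1.0 - sponge_absorption))
            if n:
                p = rng.integers(s, e, size=n)
                chroms.append(np.full(n, chrom, dtype=object))
                starts.append(p)
        chroms = np.concatenate(chroms) if chroms else np.array([], dtype=object)
        starts = np.concatenate(starts) if starts else np.array([], dtype=int)
        strands = rng.choice(["+", "-"], size=len(starts))
        df = pd.DataFrame({
            "chrom": chroms,
            "start": starts,
            "end": starts + read_len,
            "strand": strands,
        })
        # clip read ends at chromosome boundaries
        lens = df["chrom"].map(dict(genome.chromosomes))
        df["end"] = np.minimum(df["end"], lens)
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort",
                            ignore_index=True)
        out[f"sample{k + 1}"] = df
    return out


def recovery_metrics(called: RegionSet, bundle: TruthBundle) -> dict:
    """Score a called exclusion set against the planted truth.

    jaccard_merged is the Jaccard count overlap between the called set and
    the combined truth, with the union denominator counting merged intervals
    (called and truth boundaries never coincide exactly, so the
    distinct-tuple union would saturate near 0.5 even for perfect recovery).
    label_accuracy is the fraction of called regions whose annotation class
    matches the truth classes they overlap; ambiguous_bare_high_signal counts
    regions overlapping both truth kinds yet labeled plain "High Signal".
    """
    from .intervals import overlap_count
    from .metrics import jaccard_count

    truth = RegionSet("truth", list(bundle.hs_truth) + list(bundle.lm_truth),
                      bundle.genome)
    jc = jaccard_count(called, truth, union="merged") if len(called) else 0.0
    correct = ambiguous_bare = 0
    for r in called:
        probe = RegionSet("probe", [Region(r.chrom, r.start, r.end)])
        in_hs = overlap_count(probe, bundle.hs_truth) > 0
        in_lm = overlap_count(probe, bundle.lm_truth) > 0
        want = ("High Signal, Low Mappability" if in_hs and in_lm
                else "High Signal" if in_hs
                else "Low Mappability" if in_lm else None)
        if want == r.label:
            correct += 1
        if in_hs and in_lm and r.label == "High Signal":
            ambiguous_bare += 1
    return {
        "jaccard_merged": float(jc),
        "label_accuracy": correct / len(called) if len(called) else 0.0,
        "n_called": len(called),
        "n_truth": len(truth),
        "ambiguous_bare_high_signal": ambiguous_bare,
    }


def simulate_transcripts(genome: GenomeSpec, n: int = 50,
                         exons_per_transcript_range: tuple[int, int] = (1, 5),
                         exon_width_range: tuple[int, int] = (200, 2000),
                         biotype_mix: dict[str, float] | None = None,
                         seed: int = 1) -> list[TranscriptModel]:
    """Simulate transcript models with disjoint exons and a biotype mix."""
    if biotype_mix is None:
        biotype_mix = {"protein_coding": 0.6, "lncRNA": 0.25, "other": 0.15}
    biotypes = list(biotype_mix)
    probs = np.array([biotype_mix[b] for b in biotypes], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    chrom_lengths = list(genome.chromosomes)
    weights = np.array([l for _, l in chrom_lengths], dtype=float)
    weights /= weights.sum()
    transcripts = []
    for i in range(n):
        n_ex = int(rng.integers(*exons_per_transcript_range, endpoint=True))
        widths = rng.integers(*exon_width_range, size=n_ex, endpoint=True)
        introns = rng.integers(100, 5000, size=n_ex)
        span = int(widths.sum() + introns[:-1].sum()) if n_ex > 1 else int(widths.sum())
        placed = False
        for _ in range(1000):
            ci = rng.choice(len(chrom_lengths), p=weights)
            chrom, length = chrom_lengths[ci]
            if length <= span:
                continue
            start = int(rng.integers(0, length - span))
            placed = True
            break
        if not placed:
            raise ValueError("could not place transcript: genome too small")
        exons, pos = [], start
        for j in range(n_ex):
            exons.append((pos, pos + int(widths[j])))
            pos += int(widths[j]) + (int(introns[j]) if j < n_ex - 1 else 0)
        biotype = biotypes[int(rng.choice(len(biotypes), p=probs))]
        transcripts.append(TranscriptModel(f"tx{i + 1}", f"gene{i + 1}",
                                           biotype, chrom, exons))
    return transcripts
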