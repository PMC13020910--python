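# Methods

## Interval model

Regions are 0-based half-open intervals on named chromosomes, unstranded,
kept sorted lexicographically by chromosome then (start, end). "Merging
within N bp" joins regions whose inter-region distance (`next.start −
prev.end`) is ≤ N, matching the prevailing genome-arithmetic convention
(`bedtools merge -d N`); N = 0 therefore joins overlapping and bookended
regions only. The footprint width `W(S)` is computed on the self-merged
footprint, so internally overlapping inputs never double-count bases —
exclusion sets are conceptually base sets. Width filters are strict:
"smaller than 1000 bp" removes widths ≤ 999.

Merged regions carry the ordered union of their distinct input labels,
joined by `", "`; the caller re-canonicalizes so a mixed region is always
exactly `High Signal, Low Mappability` regardless of which class appears
first along the chromosome.

The interval algebra (merge, complement, overlap counting, intersection
width) is validated against a per-base boolean-mask brute force on
randomized toy genomes; agreement is exact, not approximate.

## Overlap statistics

The Jaccard count overlap counts regions: the average of the two directed
overlap counts divided by the number of unique regions in the union. "Unique
regions in the union" is ambiguous; we default to distinct
(chrom, start, end) tuples, which makes identical catalogues score 1 and the
small worked example score 0.25. This reading saturates near 0.5 for
catalogues that agree region-for-region but not coordinate-for-coordinate
(as any caller-vs-truth comparison does), so `jaccard_count` also offers
`union="merged"`, which counts intervals of the merged union footprint and
is the reading used to score recovery of planted truth.

The Forbes width overlap `Fw = G·W(A∩B)/(W(A)·W(B))` is base-weighted and
normalized by total genome size, making it robust to catalogues of very
different size and coverage. `Fw(A,A) = G/W(A)`, so the matrix diagonal is
not constant; for distance conversion we first normalize by self-similarity,
`F̂_ij = F_ij/√(F_ii·F_jj) = W(i∩j)/√(W(i)·W(j))`, an Ochiai coefficient
guaranteed to lie in [0, 1], and take `d = 1 − F̂` (for Jaccard, `d = 1 −
Jc`). No transform is canonical here; outputs are labeled with the one used.

Classical (Torgerson) MDS double-centers `−D²/2` and eigendecomposes;
negative eigenvalues (non-Euclidean distances) are truncated to zero with a
warning. Agglomerative clustering uses Lance–Williams recurrences for Ward
and complete linkage with a deterministic tie-break (lexicographically
smallest cluster-id pair). We implement the agglomeration directly to pin
down tie behavior; on tie-free inputs it reproduces
`scipy.cluster.hierarchy.linkage` row-for-row, which the tests check.

## High Signal derivation

Input-library coverage should be near-uniform, so strong local enrichment
marks artifacts. The scanner slides windows (default 300 bp, step = half a
window) and compares the observed count to the largest of three expected
rates: genome-wide, and short/long local backgrounds (slocal = 10 kb,
llocal = 100 kb). Local rates are estimated in two passes: a first pass
flags windows provisionally enriched against the genome-wide rate, and the
local backgrounds are then computed from unmasked bases only, falling back
to the genome-wide rate where a local window is entirely masked. Without
masking, a broad pileup inflates its own local background and reports fold
≈ 1; with it, a 10 kb segment at 10× background is recovered at fold ≈ 10.
Contiguous windows at or above `min_fold_emit` (default 1.5) merge into one
peak carrying the maximum window fold change; duplicate reads all count.

Selection keeps peaks whose fold change strictly exceeds
`min + fraction·(max − min)` with fraction = 0.99 — anchored at the minimum
of the observed range (anchoring at zero is exposed via the `fraction`
parameter if wanted). A degenerate range (all fold changes equal) selects
nothing and warns. Survivors are merged within 1 kb and filtered to ≥ 1 kb,
then unioned with centromeres using gap 0 (overlap/bookend only, since no
merge distance is prescribed for that union); the union is not re-filtered
by width.

## Low Mappability derivation

Five steps on a per-base mappability track in [0, 1]: select the mappable
universe (value > 0.01), merge it within 1 kb (absorbing short unmappable
gaps so interspersed mappable sequence is preserved), invert against the
genome, merge the inversion within 1 kb, and drop regions < 1 kb. Note the
final merge can bridge mappable islands up to 1 kb wide into an output
region; consequently "every output base has mappability ≤ 0.01" holds only
up to such islands, and the property tests assert exactly that (regions
start and end on low-mappability bases; interior high-mappability runs are
≤ the merge gap). Bases absent from the track are treated as mappability 0.

## Exclusion caller

The pipeline is: count read 5′ starts into overlapping bins (default 1 kb
bins, 500 bp overlap; a read counts in every bin containing its 5′ base, so
overlaps cannot create gaps; terminal partial bins participate with their
true width) → normalize to reads per million → aggregate across samples by
the per-bin median (a quantile is available) → flag bins → project flags to
bin extents → merge within the bridge distance (default 20 kb) → annotate →
drop regions < 1 kb.

Flag rules (all exposed as parameters, since the tool this reworks left its
internal thresholds undocumented):

- high signal: signal ≥ the empirical 95th percentile of all bins AND
  strictly > 3× the genome-wide median. The percentile caps how much of the
  genome can ever be flagged (5%); the fold guard does the discriminating,
  so flat coverage yields no flags and the false-flag rate on uniform
  Poisson coverage is ≈ 0. A tighter percentile (e.g. 0.999) caps flagging
  at 0.1% of bins, which cannot cover artifact footprints of a few percent
  of the genome — hence the 0.95 default.
- low mappability: mean bin mappability ≤ 0.1.

Flags are independent; a bridged region containing both kinds is annotated
`High Signal, Low Mappability`, never collapsed to `High Signal`. The k-mer
parameter is provenance metadata of the user-supplied mappability track
(the toolkit does not compute mappability); the track's own single- vs
multi-read convention is accepted as-is and recorded.

## Impact assessment

Transcript impact counts, per set and biotype (protein_coding, lncRNA,
other; unknown biotypes map to other with a warning), the transcripts with
a non-zero sum of exon bases covered by the set, and those base totals.

Correlation impact bins reads into a non-overlapping 10 kb tiling (the
documented default of the reference coverage-summary tool), computes
Pearson correlation on raw counts (no log transform, as none is
prescribed), removes reads sharing ≥ 1 base with the exclusion footprint
(read-level filtering; single-end semantics, each record independent), and
reports `delta = r_after − r_before` with rows ordered by complete-linkage
clustering of Euclidean distances between delta rows. Shared artifact
pileups inflate between-sample correlation, so the mean off-diagonal delta
is negative when real artifacts are removed — and is exactly zero when no
read overlaps the set.

## Synthetic fixtures

`plant_truth` places disjoint high-signal and low-mappability truth regions
(defaults: 8 high-signal of 5–50 kb and 5 low-mappability of 10–100 kb on a
10 Mb genome), pairwise separated by > 25 kb so that, with the default
20 kb bridge, each truth region maps to exactly one called region. The
mappability track is 1.0 everywhere except 0.005 on low-mappability truth.
`simulate_reads` draws Poisson-uniform read starts at rate depth/genome
(default 5×10⁵ reads/sample), multiplied by `enrichment` (default 20)
inside high-signal truth and by `lm_retention` (default 0.05) inside
low-mappability truth; `sponge_absorption` thins the artifact excess above
background, emulating decoy sequences capturing artifact-prone reads at
alignment. Samples use independent seeded streams; all generators are
bit-reproducible.

What the generator does **not** emulate: sequence content and alignment
(reads are interval placements, not FASTQ), mappability gradients (the
track is binary-valued), PCR duplication structure, fragment-length
distributions, paired-end constraints, and chromosome-scale coverage waves.
Passing tests therefore demonstrate the algorithmic contracts — binning,
thresholds, bridging, annotation, metric arithmetic — under an idealized
coverage model, not performance on real libraries.

## Problem sizes and numerical choices

The simulation-backed checks use a 10 Mb single-chromosome genome with
5 samples × 5×10⁵ reads for caller recovery (five independent seeds) and a
2 Mb genome with 3 samples × 10⁵ reads for the correlation-delta
construction; these sizes give stable statistics (recovery is exact and the
delta sign is reproduced on every tested seed) while keeping a full run in
tens of seconds. Quantiles use numpy's default (linear interpolation) on
the aggregated bin signal. MDS eigenvalue truncation and the clustering
tie-break are described above; distance matrices are symmetrized and their
diagonals forced to zero before use. Degenerate inputs fail loudly: empty
read tables, zero-footprint sets in Forbes, two empty sets in Jaccard, and
zero-variance samples in Pearson all raise errors naming the offender.

## Known limitations

- The caller's thresholds are calibrated for input-like (uniform
  background) coverage; enriched libraries (actual ChIP) violate the
  median/percentile logic.
- The fold-enrichment scanner is a deliberately simple local-background
  method, not a reimplementation of any external peak caller's p-value
  machinery; absolute fold changes near segment edges are diluted by
  half-covered windows.
- Jaccard count overlap depends on how region boundaries are drawn by each
  catalogue's merge step; the Forbes width statistic is the more robust
  cross-catalogue comparison and both are reported by the `compare`
  command.
- BAM input is supported only through an adapter requiring pysam; the
  native formats are plain-text tagAlign/BED/bedGraph.
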