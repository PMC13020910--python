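"""Pairwise overlap statistics among exclusion sets and their ordination.

Two similarity measures are used. The Jaccard count overlap

    Jc(A, B) = (1/2) * (|{a in A : a overlaps B}| + |{b in B : b overlaps A}|)
               / |A ∪ B|

counts regions rather than bases, with |A ∪ B| the number of distinct
(chrom, start, end) tuples in the union. The Forbes width overlap

    Fw(A, B) = G * W(A ∩ B) / (W(A) * W(B))

is base-pair-weighted and normalized by the total genome size G, making it
robust to large differences in list size and genome coverage. Similarity
matrices are converted to distances and summarized by classical
(Torgerson) multidimensional scaling and agglomerative clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .intervals import (RegionSet, intersection_width, merge_within,
                        overlap_count, union_unique_count)

__all__ = [
    "OverlapMatrix", "DistanceMatrix", "MdsResult", "LinkageTree",
    "jaccard_count", "forbes_width", "pairwise_matrix",
    "similarity_to_distance", "classical_mds", "linkage",
]


class UndefinedMetricError(ValueError):
    pass


@dataclass
class OverlapMatrix:
    set_names: list[str]
    values: np.ndarray
    metric: str  # {"jaccard_count", "forbes_width"}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.set_names)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match set names")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("overlap matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.set_names, columns=self.set_names)


@dataclass
class DistanceMatrix:
    set_names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite distance entries")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(self.values, 0.0)
        self.values = np.maximum(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.set_names, columns=self.set_names)


@dataclass
class MdsResult:
    set_names: list[str]
    coordinates: np.ndarray  # n x k
    eigenvalues: np.ndarray  # all n, descending


@dataclass
class LinkageTree:
    """Ordered merge steps (cluster_i, cluster_j, height, size), scipy-style.

    Original observations are clusters 0..n-1; the cluster formed at step t
    gets id n+t.
    """

    set_names: list[str]
    merges: np.ndarray  # (n-1) x 4

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges,
                            columns=["cluster_i", "cluster_j", "height", "size"])


def jaccard_count(a: RegionSet, b: RegionSet, union: str = "tuples") -> float:
    """Jaccard count overlap between two region sets.

    `union` selects the denominator reading: "tuples" counts distinct
    (chrom, start, end) tuples in A ∪ B (the default; two near-identical but
    not coordinate-identical catalogues score near 0.5); "merged" counts the
    intervals of the merged union footprint, which is the appropriate reading
    when comparing a called set against a planted truth whose boundaries can
    never coincide exactly.
    """
    if len(a) + len(b) == 0:
        raise UndefinedMetricError("Jaccard count undefined for two empty sets")
    num = 0.5 * (overlap_count(a, b) + overlap_count(b, a))
    if union == "tuples":
        denom = union_unique_count(a, b)
    elif union == "merged":
        denom = len(merge_within(
            RegionSet("union", list(a.regions) + list(b.regions)), 0))
    else:
        raise ValueError(f"unknown union reading {union!r}")
    return num / denom


def forbes_width(a: RegionSet, b: RegionSet, genome: GenomeSpec) -> float:
    wa, wb = a.footprint_width, b.footprint_width
    if wa == 0 or wb == 0:
        raise UndefinedMetricError("Forbes width undefined for a zero-footprint set")
    return genome.total_size * intersection_width(a, b) / (wa * wb)


def pairwise_matrix(sets: list[RegionSet], metric: str,
                    genome: GenomeSpec | None = None) -> OverlapMatrix:
    """Symmetric matrix of per-pair metric values (diagonal = self-metric)."""
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    if metric == "forbes_width" and genome is None:
        raise ValueError("forbes_width requires a genome")
    n = len(sets)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            try:
                if metric == "jaccard_count":
                    v = jaccard_count(sets[i], sets[j])
                elif metric == "forbes_width":
                    v = forbes_width(sets[i], sets[j], genome)
                else:
                    raise ValueError(f"unknown metric {metric!r}")
            except UndefinedMetricError as e:
                raise UndefinedMetricError(
                    f"{sets[i].name} vs {sets[j].name}: {e}") from None
            vals[i, j] = vals[j, i] = v
    return OverlapMatrix([s.name for s in sets], vals, metric)


def similarity_to_distance(m: OverlapMatrix) -> DistanceMatrix:
    """Convert a similarity matrix to a distance matrix in [0, 1].

    Jaccard: d = 1 - Jc. Forbes: self-similarity normalization first,
    F̂_ij = F_ij / sqrt(F_ii F_jj) = W(i∩j)/sqrt(W(i) W(j)) (an Ochiai
    coefficient, always in [0,1]), then d = 1 - F̂.
    """
    v = m.values
    if not np.isfinite(v).all():
        raise ValueError("non-finite similarity entries")
    if m.metric == "jaccard_count":
        d = 1.0 - v
    elif m.metric == "forbes_width":
        diag = np.sqrt(np.diag(v))
        norm = v / np.outer(diag, diag)
        d = 1.0 - norm
    else:
        raise ValueError(f"unknown metric {m.metric!r}")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(m.set_names, np.clip(d, 0.0, None))


def classical_mds(d: DistanceMatrix, k: int = 2) -> MdsResult:
    """Classical (Torgerson) MDS: double-center -D^2/2 and eigendecompose.

    Coordinates come from the top-k non-negative eigenvalues; negative
    eigenvalues (non-Euclidean distances) are truncated to zero with a
    warning.
    """
    dm = d.values
    n = dm.shape[0]
    if k >= n:
        raise ValueError(f"k={k} requires at least {k + 1} sets, got {n}")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[:k].min() < -1e-9 * max(1.0, abs(evals).max()):
        warnings.warn("negative MDS eigenvalues truncated to zero "
                      "(distance matrix is not Euclidean-embeddable)")
    lam = np.clip(evals[:k], 0.0, None)
    coords = evecs[:, :k] * np.sqrt(lam)
    return MdsResult(d.set_names, coords, evals)


def linkage(d: DistanceMatrix, method: str = "ward") -> LinkageTree:
    """Agglomerative clustering via Lance–Williams recurrences.

    Supported methods: "ward" (on a distance matrix, heights are the Ward
    merge distances) and "complete". Ties are broken by the lexicographically
    smallest (i, j) cluster-id pair for reproducibility.
    """
    if method not in ("ward", "complete"):
        raise ValueError(f"unknown method {method!r}")
    n = len(d.set_names)
    if n < 2:
        raise ValueError("need at least 2 observations to cluster")
    dist = d.values.astype(float).copy()
    np.fill_diagonal(dist, np.inf)
    active = {i: (i, 1) for i in range(n)}  # slot -> (cluster id, size)
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        slots = sorted(active)
        # minimal distance; tie-break on smallest (id_i, id_j)
        best = None
        for ii, si in enumerate(slots):
            for sj in slots[ii + 1:]:
                h = dist[si, sj]
                idp = tuple(sorted((active[si][0], active[sj][0])))
                if best is None or h < best[0] - 1e-15 or (
                        abs(h - best[0]) <= 1e-15 and idp < best[1]):
                    best = (h, idp, si, sj)
        h, _, si, sj = best
        (ci, ni), (cj, nj) = active[si], active[sj]
        lo, hi = (ci, cj) if ci < cj else (cj, ci)
        merges[step] = (lo, hi, h, ni + nj)
        # Lance-Williams update into slot si
        for sk in slots:
            if sk in (si, sj):
                continue
            dik, djk = dist[si, sk], dist[sj, sk]
            nk = active[sk][1]
            if method == "complete":
                new = max(dik, djk)
            else:  # ward
                t = ni + nj + nk
                new = np.sqrt(max(((ni + nk) * dik ** 2 + (nj + nk) * djk ** 2
                                   - nk * h ** 2) / t, 0.0))
            dist[si, sk] = dist[sk, si] = new
        dist[sj, :] = dist[:, sj] = np.inf
        del active[sj]
        active[si] = (n + step, ni + nj)
    return LinkageTree(d.set_names, merges)


def write_matrix_tsv(m, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="set")


def read_matrix_tsv(path, metric: str | None = None):
    df = pd.read_csv(path, sep="\t", index_col=0)
    if metric is None:
        return DistanceMatrix(list(df.index), df.to_numpy())
    return OverlapMatrix(list(df.index), df.to_numpy(), metric)
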