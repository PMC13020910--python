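"""Descriptive statistics of exclusion sets (count, coverage, width summary)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .derivation import HIGH_SIGNAL
from .intervals import RegionSet, overlap_count

__all__ = ["describe_sets", "pairwise_overlap_counts"]


def describe_sets(sets: list[RegionSet]) -> pd.DataFrame:
    """Per-set region count, base coverage, width summary, and the fraction of
    regions annotated as (at least) "High Signal"."""
    rows = []
    for s in sets:
        widths = np.array([r.width for r in s.regions])
        n = len(s)
        rows.append({
            "set_name": s.name,
            "count": n,
            "coverage_bp": s.footprint_width,
            "min_width": int(widths.min()) if n else 0,
            "mean_width": float(widths.mean()) if n else 0.0,
            "median_width": float(np.median(widths)) if n else 0.0,
            "max_width": int(widths.max()) if n else 0,
            "high_signal_fraction":
                sum(HIGH_SIGNAL in r.label for r in s.regions) / n if n else 0.0,
        })
    return pd.DataFrame(rows)


def pairwise_overlap_counts(sets: list[RegionSet]) -> pd.DataFrame:
    """Matrix where entry (i, j) is the number of regions of set i overlapping set j."""
    names = [s.name for s in sets]
    mat = np.zeros((len(sets), len(sets)), dtype=int)
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            mat[i, j] = overlap_count(a, b)
    return pd.DataFrame(mat, index=names, columns=names)
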