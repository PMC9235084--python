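"""Insulation-score TAD boundary calling and WT/KO domain comparison.

The insulation score of bin i is log2 of the mean contact count in the
w×w square of the w bins upstream of i against bin i and the w−1 bins
downstream (the contacts crossing the left edge of bin i),
normalised by the chromosome-wide mean of that statistic. Boundaries are
local insulation minima whose prominence (depth below the flanking
maxima) exceeds ``min_drop``; domains are the spans between successive
boundaries, filtered by size. Nested/hierarchical domains are not
modelled — counts, sizes, and boundary stability are the quantities of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import BinTable, ContactMatrix

__all__ = [
    "TadSet", "TadComparison",
    "insulation_profile", "call_tads", "compare_tads",
]


@dataclass
class TadSet:
    bins: BinTable
    boundaries: list[int]                 # sorted global bin indices
    tads: list[tuple[int, int]]           # global [start_bin, end_bin) spans
    insulation: np.ndarray                # per-bin, NaN near chromosome ends

    def sizes_bp(self) -> np.ndarray:
        starts = self.bins.df["start"].to_numpy()
        ends = self.bins.df["end"].to_numpy()
        return np.array([ends[b - 1] - starts[a] for a, b in self.tads], dtype=float)


@dataclass
class TadComparison:
    n_tads_a: int
    n_tads_b: int
    size_quantiles_a: dict[int, float]
    size_quantiles_b: dict[int, float]
    boundary_jaccard: float


def insulation_profile(matrix: ContactMatrix, window: int = 500_000) -> np.ndarray:
    """Per-bin insulation score (log2, centred on the chromosome mean)."""
    bins = matrix.bins
    bin_size = int(bins.df["end"].iloc[0] - bins.df["start"].iloc[0])
    w = int(window // bin_size)
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    out = np.full(bins.n_bins, np.nan)
    for chrom in bins.chroms:
        lo, hi = bins.chrom_range(chrom)
        n = hi - lo
        if w >= n:
            raise ValueError(f"window larger than chromosome {chrom}")
        dense = matrix.dense_chrom(chrom)
        raw = np.full(n, np.nan)
        for i in range(w, n - w):
            raw[i] = dense[i - w: i, i: i + w].mean()
        defined = ~np.isnan(raw)
        mean = np.nanmean(raw)
        if mean <= 0:
            continue
        vals = raw[defined]
        with np.errstate(divide="ignore"):
            out[lo:hi][defined] = np.where(vals > 0, np.log2(vals / mean), np.nan)
    return out


def call_tads(
    bins: BinTable,
    insulation: np.ndarray,
    min_drop: float = 0.1,
    min_size: int = 75_000,
    max_size: int = 5_000_000,
) -> TadSet:
    """Boundaries at insulation minima with prominence >= min_drop."""
    boundaries: list[int] = []
    tads: list[tuple[int, int]] = []
    starts = bins.df["start"].to_numpy()
    ends = bins.df["end"].to_numpy()
    for chrom in bins.chroms:
        lo, hi = bins.chrom_range(chrom)
        ins = insulation[lo:hi]
        defined = np.flatnonzero(~np.isnan(ins))
        if len(defined) < 3:
            continue
        seg = ins[defined[0]: defined[-1] + 1]
        peaks, _ = find_peaks(-seg, prominence=min_drop)
        chrom_bounds = [lo + defined[0] + int(p) for p in peaks]
        boundaries.extend(chrom_bounds)
        for a, b in zip(chrom_bounds[:-1], chrom_bounds[1:]):
            size = ends[b - 1] - starts[a]
            if min_size <= size <= max_size:
                tads.append((a, b))
    return TadSet(bins=bins, boundaries=sorted(boundaries), tads=tads,
                  insulation=insulation)


def _greedy_match(a: np.ndarray, b: np.ndarray, tol: int) -> int:
    """Number of boundary pairs matched within tol bins, each used once."""
    if len(a) == 0 or len(b) == 0:
        return 0
    pairs = [
        (abs(int(x) - int(y)), i, j)
        for i, x in enumerate(a) for j, y in enumerate(b)
        if abs(int(x) - int(y)) <= tol
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = 0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched += 1
    return matched


def compare_tads(a: TadSet, b: TadSet, tolerance: int = 1) -> TadComparison:
    """Boundary Jaccard (±tolerance bins) and size-quantile comparison."""
    if not a.bins.same_as(b.bins):
        raise ValueError("TAD sets have mismatched bin tables")
    ba = np.array(a.boundaries)
    bb = np.array(b.boundaries)
    matched = _greedy_match(ba, bb, tolerance)
    union = len(ba) + len(bb) - matched
    jaccard = matched / union if union else 1.0
    qs = [10, 25, 50, 75, 90]

    def quantiles(ts: TadSet) -> dict[int, float]:
        sizes = ts.sizes_bp()
        if len(sizes) == 0:
            return {q: float("nan") for q in qs}
        return {q: float(np.percentile(sizes, q)) for q in qs}

    return TadComparison(
        n_tads_a=len(a.tads),
        n_tads_b=len(b.tads),
        size_quantiles_a=quantiles(a),
        size_quantiles_b=quantiles(b),
        boundary_jaccard=float(jaccard),
    )
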