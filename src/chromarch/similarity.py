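"""Stratum-adjusted correlation coefficient (SCC) between contact maps.

Both matrices are mean-filter smoothed with half-window ``h``, then a
Pearson correlation r_k is computed per diagonal distance k (stratum)
and combined as Σ w_k r_k / Σ w_k with w_k = n_k·s_k(a)·s_k(b), where
n_k is the pair count and s_k the per-stratum standard deviation. Strata
with fewer than 3 pairs or zero variance carry no weight. Multi-
chromosome SCC is the pair-count-weighted mean over chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ContactMatrix

__all__ = ["SccResult", "smooth_matrix", "scc"]


@dataclass
class SccResult:
    scc: float
    per_stratum: pd.DataFrame  # distance_bp, pearson_r, n_pairs, weight
    h: int
    max_dist: int


def _smooth_dense(dense: np.ndarray, h: int) -> np.ndarray:
    """Mean filter with the neighbourhood clipped at the matrix edge."""
    if h == 0:
        return dense.astype(float)
    size = 2 * h + 1
    num = ndimage.uniform_filter(dense.astype(float), size=size, mode="constant") * size**2
    den = ndimage.uniform_filter(np.ones_like(dense, dtype=float), size=size,
                                 mode="constant") * size**2
    return np.maximum(num / den, 0.0)  # clip float-error negatives


def smooth_matrix(matrix: ContactMatrix, h: int) -> ContactMatrix:
    """Replace each entry by the mean of its (2h+1)×(2h+1) neighbourhood.

    Neighbourhoods are clipped at the chromosome-block edge and
    renormalised by their clipped size; h = 0 is the identity.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    if h == 0:
        return ContactMatrix(matrix.bins, matrix.mat.copy())
    rows, cols, data = [], [], []
    for chrom in matrix.bins.chroms:
        lo, hi = matrix.bins.chrom_range(chrom)
        sm = _smooth_dense(matrix.dense_chrom(chrom), h)
        iu, ju = np.triu_indices(hi - lo)
        keep = sm[iu, ju] != 0
        rows.append(lo + iu[keep])
        cols.append(lo + ju[keep])
        data.append(sm[iu, ju][keep])
    return ContactMatrix.from_coo(
        matrix.bins, np.concatenate(rows), np.concatenate(cols), np.concatenate(data)
    )


def _stratum_table(da: np.ndarray, db: np.ndarray, max_k: int) -> list[tuple[int, float, int, float]]:
    """(k, r_k, n_k, w_k) per usable stratum of one chromosome block."""
    out = []
    n = da.shape[0]
    for k in range(0, min(max_k, n - 1) + 1):
        xa = np.diagonal(da, k)
        xb = np.diagonal(db, k)
        if len(xa) < 3:
            continue
        sa, sb = float(np.std(xa)), float(np.std(xb))
        if sa == 0.0 or sb == 0.0:
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        w = len(xa) * sa * sb
        out.append((k, r, len(xa), w))
    return out


def scc(a: ContactMatrix, b: ContactMatrix, h: int = 1, max_dist: int = 5_000_000) -> SccResult:
    """Stratum-adjusted correlation between two contact matrices."""
    if not a.bins.same_as(b.bins):
        raise ValueError("matrices have mismatched bin tables")
    bin_size = int(a.bins.df["end"].iloc[0] - a.bins.df["start"].iloc[0])
    max_k = max(int(max_dist // bin_size), 1)
    sa = smooth_matrix(a, h)
    sb = smooth_matrix(b, h)

    per_chrom = []
    strata_rows = []
    for chrom in a.bins.chroms:
        da = sa.dense_chrom(chrom)
        db = sb.dense_chrom(chrom)
        strata = _stratum_table(da, db, max_k)
        if not strata:
            continue
        wsum = sum(w for _, _, _, w in strata)
        val = sum(r * w for _, r, _, w in strata) / wsum
        npairs = sum(nk for _, _, nk, _ in strata)
        per_chrom.append((val, npairs))
        for k, r, nk, w in strata:
            strata_rows.append((chrom, k * bin_size, r, nk, w))
    if not per_chrom:
        raise ValueError("no variable strata")
    tot = sum(npairs for _, npairs in per_chrom)
    value = sum(val * npairs for val, npairs in per_chrom) / tot
    table = pd.DataFrame(
        strata_rows, columns=["chrom", "distance_bp", "pearson_r", "n_pairs", "weight"]
    )
    return SccResult(scc=float(value), per_stratum=table, h=h, max_dist=max_dist)
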