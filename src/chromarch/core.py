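"""Core in-memory containers shared by every analysis stage.

The genome is modelled as a dense, globally indexed table of fixed-size
bins (last bin of each chromosome may be short) and a symmetric,
intrachromosomal contact matrix stored as its upper triangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["BinTable", "ContactMatrix"]


class BinTable:
    """Dense, sorted, contiguous genomic bins with a global index.

    Parameters
    ----------
    df : DataFrame with columns ``chrom``, ``start``, ``end``. Row order
        defines the global bin index (0-based, dense).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)[["chrom", "start", "end"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self._validate(df)
        self.df = df
        # chrom -> (lo, hi) global index range, in file order
        self._ranges: dict[str, tuple[int, int]] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            self._ranges[str(chrom)] = (int(grp.index[0]), int(grp.index[-1]) + 1)

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if len(df) == 0:
            raise ValueError("bin table is empty")
        if (df["start"] >= df["end"]).any():
            bad = int(np.argmax((df["start"] >= df["end"]).to_numpy()))
            raise ValueError(f"bin {bad}: start >= end")
        seen: set[str] = set()
        prev_chrom = None
        prev_end = None
        for idx, (chrom, start, end) in enumerate(
            zip(df["chrom"], df["start"], df["end"])
        ):
            if chrom != prev_chrom:
                if chrom in seen:
                    raise ValueError(f"bin {idx}: chromosome {chrom} not grouped")
                seen.add(chrom)
                if start != 0:
                    raise ValueError(f"bin {idx}: first bin of {chrom} does not start at 0")
            else:
                if start != prev_end:
                    raise ValueError(f"bin {idx}: bins not contiguous on {chrom}")
            prev_chrom, prev_end = chrom, end

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(self._ranges)

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Global index half-open range [lo, hi) of a chromosome."""
        return self._ranges[chrom]

    def chrom_size(self, chrom: str) -> int:
        lo, hi = self._ranges[chrom]
        return int(self.df["end"].iloc[hi - 1])

    def bin_index(self, chrom: str, pos: np.ndarray | int) -> np.ndarray:
        """Global bin index containing each position (−1 if off the end)."""
        lo, hi = self._ranges[chrom]
        ends = self.df["end"].to_numpy()[lo:hi]
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        local = np.searchsorted(ends, pos, side="right")
        out = np.where((pos >= 0) & (local < hi - lo), local + lo, -1)
        return out

    @classmethod
    def from_chrom_sizes(cls, chrom_sizes: dict[str, int], bin_size: int) -> "BinTable":
        rows = []
        for chrom, size in chrom_sizes.items():
            starts = np.arange(0, size, bin_size, dtype=np.int64)
            ends = np.minimum(starts + bin_size, size)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return cls(pd.concat(rows, ignore_index=True))

    def same_as(self, other: "BinTable") -> bool:
        return self.df.equals(other.df)


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts, upper triangle stored.

    ``mat`` is an n×n sparse matrix holding only entries with i ≤ j;
    queries for (j, i) resolve to (i, j). Counts may be real-valued after
    smoothing; raw simulated/parsed matrices hold nonnegative integers.
    """

    bins: BinTable
    mat: sp.csr_matrix = field(repr=False)

    @classmethod
    def from_coo(cls, bins: BinTable, i, j, counts) -> "ContactMatrix":
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.float64)
        if np.any(counts < 0):
            raise ValueError("negative contact count")
        n = bins.n_bins
        if len(i) and (i.min() < 0 or j.min() < 0 or i.max() >= n or j.max() >= n):
            raise ValueError("bin index out of range")
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        m = sp.coo_matrix((counts, (lo, hi)), shape=(n, n)).tocsr()
        m.sum_duplicates()
        return cls(bins, m)

    def dense_chrom(self, chrom: str) -> np.ndarray:
        """Full symmetric dense block for one chromosome."""
        lo, hi = self.bins.chrom_range(chrom)
        block = self.mat[lo:hi, lo:hi].toarray()
        sym = block + block.T
        sym[np.diag_indices_from(sym)] -= np.diag(block)
        return sym

    def to_triplets(self) -> pd.DataFrame:
        coo = self.mat.tocoo()
        df = pd.DataFrame({"i": coo.row, "j": coo.col, "count": coo.data})
        return df.sort_values(["i", "j"]).reset_index(drop=True)

    def scaled(self, c: float) -> "ContactMatrix":
        return ContactMatrix(self.bins, self.mat * c)

    def equals(self, other: "ContactMatrix", tol: float = 0.0) -> bool:
        if not self.bins.same_as(other.bins):
            return False
        diff = (self.mat - other.mat).tocoo()
        if len(diff.data) == 0:
            return True
        return bool(np.max(np.abs(diff.data)) <= tol)
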