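"""Peak/compartment co-localization and boundary signal metaplots.

A peak belongs to the compartment of the bin containing its midpoint
(max-overlap assignment available behind a flag). The metaplot averages
a signal track in a fixed window centred on compartment boundaries,
oriented with the B side at negative offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compartments import CompartmentProfile

__all__ = ["OccupancySummary", "Metaplot", "peak_compartment_fraction", "boundary_metaplot"]


@dataclass
class OccupancySummary:
    n_peaks: int          # peaks with a labeled (non-NA) midpoint bin
    n_in_A: int
    fraction_A: float
    n_excluded_na: int    # midpoints in masked bins (reported, not counted)


@dataclass
class Metaplot:
    offsets: np.ndarray        # bp relative to boundary, symmetric around 0
    mean_signal: np.ndarray
    n_contributing: np.ndarray
    coverage_fraction: np.ndarray
    n_boundaries: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": self.offsets,
            "mean_signal": self.mean_signal,
            "n_contributing": self.n_contributing,
            "coverage_fraction": self.coverage_fraction,
        })


def peak_compartment_fraction(
    peaks: pd.DataFrame, profile: CompartmentProfile, assignment: str = "midpoint"
) -> OccupancySummary:
    """Fraction of peaks whose assigned bin is labeled A.

    Peaks in masked (NA) bins are excluded from numerator and denominator
    and reported separately.
    """
    if len(peaks) == 0:
        raise ValueError("no peaks")
    if assignment not in ("midpoint", "max_overlap"):
        raise ValueError("assignment must be 'midpoint' or 'max_overlap'")
    bins = profile.bins
    n_in_a = n_labeled = n_na = 0
    for chrom, grp in peaks.groupby("chrom", sort=False):
        if chrom not in bins.chroms:
            n_na += len(grp)
            continue
        if assignment == "midpoint":
            mids = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
            idx = bins.bin_index(chrom, mids)
        else:
            idx = np.array([
                _max_overlap_bin(bins, chrom, s, e)
                for s, e in zip(grp["start"], grp["end"])
            ])
        for b in idx:
            if b < 0 or profile.label[b] == "NA":
                n_na += 1
            else:
                n_labeled += 1
                if profile.label[b] == "A":
                    n_in_a += 1
    if n_labeled == 0:
        raise ValueError("no peaks fall in labeled bins")
    return OccupancySummary(
        n_peaks=n_labeled,
        n_in_A=n_in_a,
        fraction_A=n_in_a / n_labeled,
        n_excluded_na=n_na,
    )


def _max_overlap_bin(bins, chrom: str, start: int, end: int) -> int:
    lo, hi = bins.chrom_range(chrom)
    starts = bins.df["start"].to_numpy()
    ends = bins.df["end"].to_numpy()
    first = int(bins.bin_index(chrom, start)[0])
    if first < 0:
        return -1
    best, best_ov = -1, 0
    for b in range(first, hi):
        ov = min(end, ends[b]) - max(start, starts[b])
        if ov <= 0:
            break
        if ov > best_ov:
            best, best_ov = b, ov
    return best


def boundary_metaplot(
    signal: pd.DataFrame,
    boundaries: list[tuple[str, int]],
    window: int = 200_000,
    step: int = 25_000,
) -> Metaplot:
    """Average signal around boundaries, B side left of offset 0.

    Sample points are offset-cell centres ±(step/2, 3·step/2, …) up to
    ``window``, so the layout is symmetric around the boundary with no
    sample exactly at 0. Points beyond the track's extent on a chromosome
    do not contribute; points inside the extent but between intervals
    count as signal 0 and lower the reported coverage fraction.
    """
    if len(boundaries) == 0:
        raise ValueError("no boundaries")
    if window < step:
        raise ValueError("window must be at least one step")
    half = step / 2.0
    n_side = int(window // step)
    offsets = np.concatenate([
        -(np.arange(n_side, 0, -1) - 0.5) * step,
        (np.arange(1, n_side + 1) - 0.5) * step,
    ]).astype(float)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int, int]] = {}
    for chrom, grp in signal.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        v = grp["value"].to_numpy(dtype=float)
        by_chrom[str(chrom)] = (s, e, v, int(s.min()), int(e.max()))

    total = np.zeros_like(offsets)
    n_contrib = np.zeros_like(offsets, dtype=np.int64)
    n_covered = np.zeros_like(offsets, dtype=np.int64)
    for chrom, pos in boundaries:
        if chrom not in by_chrom:
            continue
        s, e, v, ext_lo, ext_hi = by_chrom[chrom]
        points = pos + offsets
        inside = (points >= ext_lo) & (points < ext_hi)
        iv = np.searchsorted(e, points[inside], side="right")
        vals = np.zeros(int(inside.sum()))
        covered = (iv < len(s)) & (s[np.minimum(iv, len(s) - 1)] <= points[inside])
        vals[covered] = v[iv[covered]]
        total[inside] += vals
        n_contrib[inside] += 1
        cov_idx = np.flatnonzero(inside)[covered]
        n_covered[cov_idx] += 1

    if not (n_contrib > 0).any():
        raise ValueError("no boundaries overlap the signal track")
    mean = np.full_like(offsets, np.nan)
    np.divide(total, n_contrib, out=mean, where=n_contrib > 0)
    cov = np.zeros_like(offsets)
    np.divide(n_covered, n_contrib, out=cov, where=n_contrib > 0)
    return Metaplot(
        offsets=offsets,
        mean_signal=mean,
        n_contributing=n_contrib,
        coverage_fraction=cov,
        n_boundaries=len(boundaries),
    )
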