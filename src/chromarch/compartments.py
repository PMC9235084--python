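"""Per-bin compartment scores, A/B segmentation, and profile comparison.

Scores are computed per chromosome by the observed/expected–correlation
leading-eigenvector procedure: mask empty bins, normalise each entry by
the mean count at its diagonal distance, correlate the normalised
columns, and take the eigenvector of the largest-magnitude eigenvalue,
rescaled so scores lie in [−1, 1]. The sign is oriented so that positive
scores (the A compartment) correlate with a user-supplied activity
reference track (peak density or gene density).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinTable, ContactMatrix

__all__ = [
    "CompartmentProfile",
    "ProfileComparison",
    "infer_cscores",
    "segment_and_ratio",
    "find_boundaries",
    "compare_profiles",
]

MIN_BINS_PER_CHROM = 20


@dataclass
class CompartmentProfile:
    """Per-bin compartment score in [−1, 1] with A/B/NA labels."""

    bins: BinTable
    cscore: np.ndarray   # float, NaN where masked
    label: np.ndarray    # 'A' / 'B' / 'NA'

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.df.copy()
        df["cscore"] = self.cscore
        df["label"] = self.label
        return df

    def labeled_mask(self) -> np.ndarray:
        return self.label != "NA"


@dataclass
class ProfileComparison:
    pearson_r: float
    n_bins_compared: int
    switched_bins: list[int]
    ab_ratio_a: float
    ab_ratio_b: float


def _labels_from_scores(cscore: np.ndarray) -> np.ndarray:
    label = np.full(cscore.shape, "NA", dtype="U2")
    label[np.nan_to_num(cscore, nan=0.0) > 0] = "A"
    label[np.nan_to_num(cscore, nan=0.0) < 0] = "B"
    label[np.isnan(cscore)] = "NA"
    return label


def chromosome_cscores(dense: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Leading-eigenvector compartment scores for one dense chromosome block.

    Returns per-bin scores in [−1, 1] with NaN for masked bins. Raises if
    no bin carries usable signal.
    """
    n = dense.shape[0]
    marginals = dense.sum(axis=0)
    keep = marginals > 0
    if not keep.any():
        raise ValueError("chromosome has no usable bins")
    sub = dense[np.ix_(keep, keep)].astype(float)
    m = sub.shape[0]

    # observed / expected by diagonal distance
    idx = np.arange(m)
    dist = np.abs(idx[:, None] - idx[None, :])
    expected = np.array([sub.diagonal(k).mean() for k in range(m)])
    exp_mat = expected[dist]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(exp_mat > 0, sub / exp_mat, 0.0)

    col_sd = oe.std(axis=0)
    variable = col_sd > 0
    if not variable.any():
        raise ValueError("chromosome has no usable bins (all O/E columns constant)")
    oev = oe[np.ix_(variable, variable)]
    if oev.shape[0] < 2:
        raise ValueError("chromosome has no usable bins (fewer than 2 variable bins)")
    corr = np.corrcoef(oev, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)

    eigvals, eigvecs = np.linalg.eigh(corr)
    lead = int(np.argmax(np.abs(eigvals)))
    vec = eigvecs[:, lead]
    vec = vec / np.max(np.abs(vec))

    scores = np.full(n, np.nan)
    kept_idx = np.flatnonzero(keep)[variable]
    scores[kept_idx] = vec

    ref = reference[: n]
    ok = ~np.isnan(scores)
    if ok.sum() >= 2 and np.std(ref[ok]) > 0 and np.std(scores[ok]) > 0:
        r = np.corrcoef(scores[ok], ref[ok])[0, 1]
        if r < 0:
            scores = -scores
    return scores


def infer_cscores(
    matrix: ContactMatrix, reference: np.ndarray, min_bins: int = MIN_BINS_PER_CHROM
) -> CompartmentProfile:
    """Compartment profile over all chromosomes of a contact matrix.

    ``reference`` is a per-bin activity signal (see
    :func:`chromarch.io.track_bin_values`) used only to orient the sign
    of each chromosome's eigenvector so that A is the active compartment.
    """
    bins = matrix.bins
    reference = np.asarray(reference, dtype=float)
    if reference.shape[0] != bins.n_bins:
        raise ValueError("reference must provide one value per bin")
    cscore = np.full(bins.n_bins, np.nan)
    for chrom in bins.chroms:
        lo, hi = bins.chrom_range(chrom)
        if hi - lo < min_bins:
            raise ValueError(
                f"chromosome {chrom} has fewer than {min_bins} bins"
            )
        dense = matrix.dense_chrom(chrom)
        try:
            cscore[lo:hi] = chromosome_cscores(dense, reference[lo:hi])
        except ValueError as exc:
            raise ValueError(f"{chrom}: {exc}") from None
    return CompartmentProfile(bins=bins, cscore=cscore, label=_labels_from_scores(cscore))


def segment_and_ratio(
    profile: CompartmentProfile,
) -> tuple[pd.DataFrame, float]:
    """Maximal same-label runs as segments, plus the A:B length ratio.

    NA bins break no runs but contribute to neither total; the ratio is
    total A bp / total B bp (infinite, with a warning, if no B exists).
    """
    if not profile.labeled_mask().any():
        raise ValueError("profile has no labeled bins")
    df = profile.bins.df
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    rows = []
    for chrom in profile.bins.chroms:
        lo, hi = profile.bins.chrom_range(chrom)
        run_label, run_start = None, None
        prev_end = None
        for b in range(lo, hi):
            lab = profile.label[b]
            if lab == "NA":
                continue
            if lab != run_label:
                if run_label is not None:
                    rows.append((run_label, chrom, run_start, prev_end))
                run_label, run_start = lab, int(starts[b])
            prev_end = int(ends[b])
        if run_label is not None:
            rows.append((run_label, chrom, run_start, prev_end))
    segments = pd.DataFrame(rows, columns=["compartment", "chrom", "start", "end"])

    labeled = profile.labeled_mask()
    lengths = ends - starts
    a_bp = int(lengths[(profile.label == "A")].sum())
    b_bp = int(lengths[(profile.label == "B") & labeled].sum())
    if b_bp == 0:
        warnings.warn("no B compartment bins; A:B ratio is infinite", stacklevel=2)
        ratio = float("inf")
    else:
        ratio = a_bp / b_bp
    return segments, ratio


def find_boundaries(
    profile: CompartmentProfile, direction: str = "B->A"
) -> list[tuple[str, int]]:
    """Compartment-transition positions (chrom, bp of the run's first bin).

    A B→A boundary is the start of the first A bin of each maximal A run
    whose nearest labeled left neighbour is B; NA runs in between are
    skipped and create no boundary of their own.
    """
    if direction not in ("B->A", "A->B"):
        raise ValueError("direction must be 'B->A' or 'A->B'")
    left, right = direction.split("->")
    starts = profile.bins.df["start"].to_numpy()
    out = []
    for chrom in profile.bins.chroms:
        lo, hi = profile.bins.chrom_range(chrom)
        prev_label = None
        for b in range(lo, hi):
            lab = profile.label[b]
            if lab == "NA":
                continue
            if prev_label == left and lab == right:
                out.append((chrom, int(starts[b])))
            prev_label = lab
    return out


def compare_profiles(
    wt: CompartmentProfile, dko: CompartmentProfile, switch_threshold: float = 0.2
) -> ProfileComparison:
    """Pearson r over jointly labeled bins and compartment-switch calls.

    A bin switches when its score flips sign between the two profiles and
    the absolute score change is at least ``switch_threshold`` (default
    0.2, suppressing sign flips of near-zero scores).
    """
    if not wt.bins.same_as(dko.bins):
        raise ValueError("profiles have mismatched bin tables")
    both = wt.labeled_mask() & dko.labeled_mask()
    n = int(both.sum())
    if n < 2:
        raise ValueError("fewer than 2 jointly labeled bins")
    a = wt.cscore[both]
    b = dko.cscore[both]
    r = float(np.corrcoef(a, b)[0, 1])
    flip = (np.sign(wt.cscore) * np.sign(dko.cscore) < 0) & both
    big = np.abs(np.nan_to_num(wt.cscore) - np.nan_to_num(dko.cscore)) >= switch_threshold
    switched = np.flatnonzero(flip & big).tolist()
    _, ratio_wt = segment_and_ratio(wt)
    _, ratio_dko = segment_and_ratio(dko)
    return ProfileComparison(
        pearson_r=r,
        n_bins_compared=n,
        switched_bins=switched,
        ab_ratio_a=ratio_wt,
        ab_ratio_b=ratio_dko,
    )
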