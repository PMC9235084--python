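"""Planted-truth simulation of every pipeline input.

Each generator derives its own random stream from ``(seed, op_name)`` so
that adding or re-running one generator never shifts another's output,
and every output is bit-identical across calls with an equal config.

The simulated genome has alternating A/B compartment blocks with
geometric block lengths, a contact matrix with power-law distance decay,
a multiplicative compartment checkerboard, and a within-TAD boost;
ChIP-style peaks are placed with configurable odds favouring A bins;
capture-style interaction calls get a planted other-end feature
enrichment; and label-free abundance tables carry planted binding
partners that are absent (or leak weakly) in the knockout channel.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinTable, ContactMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_compartment_truth",
    "simulate_contact_matrix",
    "simulate_peaks",
    "simulate_interactions",
    "simulate_abundance_table",
    "simulate_go_annotation",
]


@dataclass
class SimulationConfig:
    """Study-condition parameters for all generators.

    Defaults describe a desk-scale genome: a few tens of megabases binned
    at 25 kb, compartment blocks of ~500 kb, contact decay ~ d^-1, TADs
    of mean 750 kb with a 3x within-domain boost, peaks with 4:1 odds for
    A bins, capture calls confined to 1 Mb with a planted 2x other-end
    feature enrichment, and 1000 proteins of which 5% are true partners.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    bin_size: int = 25_000
    a_fraction: float = 0.45
    mean_block_len: int = 500_000
    compartment_strength: float = 0.6   # kappa
    decay_exponent: float = 1.0         # alpha
    depth: int = 200_000                # expected contacts per chromosome
    overdispersion: float = 0.0         # gamma-Poisson mixing variance (0 = Poisson)
    tad_mean_size: int = 750_000
    tad_boost: float = 3.0              # tau
    peak_count: int = 10_000
    peak_a_enrichment: float = 4.0      # e (odds multiplier; inf = A only)
    peak_width: int = 300
    signal_noise: float = 0.1
    n_fragments: int = 3_000            # per chromosome
    n_baits: int = 80                   # per chromosome
    calls_per_bait: int = 6
    max_call_dist: int = 1_000_000
    call_dist_offset: int = 150_000     # softens the call distance decay
    feature_fold: float = 2.0           # phi
    feature_base_rate: float = 0.15
    n_proteins: int = 1_000
    partner_fraction: float = 0.05
    abundance_location: float = 14.0    # ln-scale location of abundances
    abundance_scale: float = 1.5
    replicate_noise: float = 0.3        # ln-scale replicate-to-replicate sd
    partner_leak: float = 0.0           # DKO abundance of planted partners
    dropout_rate: float = 0.1           # zeroing rate in WT of non-partners
    n_null_terms: int = 100
    n_enriched_terms: int = 3
    term_size: int = 25
    enrichment_bias: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("a_fraction", "partner_fraction", "dropout_rate",
                     "feature_base_rate", "enrichment_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.compartment_strength < 0:
            raise ValueError("compartment_strength must be >= 0")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.tad_boost < 1:
            raise ValueError("tad_boost must be >= 1")
        if self.feature_fold < 1:
            raise ValueError("feature_fold must be >= 1")
        if self.peak_a_enrichment < 1:
            raise ValueError("peak_a_enrichment must be >= 1")
        if self.bin_size <= 0 or self.depth <= 0:
            raise ValueError("bin_size and depth must be positive")
        if self.n_baits > self.n_fragments:
            raise ValueError("n_baits cannot exceed n_fragments")

    def bins(self) -> BinTable:
        return BinTable.from_chrom_sizes(self.chrom_sizes, self.bin_size)

    def rng(self, op_name: str, *extra: int) -> np.random.Generator:
        """Independent stream per (seed, operation[, extras])."""
        key = zlib.crc32(op_name.encode())
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), key, *map(int, extra)])
        )


@dataclass
class GroundTruth:
    """Planted state the recovery tests grade against."""

    bins: BinTable
    labels: np.ndarray                      # per-bin 'A' / 'B'
    tad_intervals: list[tuple[int, int]]    # global [start_bin, end_bin) spans
    partner_ids: set[str] = field(default_factory=set)
    enriched_terms: set[str] = field(default_factory=set)

    def signs(self) -> np.ndarray:
        return np.where(self.labels == "A", 1.0, -1.0)

    def boundary_bins(self, direction: str = "B->A") -> list[int]:
        """Global indices of the first bin after each label transition."""
        if direction not in ("B->A", "A->B"):
            raise ValueError("direction must be 'B->A' or 'A->B'")
        left, right = direction.split("->")
        out = []
        for chrom in self.bins.chroms:
            lo, hi = self.bins.chrom_range(chrom)
            lab = self.labels[lo:hi]
            for k in range(1, len(lab)):
                if lab[k - 1] == left and lab[k] == right:
                    out.append(lo + k)
        return out

    def boundary_positions(self, direction: str = "B->A") -> list[tuple[str, int]]:
        starts = self.bins.df["start"].to_numpy()
        chroms = self.bins.df["chrom"].to_numpy()
        return [(str(chroms[b]), int(starts[b])) for b in self.boundary_bins(direction)]


# ---------------------------------------------------------------- truth --
def simulate_compartment_truth(config: SimulationConfig) -> GroundTruth:
    """Alternating A/B blocks with geometric lengths plus a TAD tiling.

    Block lengths are geometric in bins with label-specific means
    2·a_fraction·mean_block_len (A) and 2·(1−a_fraction)·mean_block_len
    (B), so strict alternation still converges to the target A fraction.
    """
    rng = config.rng("compartment_truth")
    bins = config.bins()
    labels = np.empty(bins.n_bins, dtype=object)
    tads: list[tuple[int, int]] = []

    mean_bins = {
        "A": max(2.0 * config.a_fraction * config.mean_block_len / config.bin_size, 1.0),
        "B": max(2.0 * (1.0 - config.a_fraction) * config.mean_block_len / config.bin_size, 1.0),
    }
    tad_mean_bins = max(config.tad_mean_size / config.bin_size, 1.0)

    for chrom in bins.chroms:
        lo, hi = bins.chrom_range(chrom)
        n = hi - lo
        if config.a_fraction == 1.0:
            labels[lo:hi] = "A"
        elif config.a_fraction == 0.0:
            labels[lo:hi] = "B"
        else:
            lab = "A" if rng.random() < config.a_fraction else "B"
            k = 0
            while k < n:
                blen = int(rng.geometric(1.0 / mean_bins[lab]))
                labels[lo + k: lo + min(k + blen, n)] = lab
                k += blen
                lab = "B" if lab == "A" else "A"
        k = 0
        while k < n:
            tlen = max(int(rng.geometric(1.0 / tad_mean_bins)), 2)
            tads.append((lo + k, lo + min(k + tlen, n)))
            k += tlen
    return GroundTruth(bins=bins, labels=labels.astype("U1"), tad_intervals=tads)


# -------------------------------------------------------------- matrix --
def simulate_contact_matrix(
    truth: GroundTruth, config: SimulationConfig, replicate_seed: int = 0
) -> ContactMatrix:
    """Poisson contact counts: depth · (d+1)^−α · (1 + κ·s_i·s_j) · τ^[same TAD].

    With ``overdispersion`` v > 0 the Poisson mean is itself gamma-mixed
    with unit mean and variance v (negative-binomial counts).
    """
    rng = config.rng("contact_matrix", replicate_seed)
    bins = truth.bins
    signs = truth.signs()
    tad_of = np.full(bins.n_bins, -1, dtype=np.int64)
    for t, (a, b) in enumerate(truth.tad_intervals):
        tad_of[a:b] = t

    rows, cols, data = [], [], []
    for chrom in bins.chroms:
        lo, hi = bins.chrom_range(chrom)
        n = hi - lo
        iu, ju = np.triu_indices(n)
        d = ju - iu
        mu = (d + 1.0) ** (-config.decay_exponent)
        mu *= 1.0 + config.compartment_strength * signs[lo + iu] * signs[lo + ju]
        same_tad = (tad_of[lo + iu] == tad_of[lo + ju]) & (tad_of[lo + iu] >= 0)
        mu[same_tad] *= config.tad_boost
        total = mu.sum()
        if total > 0:
            mu *= config.depth / total
        if config.overdispersion > 0:
            v = config.overdispersion
            mu = mu * rng.gamma(1.0 / v, v, size=mu.shape)
        counts = rng.poisson(mu)
        keep = counts > 0
        rows.append(lo + iu[keep])
        cols.append(lo + ju[keep])
        data.append(counts[keep])
    return ContactMatrix.from_coo(
        bins, np.concatenate(rows), np.concatenate(cols), np.concatenate(data)
    )


# --------------------------------------------------------------- peaks --
def simulate_peaks(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A-biased peak set plus its per-bin coverage signal track.

    Each peak's bin is drawn with probability proportional to the odds
    multiplier ``e`` for A bins versus 1 for B bins (``e`` = inf places
    every peak in an A bin). The signal track is the per-bin count of
    peak midpoints plus exponential noise with mean ``signal_noise``.
    """
    rng = config.rng("peaks")
    bins = truth.bins
    n = bins.n_bins
    e = config.peak_a_enrichment
    is_a = truth.labels == "A"
    if np.isinf(e):
        w = is_a.astype(float)
    else:
        w = np.where(is_a, e, 1.0)
    if w.sum() == 0:
        raise ValueError("no eligible bins for peak placement")
    w = w / w.sum()

    starts = bins.df["start"].to_numpy()
    ends = bins.df["end"].to_numpy()
    chroms = bins.df["chrom"].to_numpy()
    coverage = np.zeros(n)
    rows = []
    if config.peak_count > 0:
        chosen = rng.choice(n, size=config.peak_count, p=w)
        coverage = np.bincount(chosen, minlength=n).astype(float)
        half = config.peak_width // 2
        for b in chosen:
            width = ends[b] - starts[b]
            mid = starts[b] + int(rng.integers(0, width))
            lo_pos = max(mid - half, starts[b])
            hi_pos = min(mid + half + 1, ends[b])
            rows.append((chroms[b], lo_pos, hi_pos))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    peaks = peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    noise = rng.exponential(config.signal_noise, size=n) if config.signal_noise > 0 else 0.0
    track = bins.df.copy()
    track["value"] = coverage + noise
    return peaks, track


# -------------------------------------------------------- interactions --
def simulate_interactions(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fragment map, confident interaction calls, and a planted feature.

    Fragments tile each chromosome evenly; a random subset are baits.
    Other-ends are sampled in cis within ``max_call_dist`` of their bait
    with distance-decaying probability. A feature peak set covers
    other-end fragments with probability φ·base_rate versus base_rate for
    all remaining fragments, so the downstream fold estimate targets φ.
    Every call carries a confidence score ≥ 5.
    """
    rng = config.rng("interactions")
    bins = truth.bins
    frag_rows = []
    for chrom in bins.chroms:
        size = bins.chrom_size(chrom)
        edges = np.linspace(0, size, config.n_fragments + 1).astype(np.int64)
        for k in range(config.n_fragments):
            frag_rows.append((chrom, int(edges[k]), int(edges[k + 1]),
                              f"{chrom}_F{k:05d}"))
    frags = pd.DataFrame(frag_rows, columns=["chrom", "start", "end", "fragment_id"])
    frags["is_bait"] = False

    mids = ((frags["start"] + frags["end"]) // 2).to_numpy()
    chrom_arr = frags["chrom"].to_numpy()

    call_rows = []
    bait_idx_all = []
    for chrom in bins.chroms:
        idx = np.flatnonzero(chrom_arr == chrom)
        baits = rng.choice(idx, size=config.n_baits, replace=False)
        bait_idx_all.extend(baits.tolist())
        for b in baits:
            dist = np.abs(mids[idx] - mids[b])
            bait_set = np.isin(idx, baits)
            cand = idx[(dist <= config.max_call_dist) & (idx != b) & ~bait_set]
            if len(cand) == 0:
                continue
            p = 1.0 / (np.abs(mids[cand] - mids[b]) + config.call_dist_offset + 1.0)
            p /= p.sum()
            k = min(config.calls_per_bait, len(cand))
            oes = rng.choice(cand, size=k, replace=False, p=p)
            for oe in oes:
                score = 5.0 + rng.exponential(5.0)
                call_rows.append((b, oe, score))
    frags.loc[bait_idx_all, "is_bait"] = True

    calls = pd.DataFrame(call_rows, columns=["bait_idx", "oe_idx", "score"])
    fid = frags["fragment_id"].to_numpy()
    calls_out = pd.DataFrame({
        "bait_id": fid[calls["bait_idx"]],
        "otherend_id": fid[calls["oe_idx"]],
        "score": calls["score"].round(4),
    })

    # planted feature: covers other-end fragments at phi x the base rate
    p0 = config.feature_base_rate
    p1 = min(config.feature_fold * p0, 1.0)
    oe_set = set(calls["oe_idx"].tolist())
    carries = np.zeros(len(frags), dtype=bool)
    u = rng.random(len(frags))
    for k in range(len(frags)):
        carries[k] = u[k] < (p1 if k in oe_set else p0)
    feat_rows = []
    for k in np.flatnonzero(carries):
        s, e2 = int(frags["start"].iloc[k]), int(frags["end"].iloc[k])
        width = max((e2 - s) // 3, 1)
        off = int(rng.integers(0, max(e2 - s - width, 1)))
        feat_rows.append((frags["chrom"].iloc[k], s + off, s + off + width))
    feature = pd.DataFrame(feat_rows, columns=["chrom", "start", "end"])
    feature = feature.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return frags, calls_out, feature


# ----------------------------------------------------------- abundance --
def simulate_abundance_table(
    config: SimulationConfig, group_label: str
) -> tuple[pd.DataFrame, set[str]]:
    """Label-free WT/DKO abundance table with planted partners.

    Planted partners (a seed-stable subset shared across groups) are
    present in both WT replicates and carry ``partner_leak`` in DKO;
    non-partners fluctuate around a common level in WT and DKO. Dropout
    zeroes WT entries of non-partners only, so the planted truth stays
    recoverable at any configured dropout rate.
    """
    n = config.n_proteins
    if n < 1:
        raise ValueError("n_proteins must be >= 1")
    ids = np.array([f"P{k:05d}" for k in range(n)])
    n_partners = int(round(config.partner_fraction * n))
    if n_partners < 1:
        warnings.warn("no partners planted", stacklevel=2)
    partner_rng = config.rng("abundance_partners")
    partner_idx = partner_rng.choice(n, size=n_partners, replace=False) if n_partners else []
    is_partner = np.zeros(n, dtype=bool)
    is_partner[partner_idx] = True

    rng = config.rng("abundance", zlib.crc32(group_label.encode()))
    base = rng.lognormal(config.abundance_location, config.abundance_scale, size=n)
    rep = lambda: np.exp(rng.normal(0.0, config.replicate_noise, size=n))  # noqa: E731
    wt1, wt2 = base * rep(), base * rep()
    dko1, dko2 = base * rep(), base * rep()
    # partners: confidently present in WT, absent (or leaking) in DKO
    wt1[is_partner] = np.maximum(wt1[is_partner], 1.0)
    wt2[is_partner] = np.maximum(wt2[is_partner], 1.0)
    dko1[is_partner] = config.partner_leak
    dko2[is_partner] = config.partner_leak
    if config.dropout_rate > 0:
        for col in (wt1, wt2):
            drop = (rng.random(n) < config.dropout_rate) & ~is_partner
            col[drop] = 0.0
    table = pd.DataFrame({
        "protein_id": ids,
        "group": group_label,
        "wt1": wt1, "wt2": wt2, "dko1": dko1, "dko2": dko2,
    })
    return table, set(ids[is_partner])


# ------------------------------------------------------------------ go --
def simulate_go_annotation(
    config: SimulationConfig, partners: set[str], universe: set[str]
) -> tuple[dict[str, tuple[str, frozenset[str]]], set[str]]:
    """Null GMT terms plus planted terms biased toward the partner set."""
    if not partners <= universe:
        raise ValueError("partners must be a subset of the universe")
    rng = config.rng("go_annotation")
    uni = np.array(sorted(universe))
    part = np.array(sorted(partners))
    nonpart = np.array(sorted(universe - partners))
    annotation: dict[str, tuple[str, frozenset[str]]] = {}
    size = min(config.term_size, len(uni))
    for t in range(config.n_null_terms):
        members = rng.choice(uni, size=size, replace=False)
        annotation[f"GO:N{t:04d}"] = ("null term", frozenset(members))
    planted: set[str] = set()
    for t in range(config.n_enriched_terms):
        if len(part) == 0:
            break
        from_part = rng.random(size) < config.enrichment_bias
        k_part = min(int(from_part.sum()), len(part))
        members = np.concatenate([
            rng.choice(part, size=k_part, replace=False),
            rng.choice(nonpart, size=size - k_part, replace=False),
        ])
        term = f"GO:E{t:04d}"
        annotation[term] = ("planted enriched term", frozenset(members))
        planted.add(term)
    return annotation, planted
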