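"""ChIP–MS binding-partner selection, GO over-representation, consensus.

A protein is called a binding partner in an experiment group when it is
present in both WT immunoprecipitation replicates (WT1 ≠ 0 and WT2 ≠ 0)
and its replicate-averaged WT/DKO abundance ratio meets the threshold
(default ≥ 10; DKO average 0 with positive WT gives an infinite ratio,
passing any finite cutoff). Over-representation of partner sets in
annotated categories uses the one-sided Fisher exact (hypergeometric
upper tail) test with Benjamini–Hochberg FDR control, and the consensus
operation intersects significant categories across experiment groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "select_partners", "threshold_sweep", "ora",
    "ConsensusResult", "consensus_categories",
    "DEFAULT_GROUPS",
]

DEFAULT_GROUPS = ("ES_N1", "ES_N2", "MEF_N1", "MEF_N2")


def select_partners(
    records: pd.DataFrame,
    threshold: float = 10.0,
    strict: bool = False,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Apply the partner rule per (protein, group) record.

    Returns the records with ``wt_ave``, ``dko_ave``, ``ratio``,
    ``is_partner`` and ``threshold`` columns added. ``strict`` switches
    the ratio comparison from ≥ to >. A positive ``pseudocount`` is
    added to the DKO average before the ratio (off by default; the
    infinite-ratio convention matches partners being absent in the
    knockout).
    """
    if len(records) == 0:
        raise ValueError("no abundance records")
    for col in ("wt1", "wt2", "dko1", "dko2"):
        if (records[col] < 0).any():
            raise ValueError(f"negative abundance in column {col}")
    if records.duplicated(["protein_id", "group"]).any():
        raise ValueError("duplicate (protein, group) record")
    out = records.copy()
    out["wt_ave"] = (out["wt1"] + out["wt2"]) / 2.0
    out["dko_ave"] = (out["dko1"] + out["dko2"]) / 2.0
    denom = out["dko_ave"] + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            denom > 0,
            out["wt_ave"] / denom,
            np.where(out["wt_ave"] > 0, np.inf, np.nan),
        )
    out["ratio"] = ratio
    present = (out["wt1"] > 0) & (out["wt2"] > 0)
    passes = out["ratio"] > threshold if strict else out["ratio"] >= threshold
    out["is_partner"] = present & passes.fillna(False)
    out["threshold"] = threshold
    return out


def threshold_sweep(
    records: pd.DataFrame,
    thresholds: tuple[float, ...] = (10.0, 50.0, 500.0),
    strict_thresholds: tuple[float, ...] = (500.0,),
) -> pd.DataFrame:
    """Partner counts per ratio cutoff, pooled across experiment groups.

    Reports both tallies: distinct (protein, group) pairs and distinct
    proteins. The 500-fold cutoff is strict (>) while the others are
    inclusive (≥), following the printed convention.
    """
    if list(thresholds) != sorted(thresholds) or min(thresholds) <= 0:
        raise ValueError("thresholds must be positive and ascending")
    rows = []
    for t in thresholds:
        calls = select_partners(records, threshold=t, strict=t in strict_thresholds)
        hit = calls[calls["is_partner"]]
        rows.append((t, t in strict_thresholds, len(hit), hit["protein_id"].nunique()))
    out = pd.DataFrame(
        rows, columns=["threshold", "strict", "n_protein_group_pairs", "n_distinct_proteins"]
    )
    if not out["n_protein_group_pairs"].is_monotonic_decreasing:
        raise AssertionError("partner counts must be non-increasing in threshold")
    return out


def ora(
    sample: set[str],
    universe: set[str],
    annotation: dict[str, tuple[str, frozenset[str]]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher/hypergeometric over-representation per term.

    Term membership is intersected with the universe before testing;
    terms with no universe overlap are skipped. q-values are
    Benjamini–Hochberg across all tested terms and results are sorted by
    descending −log10(q) (ties broken by raw p).
    """
    if not sample <= universe:
        raise ValueError("sample must be a subset of the universe")
    n_universe = len(universe)
    n_sample = len(sample)
    rows = []
    for term_id, (name, members) in annotation.items():
        in_uni = members & universe
        big_k = len(in_uni)
        if big_k == 0:
            continue
        k = len(in_uni & sample)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_sample))
        expected = n_sample * big_k / n_universe
        score = k / expected if expected > 0 else 0.0
        rows.append((term_id, name, k, big_k, expected, score, p))
    df = pd.DataFrame(rows, columns=[
        "term_id", "term_name", "sample_count", "background_count",
        "expected", "enrichment_score", "p_value",
    ])
    if len(df) == 0:
        df["q_value"] = []
        df["neg_log10_q"] = []
        df["significant"] = []
        return df
    _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["q_value"] = q
    with np.errstate(divide="ignore"):
        df["neg_log10_q"] = -np.log10(df["q_value"])
    df["significant"] = df["q_value"] < alpha
    return df.sort_values(
        ["neg_log10_q", "p_value"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


@dataclass
class ConsensusResult:
    consensus_terms: set[str]          # significant in every group
    common_terms: set[str]             # significant in >= 2 groups
    unique_counts: dict[str, int]      # significant in exactly 1 group, per group
    ranking: pd.DataFrame = field(default_factory=pd.DataFrame)


def consensus_categories(
    results_by_group: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    pooled_results: pd.DataFrame | None = None,
    top_k: int = 20,
) -> ConsensusResult:
    """Cross-experiment consensus of significant categories.

    A term is consensus when q < alpha in every group. The optional
    ``pooled_results`` (an ORA run on the pooled partner set) ranks the
    consensus terms by −log10(q) for the top-k listing.
    """
    missing = [g for g in groups if g not in results_by_group]
    if missing:
        raise ValueError(f"missing experiment groups: {missing}")
    sig = {
        g: set(results_by_group[g].loc[results_by_group[g]["q_value"] < alpha, "term_id"])
        for g in groups
    }
    consensus = set.intersection(*sig.values()) if sig else set()
    counts: dict[str, int] = {}
    all_terms = set.union(*sig.values()) if sig else set()
    membership = {t: [g for g in groups if t in sig[g]] for t in all_terms}
    common = {t for t, gs in membership.items() if len(gs) >= 2}
    for g in groups:
        counts[g] = sum(1 for t, gs in membership.items() if gs == [g])

    ranking = pd.DataFrame()
    if pooled_results is not None and len(pooled_results):
        ranking = (
            pooled_results[pooled_results["term_id"].isin(consensus)]
            .sort_values(["neg_log10_q", "p_value"], ascending=[False, True], kind="stable")
            .head(top_k)
            .reset_index(drop=True)
        )
    return ConsensusResult(
        consensus_terms=consensus,
        common_terms=common,
        unique_counts=counts,
        ranking=ranking,
    )
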