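"""Compartment scoring: checkerboard recovery, oracle equivalence, segments."""

import numpy as np
import pytest

from chromarch import (
    BinTable,
    ContactMatrix,
    SimulationConfig,
    compare_profiles,
    find_boundaries,
    infer_cscores,
    segment_and_ratio,
    simulate_compartment_truth,
    simulate_contact_matrix,
)
from chromarch.compartments import chromosome_cscores

from conftest import profile_from_labels, two_block_matrix


def dense_eigen_oracle(dense: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Brute-force scorer: explicit loops, full eigendecomposition."""
    n = dense.shape[0]
    keep = dense.sum(axis=0) > 0
    sub = dense[np.ix_(keep, keep)].astype(float)
    m = sub.shape[0]
    expected = np.zeros(m)
    for k in range(m):
        vals = [sub[i, i + k] for i in range(m - k)]
        expected[k] = np.mean(vals)
    oe = np.zeros_like(sub)
    for i in range(m):
        for j in range(m):
            e = expected[abs(i - j)]
            oe[i, j] = sub[i, j] / e if e > 0 else 0.0
    sd = oe.std(axis=0)
    variable = sd > 0
    oev = oe[np.ix_(variable, variable)]
    corr = np.zeros((oev.shape[1], oev.shape[1]))
    for a in range(oev.shape[1]):
        for b in range(oev.shape[1]):
            corr[a, b] = np.corrcoef(oev[:, a], oev[:, b])[0, 1]
    corr = np.nan_to_num(corr)
    vals, vecs = np.linalg.eig(corr)
    lead = int(np.argmax(np.abs(vals)))
    vec = np.real(vecs[:, lead])
    vec = vec / np.max(np.abs(vec))
    scores = np.full(n, np.nan)
    scores[np.flatnonzero(keep)[variable]] = vec
    ok = ~np.isnan(scores)
    if np.corrcoef(scores[ok], reference[ok])[0, 1] < 0:
        scores = -scores
    return scores


class TestInferCscores:
    def test_perfect_checkerboard(self, bins8):
        cm = two_block_matrix(bins8, within=10, cross=1)
        ref = np.array([1.0] * 4 + [0.0] * 4)  # block 1 is the active side
        prof = infer_cscores(cm, ref, min_bins=4)
        assert list(prof.label[:4]) == ["A"] * 4
        assert list(prof.label[4:]) == ["B"] * 4

    def test_matches_dense_oracle_on_toy(self, bins8):
        rng = np.random.default_rng(42)
        base = two_block_matrix(bins8, within=8, cross=2).dense_chrom("chr1")
        noisy = base + rng.poisson(2.0, size=base.shape)
        noisy = np.triu(noisy)
        noisy = noisy + noisy.T - np.diag(np.diag(noisy))
        iu, ju = np.triu_indices(8)
        cm = ContactMatrix.from_coo(bins8, iu, ju, noisy[iu, ju])
        ref = rng.random(8)
        ours = infer_cscores(cm, ref, min_bins=4).cscore
        oracle = dense_eigen_oracle(noisy, ref)
        # align sign per chromosome before comparing
        if np.nansum(ours * oracle) < 0:
            oracle = -oracle
        np.testing.assert_allclose(ours, oracle, atol=1e-8)

    def test_constant_matrix_raises(self, bins8):
        n = bins8.n_bins
        iu, ju = np.triu_indices(n)
        cm = ContactMatrix.from_coo(bins8, iu, ju, np.full(len(iu), 5.0))
        with pytest.raises(ValueError, match="no usable bins"):
            infer_cscores(cm, np.random.default_rng(0).random(n), min_bins=4)

    def test_scale_invariance(self, bins8):
        cm = two_block_matrix(bins8, within=9, cross=2)
        ref = np.array([1.0] * 4 + [0.0] * 4)
        p1 = infer_cscores(cm, ref, min_bins=4)
        p2 = infer_cscores(cm.scaled(7.5), ref, min_bins=4)
        np.testing.assert_allclose(p1.cscore, p2.cscore, atol=1e-12)

    def test_scores_within_unit_interval(self, small_config):
        truth = simulate_compartment_truth(small_config)
        cm = simulate_contact_matrix(truth, small_config, 1)
        prof = infer_cscores(cm, truth.signs())
        ok = ~np.isnan(prof.cscore)
        assert (np.abs(prof.cscore[ok]) <= 1.0 + 1e-12).all()

    def test_zero_marginal_bins_masked(self, bins8):
        cm = two_block_matrix(bins8, within=10, cross=1)
        dense = cm.dense_chrom("chr1")
        dense[:, 2] = 0
        dense[2, :] = 0
        iu, ju = np.triu_indices(8)
        cm2 = ContactMatrix.from_coo(bins8, iu, ju, dense[iu, ju])
        prof = infer_cscores(cm2, np.array([1.0] * 4 + [0.0] * 4), min_bins=4)
        assert prof.label[2] == "NA" and np.isnan(prof.cscore[2])

    def test_planted_label_recovery(self):
        """>= 95% of non-masked bins get their planted label (kappa 0.6)."""
        cfg = SimulationConfig(
            chrom_sizes={"chr1": 10_000_000, "chr2": 10_000_000},
            compartment_strength=0.6, depth=200_000, seed=17,
        )
        truth = simulate_compartment_truth(cfg)
        cm = simulate_contact_matrix(truth, cfg, 1)
        prof = infer_cscores(cm, truth.signs())
        labeled = prof.labeled_mask()
        agreement = np.mean(prof.label[labeled] == truth.labels[labeled])
        assert agreement >= 0.95


class TestSegmentsAndBoundaries:
    def test_segment_arithmetic(self):
        bins = BinTable.from_chrom_sizes({"chr1": 125_000}, 25_000)
        prof = profile_from_labels(bins, ["A", "A", "B", "B", "B"])
        segments, ratio = segment_and_ratio(prof)
        assert [tuple(r) for r in segments.itertuples(index=False)] == [
            ("A", "chr1", 0, 50_000), ("B", "chr1", 50_000, 125_000)
        ]
        assert ratio == pytest.approx(50_000 / 75_000)

    def test_all_a_infinite_ratio_warns(self):
        bins = BinTable.from_chrom_sizes({"chr1": 75_000}, 25_000)
        prof = profile_from_labels(bins, ["A", "A", "A"])
        with pytest.warns(UserWarning, match="infinite"):
            segments, ratio = segment_and_ratio(prof)
        assert len(segments) == 1 and np.isinf(ratio)

    def test_recovered_ratio_tracks_planted_ratio(self):
        """A:B length ratio from inferred labels within 10% of the planted one."""
        cfg = SimulationConfig(
            chrom_sizes={"chr1": 10_000_000, "chr2": 10_000_000},
            a_fraction=0.44, depth=200_000, seed=23,
        )
        truth = simulate_compartment_truth(cfg)
        cm = simulate_contact_matrix(truth, cfg, 1)
        prof = infer_cscores(cm, truth.signs())
        _, ratio = segment_and_ratio(prof)
        p = np.mean(truth.labels == "A")
        planted_ratio = p / (1 - p)
        assert abs(ratio - planted_ratio) / planted_ratio < 0.10

    def test_boundary_definitions(self):
        bins = BinTable.from_chrom_sizes({"chr1": 100_000}, 25_000)
        prof = profile_from_labels(bins, ["B", "B", "A", "A"])
        assert find_boundaries(prof, "B->A") == [("chr1", 50_000)]
        assert find_boundaries(prof, "A->B") == []

        prof2 = profile_from_labels(
            BinTable.from_chrom_sizes({"chr1": 75_000}, 25_000), ["A", "B", "A"]
        )
        assert find_boundaries(prof2, "B->A") == [("chr1", 50_000)]
        assert find_boundaries(prof2, "A->B") == [("chr1", 25_000)]

    def test_na_runs_skipped_not_boundary(self):
        bins = BinTable.from_chrom_sizes({"chr1": 100_000}, 25_000)
        prof = profile_from_labels(bins, ["B", "NA", "NA", "A"])
        assert find_boundaries(prof, "B->A") == [("chr1", 75_000)]

    def test_boundary_recovery_on_strong_simulation(self):
        cfg = SimulationConfig(
            chrom_sizes={"chr1": 10_000_000},
            compartment_strength=0.9, depth=2_000_000, seed=31,
        )
        truth = simulate_compartment_truth(cfg)
        cm = simulate_contact_matrix(truth, cfg, 1)
        prof = infer_cscores(cm, truth.signs())
        assert find_boundaries(prof, "B->A") == truth.boundary_positions("B->A")


class TestCompareProfiles:
    def test_identity(self, bins8):
        cm = two_block_matrix(bins8, within=10, cross=1)
        prof = infer_cscores(cm, np.array([1.0] * 4 + [0.0] * 4), min_bins=4)
        res = compare_profiles(prof, prof)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.switched_bins == []

    def test_replicates_highly_correlated(self, small_config):
        truth = simulate_compartment_truth(small_config)
        ref = truth.signs()
        p1 = infer_cscores(simulate_contact_matrix(truth, small_config, 1), ref)
        p2 = infer_cscores(simulate_contact_matrix(truth, small_config, 2), ref)
        assert compare_profiles(p1, p2).pearson_r >= 0.9

    def test_different_truths_uncorrelated(self):
        rs = []
        for seed in range(8):
            c1 = SimulationConfig(chrom_sizes={"chr1": 5_000_000}, seed=100 + seed)
            c2 = SimulationConfig(chrom_sizes={"chr1": 5_000_000}, seed=200 + seed)
            t1 = simulate_compartment_truth(c1)
            t2 = simulate_compartment_truth(c2)
            p1 = infer_cscores(simulate_contact_matrix(t1, c1, 1), t1.signs())
            p2 = infer_cscores(simulate_contact_matrix(t2, c2, 1), t2.signs())
            rs.append(compare_profiles(p1, p2).pearson_r)
        assert abs(np.mean(rs)) < 0.25

    def test_mismatched_bins_rejected(self, bins8):
        prof = profile_from_labels(bins8, ["A"] * 4 + ["B"] * 4)
        other = profile_from_labels(
            BinTable.from_chrom_sizes({"chr1": 100_000}, 25_000), ["A", "B", "A", "B"]
        )
        with pytest.raises(ValueError, match="mismatched"):
            compare_profiles(prof, other)
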