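"""Statistical and determinism properties of the planted-truth generators."""

import numpy as np
import pandas as pd
import pytest

from chromarch import (
    SimulationConfig,
    select_partners,
    simulate_abundance_table,
    simulate_compartment_truth,
    simulate_contact_matrix,
    simulate_go_annotation,
    simulate_interactions,
    simulate_peaks,
)


class TestCompartmentTruth:
    def test_determinism(self, small_config):
        t1 = simulate_compartment_truth(small_config)
        t2 = simulate_compartment_truth(small_config)
        assert np.array_equal(t1.labels, t2.labels)
        assert t1.tad_intervals == t2.tad_intervals

    def test_a_fraction_converges(self):
        """Monte-Carlo over seeds: mean A fraction within 3 SE of target 0.5."""
        fracs = []
        for seed in range(3000):
            cfg = SimulationConfig(
                chrom_sizes={"chr1": 10_000_000}, a_fraction=0.5, seed=seed
            )
            truth = simulate_compartment_truth(cfg)
            fracs.append(np.mean(truth.labels == "A"))
        mean = np.mean(fracs)
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(mean - 0.5) < 3 * se + 1e-9

    def test_all_a_has_no_boundaries(self):
        cfg = SimulationConfig(chrom_sizes={"chr1": 2_000_000}, a_fraction=1.0)
        truth = simulate_compartment_truth(cfg)
        assert (truth.labels == "A").all()
        assert truth.boundary_bins("B->A") == []
        assert truth.boundary_bins("A->B") == []

    def test_boundaries_consistent_with_labels(self, small_config):
        truth = simulate_compartment_truth(small_config)
        for b in truth.boundary_bins("B->A"):
            assert truth.labels[b - 1] == "B" and truth.labels[b] == "A"

    def test_tads_partition_sorted_nonoverlapping(self, small_config):
        truth = simulate_compartment_truth(small_config)
        spans = truth.tad_intervals
        assert spans == sorted(spans)
        for (a1, b1), (a2, _) in zip(spans[:-1], spans[1:]):
            assert b1 <= a2


class TestContactMatrix:
    def test_symmetry_and_nonnegative(self, small_config):
        truth = simulate_compartment_truth(small_config)
        cm = simulate_contact_matrix(truth, small_config, 1)
        dense = cm.dense_chrom("chr1")
        assert np.array_equal(dense, dense.T)
        assert (cm.mat.data >= 0).all()
        assert np.allclose(cm.mat.data, np.round(cm.mat.data))

    def test_decay_exponent_recovered(self):
        """log-log regression on distance-stratified means recovers -alpha."""
        cfg = SimulationConfig(
            chrom_sizes={"chr1": 10_000_000},
            compartment_strength=0.0, tad_boost=1.0,
            decay_exponent=1.0, depth=2_000_000, seed=11,
        )
        truth = simulate_compartment_truth(cfg)
        dense = simulate_contact_matrix(truth, cfg, 1).dense_chrom("chr1")
        dists = np.arange(1, 101)
        means = np.array([np.mean(np.diagonal(dense, d)) for d in dists])
        slope = np.polyfit(np.log(dists + 1.0), np.log(means), 1)[0]
        assert abs(slope - (-1.0)) < 0.1

    def test_checkerboard_contrast(self):
        cfg = SimulationConfig(
            chrom_sizes={"chr1": 10_000_000},
            compartment_strength=0.6, tad_boost=1.0, depth=2_000_000, seed=3,
        )
        truth = simulate_compartment_truth(cfg)
        dense = simulate_contact_matrix(truth, cfg, 1).dense_chrom("chr1")
        signs = truth.signs()
        same_tot, cross_tot = [], []
        for d in range(5, 60):
            diag = np.diagonal(dense, d)
            pair = signs[:-d] * signs[d:]
            same_tot.extend(diag[pair > 0])
            cross_tot.extend(diag[pair < 0])
        assert np.mean(same_tot) > np.mean(cross_tot)

    def test_replicates_differ_but_same_truth(self, small_config):
        truth = simulate_compartment_truth(small_config)
        m1 = simulate_contact_matrix(truth, small_config, 1)
        m2 = simulate_contact_matrix(truth, small_config, 2)
        assert not m1.equals(m2)
        assert m1.equals(simulate_contact_matrix(truth, small_config, 1))


class TestPeaks:
    def test_all_a_placement_at_infinite_odds(self, small_config):
        cfg = SimulationConfig(
            chrom_sizes={"chr1": 5_000_000}, peak_a_enrichment=float("inf"), seed=7
        )
        truth = simulate_compartment_truth(cfg)
        peaks, _ = simulate_peaks(truth, cfg)
        mids = (peaks["start"] + peaks["end"]) // 2
        idx = truth.bins.bin_index("chr1", mids.to_numpy())
        assert (truth.labels[idx] == "A").all()

    def test_a_fraction_of_peaks_binomial(self):
        """Balanced genome at odds e=4: P(A) = 4/5 within 3 binomial SE."""
        cfg = SimulationConfig(
            chrom_sizes={"chr1": 10_000_000}, a_fraction=0.5,
            peak_a_enrichment=4.0, peak_count=10_000, seed=21,
        )
        truth = simulate_compartment_truth(cfg)
        peaks, _ = simulate_peaks(truth, cfg)
        mids = (peaks["start"] + peaks["end"]) // 2
        idx = truth.bins.bin_index("chr1", mids.to_numpy())
        p_a = np.mean(truth.labels == "A")
        expected = 4 * p_a / (4 * p_a + (1 - p_a))
        observed = np.mean(truth.labels[idx] == "A")
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(observed - expected) < 3 * se

    def test_zero_peaks_flat_track(self):
        cfg = SimulationConfig(
            chrom_sizes={"chr1": 2_000_000}, peak_count=0, signal_noise=0.0
        )
        truth = simulate_compartment_truth(cfg)
        peaks, track = simulate_peaks(truth, cfg)
        assert len(peaks) == 0
        assert (track["value"] == 0).all()


class TestInteractions:
    def test_calls_within_max_dist(self, small_config):
        truth = simulate_compartment_truth(small_config)
        frags, calls, _ = simulate_interactions(truth, small_config)
        mids = ((frags["start"] + frags["end"]) // 2).to_numpy()
        pos = {f: m for f, m in zip(frags["fragment_id"], mids)}
        d = np.array([abs(pos[b] - pos[o]) for b, o in
                      zip(calls["bait_id"], calls["otherend_id"])])
        assert (d <= small_config.max_call_dist).all()

    def test_scores_at_least_five(self, small_config):
        truth = simulate_compartment_truth(small_config)
        _, calls, _ = simulate_interactions(truth, small_config)
        assert (calls["score"] >= 5.0).all()

    def test_fragments_tile_chromosome(self, small_config):
        truth = simulate_compartment_truth(small_config)
        frags, _, _ = simulate_interactions(truth, small_config)
        assert frags["start"].iloc[0] == 0
        assert (frags["start"].to_numpy()[1:] == frags["end"].to_numpy()[:-1]).all()
        assert frags["end"].iloc[-1] == 5_000_000


class TestAbundance:
    def test_clean_table_recovered_exactly(self):
        cfg = SimulationConfig(dropout_rate=0.0, partner_leak=0.0, seed=5)
        table, planted = simulate_abundance_table(cfg, "ES_N1")
        calls = select_partners(table, threshold=10.0)
        recovered = set(calls.loc[calls["is_partner"], "protein_id"])
        assert recovered == planted

    def test_partner_count_arithmetic(self):
        cfg = SimulationConfig(n_proteins=1000, partner_fraction=0.05)
        _, planted = simulate_abundance_table(cfg, "MEF_N1")
        assert len(planted) == 50

    def test_nonpartner_ratio_tail_below_one_percent(self):
        cfg = SimulationConfig(n_proteins=5000, dropout_rate=0.0, seed=13)
        table, planted = simulate_abundance_table(cfg, "ES_N2")
        nonp = table[~table["protein_id"].isin(planted)]
        ratio = (nonp["wt1"] + nonp["wt2"]) / (nonp["dko1"] + nonp["dko2"])
        assert np.mean(ratio >= 10) < 0.01

    def test_no_partner_warning(self):
        cfg = SimulationConfig(n_proteins=10, partner_fraction=0.0)
        with pytest.warns(UserWarning, match="no partners planted"):
            simulate_abundance_table(cfg, "ES_N1")

    def test_partner_set_shared_across_groups(self):
        cfg = SimulationConfig(seed=9)
        _, p1 = simulate_abundance_table(cfg, "ES_N1")
        _, p2 = simulate_abundance_table(cfg, "MEF_N2")
        assert p1 == p2


class TestGoAnnotation:
    def test_determinism(self, small_config):
        universe = {f"P{k}" for k in range(200)}
        partners = {f"P{k}" for k in range(20)}
        a1, e1 = simulate_go_annotation(small_config, partners, universe)
        a2, e2 = simulate_go_annotation(small_config, partners, universe)
        assert a1 == a2 and e1 == e2

    def test_partners_must_be_subset(self, small_config):
        with pytest.raises(ValueError, match="subset"):
            simulate_go_annotation(small_config, {"X"}, {"A", "B"})

    def test_planted_terms_biased_to_partners(self, small_config):
        universe = {f"P{k}" for k in range(500)}
        partners = {f"P{k}" for k in range(25)}
        ann, planted = simulate_go_annotation(small_config, partners, universe)
        for term in planted:
            members = ann[term][1]
            frac = len(members & partners) / len(members)
            assert frac > len(partners) / len(universe) * 4
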