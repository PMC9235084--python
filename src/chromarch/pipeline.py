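"""End-to-end orchestration: simulate -> analyse -> report.

Runs every stage in dependency order from a single config, writing each
output through the io layer together with a provenance sidecar (stage
name, parameters, seed, SHA-256 digests of inputs and outputs). A rerun
with an identical config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .compartments import compare_profiles, find_boundaries, infer_cscores, segment_and_ratio
from .occupancy import boundary_metaplot, peak_compartment_fraction
from .partners import DEFAULT_GROUPS, consensus_categories, ora, select_partners, threshold_sweep
from .pir import feature_enrichment, filter_significant
from .similarity import scc
from .simulate import (
    SimulationConfig,
    simulate_abundance_table,
    simulate_compartment_truth,
    simulate_contact_matrix,
    simulate_go_annotation,
    simulate_interactions,
    simulate_peaks,
)
from .tads import call_tads, compare_tads, insulation_profile

__all__ = ["PipelineConfig", "run_pipeline", "simulate_dataset"]


@dataclass
class PipelineConfig:
    outdir: str = "chromarch_run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    metaplot_window: int = 200_000
    scc_h: int = 1
    scc_max_dist: int = 5_000_000
    tad_window: int = 500_000
    tad_min_drop: float = 0.1
    tad_min_size: int = 75_000
    tad_max_size: int = 5_000_000
    score_threshold: float = 5.0
    pir_max_dist: int = 1_000_000
    pir_n_rand: int = 100
    pir_n_dist_bins: int = 20
    ratio_thresholds: tuple = (10.0, 50.0, 500.0)
    alpha: float = 0.05
    switch_threshold: float = 0.2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _provenance(outdir: Path, stage: str, params: dict,
                inputs: list[Path], outputs: list[Path]) -> None:
    rec = {
        "stage": stage,
        "parameters": params,
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / f"{stage}.provenance.json").write_text(json.dumps(rec, indent=2, default=str))


def simulate_dataset(cfg: SimulationConfig, outdir: Path) -> dict[str, Path]:
    """Emit a complete simulated dataset directory plus ground-truth sidecar."""
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_compartment_truth(cfg)
    paths: dict[str, Path] = {}

    wt1 = simulate_contact_matrix(truth, cfg, replicate_seed=1)
    wt2 = simulate_contact_matrix(truth, cfg, replicate_seed=2)
    dko = simulate_contact_matrix(truth, cfg, replicate_seed=3)
    for name, cm in [("wt_rep1", wt1), ("wt_rep2", wt2), ("dko_rep1", dko)]:
        mpath, bpath = outdir / f"{name}.matrix.tsv", outdir / f"{name}.bins.bed"
        cio.write_matrix(cm, mpath, bpath)
        paths[f"{name}_matrix"] = mpath
        paths[f"{name}_bins"] = bpath

    peaks, track = simulate_peaks(truth, cfg)
    cio.write_bed(peaks, outdir / "peaks.bed")
    cio.write_bedgraph(track, outdir / "signal.bedgraph")
    paths["peaks"] = outdir / "peaks.bed"
    paths["signal"] = outdir / "signal.bedgraph"

    frags, calls, feature = simulate_interactions(truth, cfg)
    cio.write_fragments(frags, outdir / "fragments.tsv")
    cio.write_interactions(calls, outdir / "interactions.tsv")
    cio.write_bed(feature, outdir / "feature.bed")
    paths.update(fragments=outdir / "fragments.tsv",
                 interactions=outdir / "interactions.tsv",
                 feature=outdir / "feature.bed")

    tables = []
    partner_ids: set[str] = set()
    for group in DEFAULT_GROUPS:
        tab, pids = simulate_abundance_table(cfg, group)
        tables.append(tab)
        partner_ids = pids
    abundance = pd.concat(tables, ignore_index=True)
    cio.write_abundance(abundance, outdir / "abundance.tsv")
    paths["abundance"] = outdir / "abundance.tsv"

    universe = set(abundance["protein_id"].unique())
    annotation, enriched = simulate_go_annotation(cfg, partner_ids, universe)
    cio.write_gmt(annotation, outdir / "annotation.gmt")
    paths["annotation"] = outdir / "annotation.gmt"

    truth_df = truth.bins.df.copy()
    truth_df["label"] = truth.labels
    truth_df.to_csv(outdir / "truth.compartments.tsv", sep="\t", index=False)
    pd.DataFrame(truth.tad_intervals, columns=["start_bin", "end_bin"]).to_csv(
        outdir / "truth.tads.tsv", sep="\t", index=False
    )
    pd.DataFrame({"partner_id": sorted(partner_ids)}).to_csv(
        outdir / "truth.partners.tsv", sep="\t", index=False
    )
    pd.DataFrame({"term_id": sorted(enriched)}).to_csv(
        outdir / "truth.enriched_terms.tsv", sep="\t", index=False
    )
    paths["truth_compartments"] = outdir / "truth.compartments.tsv"
    return paths


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage on a simulated dataset; returns the report dir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.sim_config()
    report: dict = {"seed": config.seed}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            (outdir / "FAILED").write_text(f"{name}: {exc}\n")
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    data_dir = outdir / "data"
    paths = stage("simulate", lambda: simulate_dataset(cfg, data_dir))
    _provenance(outdir, "simulate", {"seed": config.seed, **asdict(cfg)},
                [], sorted(data_dir.iterdir()))

    def stage_compartments():
        wt = cio.read_matrix(paths["wt_rep1_matrix"], paths["wt_rep1_bins"])
        dko = cio.read_matrix(paths["dko_rep1_matrix"], paths["dko_rep1_bins"])
        track = cio.read_bedgraph(paths["signal"])
        ref = cio.track_bin_values(track, wt.bins)
        prof_wt = infer_cscores(wt, ref)
        prof_dko = infer_cscores(dko, ref)
        out = prof_wt.to_frame()
        out.to_csv(outdir / "cscores_wt.tsv", sep="\t", index=False)
        segments, ratio = segment_and_ratio(prof_wt)
        cio.write_bed(segments.rename(columns={"compartment": "score"})
                      [["chrom", "start", "end"]], outdir / "segments_wt.bed")
        cmp_res = compare_profiles(prof_wt, prof_dko, config.switch_threshold)
        report["compartments"] = {
            "ab_ratio_wt": ratio,
            "wt_vs_dko_pearson_r": cmp_res.pearson_r,
            "n_switched_bins": len(cmp_res.switched_bins),
        }
        return prof_wt

    prof_wt = stage("compartments", stage_compartments)
    _provenance(outdir, "compartments",
                {"switch_threshold": config.switch_threshold},
                [paths["wt_rep1_matrix"], paths["dko_rep1_matrix"], paths["signal"]],
                [outdir / "cscores_wt.tsv", outdir / "segments_wt.bed"])

    def stage_occupancy():
        peaks = cio.read_bed(paths["peaks"])
        track = cio.read_bedgraph(paths["signal"])
        occ = peak_compartment_fraction(peaks, prof_wt)
        bounds = find_boundaries(prof_wt, "B->A")
        meta = boundary_metaplot(track, bounds, window=config.metaplot_window,
                                 step=cfg.bin_size)
        meta.to_frame().to_csv(outdir / "metaplot.tsv", sep="\t", index=False)
        report["occupancy"] = {
            "n_peaks": occ.n_peaks, "n_in_A": occ.n_in_A,
            "fraction_A": occ.fraction_A, "n_excluded_na": occ.n_excluded_na,
            "n_b_to_a_boundaries": len(bounds),
        }

    stage("occupancy", stage_occupancy)
    _provenance(outdir, "occupancy", {"window": config.metaplot_window},
                [paths["peaks"], paths["signal"]], [outdir / "metaplot.tsv"])

    def stage_scc():
        wt1 = cio.read_matrix(paths["wt_rep1_matrix"], paths["wt_rep1_bins"])
        wt2 = cio.read_matrix(paths["wt_rep2_matrix"], paths["wt_rep2_bins"])
        dko = cio.read_matrix(paths["dko_rep1_matrix"], paths["dko_rep1_bins"])
        r_rep = scc(wt1, wt2, h=config.scc_h, max_dist=config.scc_max_dist)
        r_cross = scc(wt1, dko, h=config.scc_h, max_dist=config.scc_max_dist)
        r_rep.per_stratum.to_csv(outdir / "scc_strata.tsv", sep="\t", index=False)
        report["scc"] = {"wt_rep1_vs_rep2": r_rep.scc, "wt_vs_dko": r_cross.scc}
        return wt1, dko

    wt1, dko = stage("scc", stage_scc)
    _provenance(outdir, "scc", {"h": config.scc_h, "max_dist": config.scc_max_dist},
                [paths["wt_rep1_matrix"], paths["wt_rep2_matrix"]],
                [outdir / "scc_strata.tsv"])

    def stage_tads():
        t_wt = call_tads(wt1.bins, insulation_profile(wt1, config.tad_window),
                         config.tad_min_drop, config.tad_min_size, config.tad_max_size)
        t_dko = call_tads(dko.bins, insulation_profile(dko, config.tad_window),
                          config.tad_min_drop, config.tad_min_size, config.tad_max_size)
        comp = compare_tads(t_wt, t_dko)
        starts = wt1.bins.df["start"].to_numpy()
        chroms = wt1.bins.df["chrom"].to_numpy()
        pd.DataFrame({
            "chrom": chroms[t_wt.boundaries],
            "start": starts[t_wt.boundaries],
            "end": starts[t_wt.boundaries] + cfg.bin_size,
        }).to_csv(outdir / "tad_boundaries_wt.bed", sep="\t", header=False, index=False)
        report["tads"] = {
            "n_tads_wt": comp.n_tads_a, "n_tads_dko": comp.n_tads_b,
            "boundary_jaccard": comp.boundary_jaccard,
        }

    stage("tads", stage_tads)
    _provenance(outdir, "tads",
                {"window": config.tad_window, "min_drop": config.tad_min_drop},
                [paths["wt_rep1_matrix"], paths["dko_rep1_matrix"]],
                [outdir / "tad_boundaries_wt.bed"])

    def stage_pir():
        frags = cio.read_fragments(paths["fragments"])
        calls = cio.read_interactions(paths["interactions"], frags)
        feature = cio.read_bed(paths["feature"])
        sig = filter_significant(calls, config.score_threshold)
        enr = feature_enrichment(
            sig, frags, feature, feature_name="planted_feature",
            max_dist=config.pir_max_dist, n_rand=config.pir_n_rand,
            n_dist_bins=config.pir_n_dist_bins, seed=config.seed,
        )
        pd.DataFrame([enr.__dict__]).to_csv(outdir / "pir_enrichment.tsv",
                                            sep="\t", index=False)
        report["pir"] = {
            "n_significant_calls": len(sig), "observed": enr.observed,
            "expected_mean": enr.expected_mean, "fold": enr.fold,
            "p_value": enr.p_value,
        }

    stage("pir_enrichment", stage_pir)
    _provenance(outdir, "pir_enrichment",
                {"score_threshold": config.score_threshold, "n_rand": config.pir_n_rand},
                [paths["interactions"], paths["fragments"], paths["feature"]],
                [outdir / "pir_enrichment.tsv"])

    def stage_partners():
        records = cio.read_abundance(paths["abundance"])
        sweep = threshold_sweep(records, tuple(config.ratio_thresholds))
        sweep.to_csv(outdir / "partner_sweep.tsv", sep="\t", index=False)
        calls = select_partners(records, threshold=float(config.ratio_thresholds[0]))
        calls[calls["is_partner"]].to_csv(outdir / "partners.tsv", sep="\t", index=False)
        report["partners"] = {
            "sweep": {
                f"{row.threshold:g}": int(row.n_protein_group_pairs)
                for row in sweep.itertuples()
            },
        }
        return records, calls

    records, partner_calls = stage("partners", stage_partners)
    _provenance(outdir, "partners", {"thresholds": list(config.ratio_thresholds)},
                [paths["abundance"]],
                [outdir / "partner_sweep.tsv", outdir / "partners.tsv"])

    def stage_ora():
        annotation = cio.read_gmt(paths["annotation"])
        universe = set(records["protein_id"].unique())
        results = {}
        pooled: set[str] = set()
        for group in DEFAULT_GROUPS:
            sample = set(
                partner_calls.loc[
                    (partner_calls["group"] == group) & partner_calls["is_partner"],
                    "protein_id",
                ]
            )
            pooled |= sample
            res = ora(sample, universe, annotation, alpha=config.alpha)
            res.to_csv(outdir / f"ora_{group}.tsv", sep="\t", index=False)
            results[group] = res
        pooled_res = ora(pooled, universe, annotation, alpha=config.alpha)
        cons = consensus_categories(results, alpha=config.alpha,
                                    pooled_results=pooled_res)
        cons.ranking.to_csv(outdir / "consensus_top.tsv", sep="\t", index=False)
        report["ora"] = {
            "n_consensus_terms": len(cons.consensus_terms),
            "n_common_terms": len(cons.common_terms),
            "unique_counts": cons.unique_counts,
        }

    stage("ora_consensus", stage_ora)
    _provenance(outdir, "ora_consensus", {"alpha": config.alpha},
                [paths["annotation"], paths["abundance"]],
                [outdir / "consensus_top.tsv"])

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return outdir
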