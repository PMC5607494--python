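"""End-to-end orchestration: simulate -> call HMDs -> summits -> anchors ->
metaprofiles -> spacing -> SVMs -> correlations -> periodicity -> report.

The pipeline is deterministic under a fixed seed; the report is a plain
JSON-serializable dict whose every number comes from a stage output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .accessibility import call_summits, coverage, overlap_stats, shift_cuts
from .hmd import HMD, call_hmds, genome_fraction
from .metaprofile import (
    metaprofile,
    position_count_track,
    select_anchors,
)
from .periodicity import pairwise_distance_histogram, scan_occurrences, top_kmers
from .simulate import SyntheticConfig, SyntheticDataset, generate
from .spacing import boundary_linker_gap, estimate_spacing
from .svm import (
    build_hmd_vs_methylated_sets,
    build_linker_core_sets,
    compare_weights,
    correlate,
    correlation_histogram,
    evaluate,
    score_hmd,
    train,
)

log = logging.getLogger("hmdnuc")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    # hmd calling
    min_cpgs: int = 10
    ratio_threshold: float = 0.4
    # accessibility
    cut_shift: int = 50
    smooth_bw: int = 73
    min_height: float = 2.0
    min_separation: int = 150
    fold_enrichment: float = 5.0
    # metaprofiles / spacing
    flank: int = 1000
    max_tss_dist: int = 1000
    # svm
    k: int = 6
    C: float = 1.0
    seq_len: int = 100
    min_summit_gap: int = 150
    neg_copies: int = 10
    hypo_max_len: int = 3000
    # periodicity
    top_n: int = 10
    min_dist: int = 3
    max_dist: int = 1000
    binwidth: int = 10
    # correlations
    alpha: float = 0.05
    max_correlated_hmds: int = 100

    def resolved_synthetic(self) -> SyntheticConfig:
        if self.synthetic is not None:
            return self.synthetic
        return SyntheticConfig(seed=self.seed)


@dataclass
class PipelineResult:
    """Intermediate objects of a pipeline run, for inspection and tests."""

    dataset: SyntheticDataset
    hmds: list[HMD]
    summits: list
    anchors: list
    anchors_5p: list
    dnase_track: object
    dyad_profile: object
    dnase_profile: object
    spacing_hmd: object
    spacing_meth: object
    gap_5p: int
    model_dnase: object
    model_hypo: object
    eval_dnase: dict
    eval_hypo: dict
    weight_comparison: dict
    correlations: dict
    periodicity: object
    report: dict


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    t0 = time.time()
    sim_config = config.resolved_synthetic()

    def stage(name: str) -> None:
        log.info("stage %-14s t=%.1fs", name, time.time() - t0)

    stage("simulate")
    dataset = generate(sim_config)
    chrom_lengths = dataset.genome.lengths()

    stage("call-hmds")
    hmds = call_hmds(
        dataset.methylation,
        min_cpgs=config.min_cpgs,
        ratio_threshold=config.ratio_threshold,
    )
    log.info("called %d HMDs", len(hmds))

    stage("summits")
    shifted = shift_cuts(dataset.dnase_cuts, config.cut_shift, chrom_lengths)
    dnase_track = coverage(shifted, chrom_lengths, config.smooth_bw)
    summits = call_summits(
        dnase_track,
        min_height=config.min_height,
        min_separation=config.min_separation,
        fold_enrichment=config.fold_enrichment,
    )
    log.info("called %d summits", len(summits))

    stage("anchors")
    anchors = select_anchors(hmds, summits, dataset.tss, config.max_tss_dist)
    anchors_5p = [a for a in anchors if a.side == "5p"]

    stage("profiles")
    dyad_track = position_count_track(dataset.mnase_midpoints, chrom_lengths)
    dyad_profile = metaprofile(
        dyad_track, anchors_5p, config.flank, orient=True, track_name="dyads"
    )
    dnase_profile = metaprofile(
        dnase_track, anchors_5p, config.flank, orient=True, track_name="dnase"
    )

    stage("spacing")
    spacing_hmd = estimate_spacing(dyad_profile, side="hmd")
    spacing_meth = estimate_spacing(dyad_profile, side="methylated")
    gap_5p = boundary_linker_gap(dnase_profile)

    stage("overlap")
    ostats = overlap_stats(summits, hmds, dataset.genome.total_length())

    stage("svm-dnase")
    holdout = sim_config.holdout_chrom
    linker_sets = build_linker_core_sets(
        hmds,
        summits,
        dataset.genome,
        seq_len=config.seq_len,
        min_summit_gap=config.min_summit_gap,
        holdout_chrom=holdout,
    )
    model_dnase = train(linker_sets, k=config.k, C=config.C)
    eval_dnase = evaluate(model_dnase, linker_sets)

    stage("svm-hypo")
    hypo_sets = build_hmd_vs_methylated_sets(
        hmds,
        dataset.genome,
        max_len=config.hypo_max_len,
        neg_copies=config.neg_copies,
        seed=config.seed,
        holdout_chrom=holdout,
    )
    model_hypo = train(hypo_sets, k=config.k, C=config.C)
    eval_hypo = evaluate(model_hypo, hypo_sets)
    weight_comparison = compare_weights(model_hypo, model_dnase, top_n=20)

    stage("correlate")
    holdout_hmds = [
        h for h in hmds if h.chrom == holdout and len(h.interval) >= config.seq_len
    ][: config.max_correlated_hmds]
    scoreds = []
    for i, h in enumerate(holdout_hmds):
        s = score_hmd(h, dataset.genome, model_dnase, hmd_id=i)
        scoreds.append(correlate(s, dnase_track))
    corr = correlation_histogram(scoreds, alpha=config.alpha)

    stage("periodicity")
    kmers = top_kmers(model_dnase, config.top_n)
    occ = scan_occurrences(hmds, dataset.genome, kmers)
    hist = pairwise_distance_histogram(
        occ,
        min_dist=config.min_dist,
        max_dist=config.max_dist,
        binwidth=config.binwidth,
    )

    stage("report")
    report = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "holdout_chrom": holdout,
        },
        "counts": {
            "n_hmds": len(hmds),
            "n_summits": len(summits),
            "n_anchors_5p": len(anchors_5p),
            "n_anchors_3p": len(anchors) - len(anchors_5p),
        },
        "overlap_stats": ostats,
        "spacing": {
            "hmd": {
                "spacing_bp": spacing_hmd.spacing,
                "peak_acf": spacing_hmd.peak_acf,
                "confident": spacing_hmd.confident,
            },
            "methylated": {
                "spacing_bp": spacing_meth.spacing,
                "peak_acf": spacing_meth.peak_acf,
                "confident": spacing_meth.confident,
            },
        },
        "boundary_linker_gap_bp": gap_5p,
        "svm_dnase": {
            "auc": eval_dnase["auc"],
            "n_test_pos": eval_dnase["n_test_pos"],
            "n_test_neg": eval_dnase["n_test_neg"],
            "top_kmers": [
                {"kmer": kmer, "weight": model_dnase.weight_of(kmer)}
                for kmer in kmers
            ],
        },
        "svm_hypo": {
            "auc": eval_hypo["auc"],
            "n_test_pos": eval_hypo["n_test_pos"],
            "n_test_neg": eval_hypo["n_test_neg"],
        },
        "weight_comparison": {
            "rank_test_p": weight_comparison["rank_test_p"],
            "top_kmers": weight_comparison["top_kmers"],
        },
        "correlations": {
            "n_significant": corr["n_significant"],
            "n_significant_positive": corr["n_significant_positive"],
            "n_total": corr["n_total"],
        },
        "periodicity": {
            "mode_bin_center_bp": hist.mode_bin_center,
            "n_pairs": hist.total,
        },
    }
    stage("done")
    return PipelineResult(
        dataset=dataset,
        hmds=hmds,
        summits=summits,
        anchors=anchors,
        anchors_5p=anchors_5p,
        dnase_track=dnase_track,
        dyad_profile=dyad_profile,
        dnase_profile=dnase_profile,
        spacing_hmd=spacing_hmd,
        spacing_meth=spacing_meth,
        gap_5p=gap_5p,
        model_dnase=model_dnase,
        model_hypo=model_hypo,
        eval_dnase=eval_dnase,
        eval_hypo=eval_hypo,
        weight_comparison=weight_comparison,
        correlations=corr,
        periodicity=hist,
        report=report,
    )


def write_report(report: dict, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    md = outdir / "report.md"
    lines = ["# hmdnuc pipeline report", ""]
    sp = report["spacing"]
    lines += [
        f"- HMDs called: {report['counts']['n_hmds']}",
        f"- summits called: {report['counts']['n_summits']}",
        f"- spacing (HMD side): {sp['hmd']['spacing_bp']} bp",
        f"- spacing (methylated side): {sp['methylated']['spacing_bp']} bp",
        f"- 5' boundary linker gap: {report['boundary_linker_gap_bp']} bp",
        f"- SVM_DNaseI holdout AUC: {report['svm_dnase']['auc']:.3f}",
        f"- SVM_hypo holdout AUC: {report['svm_hypo']['auc']:.3f}",
        f"- periodicity mode: {report['periodicity']['mode_bin_center_bp']} bp",
    ]
    md.write_text("\n".join(lines) + "\n")
    return path
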