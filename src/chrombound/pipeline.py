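"""End-to-end orchestration: synthetic generation through summary report.

``run_all`` executes the stages in dependency order on a synthetic dataset
(or user-supplied files), applying the standard thresholds — peak fold/p
filters, >3-fold / 2 kb merge / >2 kb length domain rule, 1 kb boundary and
TSS rules, CPM detection and filtering, >2-fold change, randomization with a
fixed seed — and writes a versioned JSON summary plus TSV tables. Re-running
with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boundary_analysis import (
    boundary_colocalization,
    extract_boundaries,
    mark_boundaries,
    shared_boundary_sites,
)
from .colocalization_null import colocalization_test
from .core_intervals import GenomeAssembly, IntervalSet, read_bed, read_chrom_sizes
from .expression_integration import (
    compare_expression_by_class,
    detect_transcripts,
    domain_expression_association,
    filter_transcripts,
    link_peaks_to_genes,
)
from .genome_bins import BinScheme, build_bins, peak_bin_distribution
from .peak_occupancy import classify_cooccupancy, classify_cross_cell, percent_common
from .repressive_domains import call_domains, domain_stats
from .synthetic_data import (
    make_expression,
    make_genes,
    make_genome,
    make_h3k27me3_track,
    make_peak_panel,
)

logger = logging.getLogger("chrombound")

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Thresholds and sizes for an end-to-end run.

    With no input paths the run operates on a synthetic dataset generated from
    ``seed``; every stochastic stage derives its stream from that one seed.
    """

    seed: int = 0
    out_dir: str = "chrombound_out"
    # synthetic sizes
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    gap_fraction: float = 0.05
    n_peaks: int = 800
    n_genes: int = 300
    k_references: int = 7
    # thresholds (the study's printed constants)
    min_fold: float = 8.0
    max_p: float = 1e-5
    min_bp: int = 1
    domain_min_fold: float = 3.0
    domain_merge_gap: int = 2_000
    domain_min_length: int = 2_000
    boundary_d: int = 1_000
    tss_d: int = 1_000
    cpm_threshold: float = 1.0
    min_samples: int = 3
    min_fold_change: float = 2.0
    n_iterations: int = 200
    run_null: bool = True

    def validate(self) -> None:
        numeric = [
            self.min_fold, self.min_bp, self.domain_min_fold, self.domain_merge_gap,
            self.domain_min_length, self.boundary_d, self.tss_d, self.cpm_threshold,
            self.min_samples, self.min_fold_change, self.n_iterations,
        ]
        if any(v < 0 for v in numeric):
            raise ValueError("all thresholds must be >= 0")
        if self.run_null and self.seed is None:
            raise ValueError("a seed is required when randomization is enabled")


def run_all(config: RunConfig) -> dict:
    """Run every stage on a synthetic dataset; write JSON + TSV summaries.

    Returns the summary dict (also written to ``<out_dir>/summary.json``).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("run_all: seed=%d out=%s", config.seed, out_dir)

    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "config": asdict(config),
    }

    # --- synthetic inputs -------------------------------------------------
    assembly = make_genome(
        config.n_chrom, config.chrom_length, config.gap_fraction, seed=config.seed
    )
    genes = make_genes(assembly, config.n_genes, seed=config.seed + 1)
    panel = make_peak_panel(
        assembly,
        n_peaks=config.n_peaks,
        k_references=config.k_references,
        seed=config.seed + 2,
        genes=genes,
    )
    track, planted_domains = make_h3k27me3_track(
        assembly, seed=config.seed + 3, domain_genome_fraction=0.04
    )
    table, _expr_truth = make_expression(
        genes,
        seed=config.seed + 4,
        gene_classes=panel.gene_classes,
        domains=planted_domains,
        group_b_de_fraction=0.2,
    )

    # --- co-occupancy -----------------------------------------------------
    co = classify_cooccupancy(panel.target, panel.partner, min_bp=config.min_bp)
    summary["cooccupancy"] = {
        "n_both": co.n_both,
        "n_a_only": co.n_a_only,
        "n_b_only": co.n_b_only,
        "pct_a_cooccupied": percent_common(co.n_both, co.n_a)[0],
    }

    # --- cross-cell sharing -----------------------------------------------
    cc = classify_cross_cell(panel.target, panel.references, min_bp=config.min_bp)
    fr = cc.fractions()
    summary["cross_cell"] = {
        "k": cc.k,
        "n_specific": cc.n_specific,
        "n_invariant": cc.n_invariant,
        "n_intermediate": cc.n_intermediate,
        "pct_specific": 100.0 * fr["specific"],
        "pct_invariant": 100.0 * fr["invariant"],
    }
    labels_bed = panel.target.df.copy()
    labels_bed["name"] = cc.labels
    labels_bed[["chrom", "start", "end", "name"]].to_csv(
        out_dir / "crosscell_labels.bed", sep="\t", header=False, index=False
    )

    # --- genome bins --------------------------------------------------------
    bins = build_bins(genes, assembly, BinScheme())
    dist = peak_bin_distribution(panel.target, bins)
    dist.to_csv(out_dir / "bin_distribution.tsv", sep="\t")
    summary["genome_bins"] = {
        name: {
            "peak_fraction": float(dist.loc[name, "peak_fraction"]),
            "genome_fraction": float(dist.loc[name, "genome_fraction"]),
        }
        for name in dist.index
    }

    # --- repressive domains -------------------------------------------------
    domains = call_domains(
        track.windows,
        min_fold=config.domain_min_fold,
        merge_gap=config.domain_merge_gap,
        min_length=config.domain_min_length,
    )
    stats = domain_stats(domains, assembly)
    summary["domains"] = {
        "n_domains": stats.n_domains,
        "n_planted": len(planted_domains),
        "mean_length": stats.mean_length,
        "genome_pct": stats.genome_pct,
    }
    pd.DataFrame(
        [(d.interval.chrom, d.interval.start, d.interval.end, d.source_window_count)
         for d in domains],
        columns=["chrom", "start", "end", "n_windows"],
    ).to_csv(out_dir / "domains.bed", sep="\t", header=False, index=False)

    # --- boundaries ---------------------------------------------------------
    boundaries = extract_boundaries(domains)
    marking = mark_boundaries(track.boundary_peaks, boundaries, d=config.boundary_d)
    coloc = boundary_colocalization(marking.marking_peaks, panel.partner, min_bp=config.min_bp)
    shared = shared_boundary_sites(marking.marking_peaks, panel.target, min_bp=config.min_bp)
    summary["boundaries"] = {
        "n_boundaries": len(boundaries),
        "n_marking_peaks": marking.n_marking_peaks,
        "n_marked_boundaries": marking.n_marked_boundaries,
        "colocalization": coloc,
        "n_shared_with_target": shared,
    }

    # --- randomization null ---------------------------------------------------
    if config.run_null:
        result = colocalization_test(
            marking.marking_peaks,
            panel.target,
            assembly,
            statistic="n_a_overlapping_b",
            n_iterations=config.n_iterations,
            seed=config.seed + 5,
        )
        summary["colocalization_null"] = {
            "observed": float(result.observed),
            "p_empirical": result.p_empirical,
            "direction": result.direction,
            "n_iterations": result.n_iterations,
            "null_quantiles": {str(k): v for k, v in result.null.quantiles().items()},
        }

    # --- expression -----------------------------------------------------------
    samples = list(table.samples)
    group_a = [s for s in samples if s.startswith("hspc")]
    group_b = [s for s in samples if s.startswith("ery")]
    detected = detect_transcripts(table, config.cpm_threshold)
    filtered = filter_transcripts(table, config.cpm_threshold, config.min_samples)
    linked = link_peaks_to_genes(
        panel.target, genes, d=config.tss_d, peak_classes=cc.labels
    )
    linked.to_csv(out_dir / "gene_links.tsv", sep="\t")
    cls = linked["gene_class"]
    comparison = compare_expression_by_class(
        cls[cls.isin(["specific", "invariant"])], table,
        samples=group_b, classes=("invariant", "specific"),
    )
    dom_assoc = domain_expression_association(domains, genes, table, samples=group_b)
    from .expression_integration import fold_change_classify

    de = fold_change_classify(table, group_a, group_b, min_fold=config.min_fold_change)
    summary["expression"] = {
        "n_detected": int(len(detected)),
        "n_filtered": int(len(filtered)),
        "n_up": int((de == "up").sum()),
        "n_down": int((de == "down").sum()),
        "class_comparison": {
            "medians": comparison.medians,
            "p_value": comparison.p_value,
            "compared": comparison.compared,
        },
        "domain_association": {
            "medians": dom_assoc.medians,
            "p_value": dom_assoc.p_value,
        },
    }

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    logger.info("run_all complete")
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
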