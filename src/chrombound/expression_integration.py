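"""Expression detection/filter/fold-change rules and peak/domain-to-gene linkage.

Counts are normalized to CPM (counts per million) against per-sample library
sizes. The detection rule keeps genes whose *median* CPM exceeds a threshold;
the filtering rule keeps genes exceeding the threshold in at least a minimum
number of samples; differential classification compares pseudocounted group
mean CPMs against a fold-change cutoff. Peaks are linked to genes when they
lie within a distance of the TSS (edge distance, overlap counting as zero),
and expression is compared across the resulting gene classes with a two-sided
Wilcoxon rank-sum (Mann-Whitney U) test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_intervals import IntervalSet, within_distance
from .genome_bins import GeneModel
from .repressive_domains import RepressiveDomain

__all__ = [
    "ExpressionTable",
    "ClassExpressionSummary",
    "detect_transcripts",
    "filter_transcripts",
    "fold_change_classify",
    "link_peaks_to_genes",
    "compare_expression_by_class",
    "domain_expression_association",
]

# higher wins when a gene is linked to peaks of several classes
_CLASS_PRECEDENCE = {"specific": 2, "invariant": 1}


@dataclass
class ExpressionTable:
    """Genes x samples raw counts with derived CPM.

    ``library_sizes`` defaults to per-sample column sums. CPM columns sum to
    1e6 when library sizes are the column sums.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = self.library_sizes.astype(float)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be > 0")
        if not self.library_sizes.index.equals(self.counts.columns):
            raise ValueError("library_sizes index must match count columns")

    @property
    def cpm(self) -> pd.DataFrame:
        return self.counts / self.library_sizes * 1e6

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class ClassExpressionSummary:
    """Per-class expression distributions and their rank-sum comparison."""

    class_values: dict[str, np.ndarray]
    medians: dict[str, float]
    statistic: float | None
    p_value: float | None
    compared: tuple[str, str] | None
    skipped: list[str] = field(default_factory=list)

    @property
    def median_difference(self) -> float | None:
        if self.compared is None:
            return None
        a, b = self.compared
        return self.medians[b] - self.medians[a]


def detect_transcripts(table: ExpressionTable, cpm_threshold: float = 1.0) -> pd.Index:
    """Genes with median CPM strictly greater than the threshold."""
    med = table.cpm.median(axis=1)
    return table.genes[med > cpm_threshold]


def filter_transcripts(
    table: ExpressionTable, cpm_threshold: float = 1.0, min_samples: int = 3
) -> pd.Index:
    """Genes whose CPM exceeds the threshold in at least ``min_samples`` samples."""
    if min_samples > len(table.samples):
        raise ValueError("min_samples exceeds number of samples")
    n_pass = (table.cpm > cpm_threshold).sum(axis=1)
    return table.genes[n_pass >= min_samples]


def fold_change_classify(
    table: ExpressionTable,
    group_a: list[str],
    group_b: list[str],
    min_fold: float = 2.0,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Classify genes as up/down/unchanged in B relative to A.

    ``ratio = (mean CPM_b + pseudocount) / (mean CPM_a + pseudocount)``;
    up iff ratio > min_fold, down iff ratio < 1/min_fold.
    """
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    cpm = table.cpm
    ratio = (cpm[group_b].mean(axis=1) + pseudocount) / (
        cpm[group_a].mean(axis=1) + pseudocount
    )
    out = pd.Series("unchanged", index=table.genes, name="de_class")
    out[ratio > min_fold] = "up"
    out[ratio < 1.0 / min_fold] = "down"
    return out


def link_peaks_to_genes(
    peaks: IntervalSet,
    genes: list[GeneModel],
    d: int = 1_000,
    peak_classes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Link peaks to genes by TSS proximity (edge distance <= ``d``).

    Returns one row per gene with columns ``gene_id, linked (bool),
    n_linked_peaks, classes (sorted unique linked classes), gene_class``.
    When a gene is linked to peaks of several classes its ``gene_class``
    follows the precedence specific > invariant > (first other
    alphabetically); all classes remain listed in ``classes``.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    p_chrom = peaks.df["chrom"].to_numpy()
    p_start = peaks.df["start"].to_numpy()
    p_end = peaks.df["end"].to_numpy()
    if peak_classes is None:
        peak_classes = np.full(len(peaks), "peak", dtype=object)
    else:
        peak_classes = np.asarray(peak_classes, dtype=object)
        if len(peak_classes) != len(peaks):
            raise ValueError("peak_classes length mismatch")
    rows = []
    for gene in genes:
        sel = np.flatnonzero(p_chrom == gene.chrom)
        if len(sel):
            dist = np.maximum(
                0, np.maximum(p_start[sel] - gene.tss, gene.tss - p_end[sel])
            )
            hit = sel[dist <= d]
        else:
            hit = np.empty(0, dtype=int)
        classes = sorted(set(peak_classes[hit]))
        if classes:
            gene_class = max(
                classes, key=lambda c: (_CLASS_PRECEDENCE.get(c, 0), c)
            )
        else:
            gene_class = "unlinked"
        rows.append(
            {
                "gene_id": gene.gene_id,
                "linked": len(hit) > 0,
                "n_linked_peaks": len(hit),
                "classes": ",".join(classes),
                "gene_class": gene_class,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _expression_values(
    table: ExpressionTable, samples: list[str] | None
) -> pd.Series:
    cols = list(table.samples) if samples is None else samples
    return np.log2(table.cpm[cols].mean(axis=1) + 1.0)


def compare_expression_by_class(
    gene_classes: pd.Series,
    table: ExpressionTable,
    samples: list[str] | None = None,
    classes: tuple[str, str] | None = None,
) -> ClassExpressionSummary:
    """Compare log2(mean CPM + 1) between two gene classes (rank-sum test).

    ``gene_classes`` maps gene id -> class label; genes absent from the
    expression table are ignored. ``classes`` picks the two classes to
    compare (default: the two largest). Classes with fewer than two genes are
    skipped with a note.
    """
    expr = _expression_values(table, samples)
    gene_classes = gene_classes[gene_classes.index.isin(expr.index)]
    values: dict[str, np.ndarray] = {}
    medians: dict[str, float] = {}
    for cls, members in gene_classes.groupby(gene_classes):
        vals = expr.loc[members.index].to_numpy(dtype=float)
        values[cls] = vals
        medians[cls] = float(np.median(vals)) if len(vals) else np.nan
    skipped = [c for c, v in values.items() if len(v) < 2]
    eligible = [c for c in values if len(values[c]) >= 2]
    if classes is None:
        eligible.sort(key=lambda c: -len(values[c]))
        pair = tuple(eligible[:2]) if len(eligible) >= 2 else None
    else:
        pair = classes if all(c in eligible for c in classes) else None
    if pair is None:
        return ClassExpressionSummary(values, medians, None, None, None, skipped)
    a, b = pair
    stat, p = stats.mannwhitneyu(values[a], values[b], alternative="two-sided")
    return ClassExpressionSummary(values, medians, float(stat), float(p), (a, b), skipped)


def domain_expression_association(
    domains: list[RepressiveDomain],
    genes: list[GeneModel],
    table: ExpressionTable,
    samples: list[str] | None = None,
) -> ClassExpressionSummary:
    """Compare expression of genes whose TSS falls inside vs outside domains."""
    labels = {}
    for gene in genes:
        inside = any(
            dom.interval.chrom == gene.chrom
            and dom.interval.start <= gene.tss < dom.interval.end
            for dom in domains
        )
        labels[gene.gene_id] = "in_domain" if inside else "outside"
    series = pd.Series(labels, name="domain_class")
    return compare_expression_by_class(
        series, table, samples=samples, classes=("outside", "in_domain")
    )
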