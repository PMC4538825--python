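"""Catalog characterization against gene models, expression and mark sets.

Answers the descriptive questions about a catalog of suspect loci: where do
they sit relative to genes (promoter / TTS / exon / intron / intergenic),
how many lie within TSS windows, does their prevalence at promoters track
gene expression, and how strongly do they co-occur with histone-mark peak
sets and transcription-factor binding ("HOT" regions, conventionally loci
bound by more than 8 distinct factors).

Feature assignment is midpoint-based with a fixed priority
promoter > TTS > exon > intron > intergenic, so the category fractions
partition to 1. Promoter and TTS windows default to +/- 1000 bp around the
TSS/TTS; the half-width is a parameter since reasonable conventions differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import (
    GenomicInterval,
    IntervalSet,
    merge_intervals,
    overlap_hits,
    windows_around_points,
)
from .io import ExpressionTable, GeneModel
from .phantom import PhantomCatalog

CATEGORIES = ("promoter", "TTS", "exon", "intron", "intergenic")


@dataclass
class FeatureAssignment:
    category: str
    gene_id: str | None
    distance_to_tss: int | None


def _loci(catalog) -> IntervalSet:
    return catalog.loci if isinstance(catalog, PhantomCatalog) else catalog


def assign_feature(
    peak: GenomicInterval,
    models: list[GeneModel],
    promoter_halfwidth: int = 1000,
    tts_halfwidth: int = 1000,
) -> FeatureAssignment:
    """Assign one peak to a genomic feature category by its midpoint.

    Priority: promoter (TSS +/- halfwidth, half-open window) > TTS window >
    exon > intron > intergenic. Ties between genes within a category are
    broken by smaller absolute distance to that gene's TSS, then by
    lexicographic gene_id.
    """
    if not models:
        raise ValueError("models must be non-empty")
    mid = peak.midpoint
    best: dict[str, tuple[int, str, str]] = {}  # category -> (|dTSS|, gid, signed)
    for m in models:
        if m.chrom != peak.chrom:
            continue
        d = mid - m.tss
        key = (abs(d), m.gene_id)
        if m.tss - promoter_halfwidth <= mid < m.tss + promoter_halfwidth:
            cat = "promoter"
        elif m.tts - tts_halfwidth <= mid < m.tts + tts_halfwidth:
            cat = "TTS"
        elif any(s <= mid < e for s, e in m.exons):
            cat = "exon"
        elif any(s <= mid < e for s, e in m.introns):
            cat = "intron"
        else:
            continue
        if cat not in best or key < (best[cat][0], best[cat][1]):
            best[cat] = (abs(d), m.gene_id, d)
    for cat in CATEGORIES[:-1]:
        if cat in best:
            _, gid, d = best[cat]
            return FeatureAssignment(cat, gid, int(d))
    return FeatureAssignment("intergenic", None, None)


def feature_distribution(
    catalog,
    models: list[GeneModel],
    promoter_halfwidth: int = 1000,
    tts_halfwidth: int = 1000,
) -> dict[str, float]:
    """Fraction of catalog loci per feature category (sums to 1)."""
    loci = _loci(catalog)
    if len(loci) == 0:
        raise ValueError("empty catalog")
    counts = dict.fromkeys(CATEGORIES, 0)
    for iv in loci:
        counts[assign_feature(iv, models, promoter_halfwidth,
                              tts_halfwidth).category] += 1
    n = len(loci)
    return {c: counts[c] / n for c in CATEGORIES}


def tss_window_fraction(
    catalog,
    models: list[GeneModel],
    window_total: int = 4000,
    chrom_sizes: dict[str, int] | None = None,
) -> float:
    """Fraction of catalog loci whose midpoint lies in the merged union of
    fixed-width TSS windows (default 4 kb total width)."""
    loci = _loci(catalog)
    if len(loci) == 0:
        raise ValueError("empty catalog")
    wins = merge_intervals(
        windows_around_points(
            [(m.chrom, m.tss) for m in models], window_total, chrom_sizes
        )
    )
    mids = loci.midpoints()
    chroms = loci.df["chrom"].to_numpy()
    inside = 0
    for chrom, mid in zip(chroms, mids):
        ws, we = wins.arrays(chrom)
        if len(ws) == 0:
            continue
        i = np.searchsorted(ws, mid, side="right") - 1
        if i >= 0 and mid < we[i]:
            inside += 1
    return inside / len(loci)


def expression_quintile_prevalence(
    models: list[GeneModel],
    expr: ExpressionTable,
    catalog,
    promoter_halfwidth: int = 1000,
) -> dict:
    """Catalog prevalence at promoters, by gene-expression quintile.

    Genes with expression values are ranked (ascending) and split into five
    equal groups, any remainder going to the lower bins; per group, the
    fraction of genes whose promoter window (TSS +/- halfwidth) contains at
    least one catalog-locus midpoint is reported together with the group
    mean expression. Genes without an expression value are excluded and
    tallied.
    """
    loci = _loci(catalog)
    known = [(m, expr.get(m.gene_id)) for m in models]
    usable = [(m, v) for m, v in known if v is not None]
    n_excluded = len(known) - len(usable)
    if len(usable) < 5:
        raise ValueError("expression available for fewer than 5 genes")
    usable.sort(key=lambda t: (t[1], t[0].gene_id))

    mids_by_chrom: dict[str, np.ndarray] = {}
    for chrom in loci.chroms():
        mask = (loci.df["chrom"] == chrom).to_numpy()
        mids_by_chrom[chrom] = np.sort(loci.midpoints()[mask])

    def has_peak(m: GeneModel) -> bool:
        mids = mids_by_chrom.get(m.chrom)
        if mids is None:
            return False
        lo = np.searchsorted(mids, m.tss - promoter_halfwidth, side="left")
        hi = np.searchsorted(mids, m.tss + promoter_halfwidth, side="left")
        return hi > lo

    n = len(usable)
    base, rem = divmod(n, 5)
    sizes = [base + (1 if i < rem else 0) for i in range(5)]
    prevalence, mean_expr, bounds = [], [], []
    pos = 0
    for size in sizes:
        group = usable[pos: pos + size]
        pos += size
        prevalence.append(
            sum(has_peak(m) for m, _ in group) / size if size else float("nan")
        )
        vals = [v for _, v in group]
        mean_expr.append(float(np.mean(vals)) if vals else float("nan"))
        bounds.append((vals[0], vals[-1]) if vals else None)
    return {
        "prevalence": prevalence,
        "mean_expression": mean_expr,
        "group_sizes": sizes,
        "n_excluded": n_excluded,
    }


def binary_mark_matrix(
    catalog,
    mark_sets: list[tuple[str, IntervalSet]],
    min_overlap: int = 1,
) -> np.ndarray:
    """Binary loci x marks co-occurrence matrix.

    Entry (i, j) is 1 iff catalog locus i overlaps mark set j by at least
    ``min_overlap`` bp; column means give per-mark prevalence. Returns a
    structured result: (matrix, labels).
    """
    loci = _loci(catalog)
    labels = [label for label, _ in mark_sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate mark labels")
    mat = np.zeros((len(loci), len(mark_sets)), dtype=np.int8)
    for j, (_, s) in enumerate(mark_sets):
        if len(s) == 0:
            continue
        hits, _ = overlap_hits(loci, s, min_overlap)
        mat[:, j] = hits
    return mat, labels


def tf_count_profile(
    catalog,
    tf_sets: list[tuple[str, IntervalSet]],
    hot_threshold: int = 8,
) -> dict:
    """Per-locus count of distinct overlapping TF sets, and the HOT fraction.

    A locus is counted once per TF label with >= 1 bp overlap; the histogram
    is normalized over loci. Loci overlapped by strictly more than
    ``hot_threshold`` distinct factors are "HOT".
    """
    if not tf_sets:
        raise ValueError("need at least one TF set")
    loci = _loci(catalog)
    if len(loci) == 0:
        raise ValueError("empty catalog")
    mat, _ = binary_mark_matrix(catalog, tf_sets, min_overlap=1)
    counts = mat.astype(np.int64).sum(axis=1)
    hist = {
        int(k): int(v) / len(loci)
        for k, v in zip(*np.unique(counts, return_counts=True))
    }
    return {
        "histogram": hist,
        "hot_fraction": float((counts > hot_threshold).mean()),
        "counts": counts,
    }
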