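"""Phantom Peak catalog derivation and the high-read-density (HDR) filter.

A "Phantom Peak" is a locus reproducibly enriched by ChIP even when the
profiled antigen is absent: any peak shared between a wild-type profile and
the matching antigen-null mutant profile cannot reflect specific
immunoprecipitation and is a false positive of the ChIP procedure itself.
This module derives such shared-peak lists per factor
(:func:`common_peaks`), combines them across factors into a merged catalog
with per-locus provenance (:func:`build_catalog`), and computes the
high-read-density regions of input chromatin (:func:`derive_hdrs`) used to
check that the catalog is not a copy-number/accessibility artifact: only a
small catalog fraction is expected to fall in HDRs
(:func:`hdr_overlap_fraction`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import IntervalSet, merge_intervals, overlap_hits
from .io import CoverageTrack


@dataclass
class CommonPeaksResult:
    """Shared peaks between a WT and an antigen-null profile.

    ``common`` holds the WT peaks (WT-anchored convention) having a
    qualifying overlap with some mutant peak.
    """

    common: IntervalSet
    n_wt_only: int
    n_mutant_only: int
    n_common: int


@dataclass
class PhantomCatalog:
    """Merged union of per-factor shared (false-positive) peak sets.

    ``provenance[i]`` lists the factor labels whose shared peaks support
    locus ``i`` of ``loci`` (frame order).
    """

    loci: IntervalSet
    provenance: list[list[str]]
    parameters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.loci)


@dataclass
class HdrSet:
    """High read density regions: top-quantile input-coverage bins, merged."""

    regions: IntervalSet
    top_fraction: float
    source_track: str = ""

    def __len__(self) -> int:
        return len(self.regions)


def common_peaks(
    wt: IntervalSet,
    mutant: IntervalSet,
    min_overlap: int = 50,
) -> CommonPeaksResult:
    """Peaks shared between WT and antigen-null profiles — the false positives.

    A WT peak is "common" iff it overlaps some (merged) mutant peak by at
    least ``min_overlap`` bp. The returned intervals are the WT peaks
    themselves (Venn counts are per-profile peak counts, so one anchor must
    be fixed; WT is used).
    """
    wt_hits, _ = overlap_hits(wt, mutant, min_overlap)
    mut_hits, _ = overlap_hits(mutant, wt, min_overlap)
    common = IntervalSet(wt.df[wt_hits], name=f"{wt.name}_common")
    return CommonPeaksResult(
        common=common,
        n_wt_only=int((~wt_hits).sum()),
        n_mutant_only=int((~mut_hits).sum()),
        n_common=int(wt_hits.sum()),
    )


def build_catalog(
    common_sets: list[tuple[str, IntervalSet]],
    merge_gap: int = 0,
) -> PhantomCatalog:
    """Combine per-factor shared-peak sets into a merged catalog.

    The union of all sets is merged with ``merge_gap``; each catalog locus
    records which factor labels contributed at least one overlapping member.
    Order-independent: permuting ``common_sets`` yields a base-identical
    catalog.
    """
    if not common_sets:
        raise ValueError("need at least one common-peak set")
    labels = [label for label, _ in common_sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate set labels")
    all_rows = []
    for _, s in common_sets:
        all_rows.extend(
            (c, int(a), int(b))
            for c, a, b in s.df[["chrom", "start", "end"]].itertuples(index=False)
        )
    loci = merge_intervals(IntervalSet(all_rows, name="phantom_catalog"),
                           min_gap=merge_gap)
    provenance: list[list[str]] = [[] for _ in range(len(loci))]
    for label, s in common_sets:
        if len(s) == 0:
            continue
        hits, pairs = overlap_hits(loci, s, min_overlap=1)
        for i in np.flatnonzero(hits):
            provenance[int(i)].append(label)
    return PhantomCatalog(
        loci=loci,
        provenance=provenance,
        parameters={"merge_gap": merge_gap, "labels": labels},
    )


def top_fraction_threshold(values: np.ndarray, top_fraction: float) -> float:
    """Score of the k-th highest value, k = max(1, floor(top_fraction * n)).

    Selecting ``value >= threshold`` keeps the top fraction by rank with
    ties at the threshold included — a plain rank rule rather than an
    interpolated quantile, so "top 1% of 1010 bins" means exactly the 10
    highest (plus ties).
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("no values to rank")
    if values.max() == values.min():
        raise ValueError("quantile degenerate: all values equal")
    k = max(1, int(np.floor(top_fraction * n)))
    return float(np.partition(values, n - k)[n - k])


def derive_hdrs(
    input_track: CoverageTrack,
    top_fraction: float = 0.01,
    merge_gap: int = 0,
) -> HdrSet:
    """High read density regions: the top-scoring input-coverage bins, merged.

    The threshold is the rank-based top-fraction cutoff over ALL genome bins
    (zeros included — the ranking is genome-wide); bins at or above it are
    selected and merged into regions. The merged-region genome fraction
    typically exceeds ``top_fraction`` because selected bins cluster.
    """
    values = input_track.all_values()
    if values.size == 0:
        raise ValueError("input track is empty")
    threshold = top_fraction_threshold(values, top_fraction)
    bs = input_track.bin_size
    rows = []
    for chrom in sorted(input_track.data):
        sel = np.flatnonzero(input_track.data[chrom] >= threshold)
        for b in sel:
            rows.append((chrom, int(b) * bs, (int(b) + 1) * bs))
    regions = merge_intervals(IntervalSet(rows, name="hdrs"), min_gap=merge_gap)
    return HdrSet(
        regions=regions,
        top_fraction=top_fraction,
        source_track=input_track.library_label,
    )


def hdr_genome_fraction(hdrs: HdrSet, genome_bp: int) -> float:
    """Fraction of the genome covered by HDR regions."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    return sum(int(w) for w in hdrs.regions.widths()) / genome_bp


def hdr_overlap_fraction(
    catalog: PhantomCatalog,
    hdrs: HdrSet,
    min_overlap: int = 1,
    filter_overlapping: bool = False,
):
    """Fraction of catalog loci with a qualifying HDR overlap.

    With ``filter_overlapping=True``, additionally returns a catalog with
    those loci removed (provenance carried over). By default the catalog is
    left intact — HDR overlap is a reported diagnostic, not a filter.
    """
    if len(catalog.loci) == 0:
        raise ValueError("empty catalog")
    hits, _ = overlap_hits(catalog.loci, hdrs.regions, min_overlap)
    fraction = float(hits.mean())
    if not filter_overlapping:
        return fraction
    keep = ~hits
    filtered = PhantomCatalog(
        loci=IntervalSet(catalog.loci.df[keep], name=catalog.loci.name),
        provenance=[p for p, k in zip(catalog.provenance, keep) if k],
        parameters={**catalog.parameters, "hdr_filtered": True},
    )
    return fraction, filtered
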