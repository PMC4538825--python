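"""Binding-site derivation from DamID probe scores.

DamID is antibody-free: the protein of interest is fused to Dam methylase
and binding sites appear as high-scoring methylation probes on a tiling
array. Comparing DamID-derived sites with a ChIP-derived catalog helps tell
genuine binding from immunoprecipitation artifacts, since the two methods
do not share the antibody failure mode.

Sites are derived by the standard percentile rule: keep the top-scoring
fraction of probes (ties at the threshold all included), extend each probe
position symmetrically to a fixed total width, and merge.
"""

from __future__ import annotations

import numpy as np

from .intervals import IntervalSet, merge_intervals
from .io import DamIdProbeTable
from .phantom import top_fraction_threshold
from .overlap_stats import OverlapReport, ReferenceRegions, reference_constrained_test
from .phantom import PhantomCatalog


def damid_peaks(
    probes: DamIdProbeTable,
    top_fraction: float = 0.01,
    extend_to: int = 1000,
) -> IntervalSet:
    """Derive binding-site intervals from a probe table.

    Probes scoring at or above the rank-based top-fraction cutoff (ties
    included) become intervals of total width ``extend_to`` centered on the
    probe position (clipped at 0); overlapping or abutting intervals are
    merged.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    if extend_to < 1:
        raise ValueError("extend_to must be >= 1")
    if len(probes) < 100:
        raise ValueError(
            f"need >= 100 probes for a stable top percentile, got {len(probes)}"
        )
    scores = probes.records["score"].to_numpy(dtype=float)
    threshold = top_fraction_threshold(scores, top_fraction)
    top = probes.records[scores >= threshold]
    half = extend_to // 2
    # clipping at 0 shortens the interval rather than shifting it
    rows = [
        (chrom, max(0, int(pos) - half), int(pos) + (extend_to - half))
        for chrom, pos in top[["chrom", "position"]].itertuples(index=False)
    ]
    return merge_intervals(IntervalSet(rows, name="damid_peaks"))


def damid_vs_catalog(
    damid_regions: IntervalSet,
    catalog: PhantomCatalog | IntervalSet,
    ref: ReferenceRegions,
    min_overlap: int = 50,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> OverlapReport:
    """Screen DamID-derived regions against a catalog.

    Thin delegate to the reference-constrained overlap test with the DamID
    regions as query.
    """
    return reference_constrained_test(
        damid_regions, catalog, ref,
        min_overlap=min_overlap, n_perm=n_perm, seed=seed,
        profile_label=damid_regions.name or "damid",
    )
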