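"""Synthetic worlds with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* a set of "sticky" promoter loci that appear in ChIP profiles of *every*
  antibody and genotype (the planted Phantom Peaks), with a propensity that
  rises logistically with gene-expression rank — active promoters are
  stickier;
* per-factor genuine binding loci that appear only in wild-type profiles
  and vanish in the antigen-null mutant;
* replicate peak sets with center jitter, dropout and uniform background
  false calls;
* input coverage with planted high-read-density regions (HDRs) at 10x
  depth, and ChIP coverage with fold enrichment at the genotype's loci;
* DamID probe tables with elevated scores at chosen target loci.

Defaults define the reference study conditions used throughout the test
suite: a 2 Mb genome (2 chromosomes), 500 genes, 2 factors with 3
antibody replicates each, 20 bp replicate jitter, 10% dropout.

All randomness flows from the single config seed; per-stage child seeds are
derived by stable hashing of stage names (CRC-32), so each artifact is
reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .intervals import IntervalSet, merge_intervals
from .io import CoverageTrack, DamIdProbeTable, ExpressionTable, GeneModel
import pandas as pd

GENOTYPES = ("WT", "mutant")


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic world; defaults are the reference conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 500
    expression_mu: float = 1.0
    expression_sigma: float = 1.0
    sticky_intercept: float = -4.0
    sticky_slope: float = 5.0
    n_genuine_per_factor: int = 100
    peak_width: int = 200
    replicate_jitter_sd: float = 20.0
    replicate_dropout: float = 0.1
    background_peak_rate: float = 5.0  # false peaks per Mb per replicate
    coverage_depth: float = 10.0  # mean reads per bin
    chip_enrichment_fold: float = 10.0
    hdr_fraction: float = 0.01  # fraction of genome planted as HDR
    hdr_region_width: int = 1000
    damid_probe_spacing: int = 100
    bin_size: int = 25
    factors: tuple[str, ...] = ("ACF1", "RSF1")

    def __post_init__(self) -> None:
        for name in ("replicate_dropout", "hdr_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.peak_width < 1 or self.chrom_length < 1:
            raise ValueError("peak_width and chrom_length must be positive")
        if self.damid_probe_spacing < 1:
            raise ValueError("damid_probe_spacing must be positive")

    def chrom_sizes(self) -> dict[str, int]:
        return {
            f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)
        }


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for one named stage, stable across runs/platforms."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic world."""

    config: SyntheticConfig
    genes: list[GeneModel]
    expression: ExpressionTable
    sticky_loci: IntervalSet
    sticky_gene_ids: list[str]
    genuine_loci: dict[str, IntervalSet]  # per factor
    hdr_loci: IntervalSet


def generate_world(cfg: SyntheticConfig) -> SyntheticTruth:
    """Generate gene models, expression, sticky/genuine/HDR loci.

    Genes are laid down left to right with jittered spacing and never
    overlap; each has 2-4 exons. A gene's promoter becomes sticky with
    probability ``logistic(intercept + slope * expression_rank_pct)``; the
    sticky locus is a peak-width interval centered at the TSS. Genuine loci
    per factor are drawn uniformly over non-sticky promoters and intergenic
    space, disjoint from sticky loci and from one another within a factor.
    """
    rng = stage_rng(cfg.seed, "world")
    sizes = cfg.chrom_sizes()
    per_chrom = _split_counts(cfg.n_genes, cfg.n_chroms, rng)

    genes: list[GeneModel] = []
    gid = 0
    for ci, (chrom, clen) in enumerate(sorted(sizes.items())):
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = clen // n
        if slot < 3000:
            raise ValueError(
                f"infeasible gene density on {chrom}: {n} genes in {clen} bp"
            )
        for k in range(n):
            glen = int(rng.integers(1000, 3001))
            lo_bound = k * slot + 500
            hi_bound = (k + 1) * slot - glen - 500
            start = int(rng.integers(lo_bound, max(lo_bound + 1, hi_bound)))
            end = start + glen
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(
                np.arange(start + 50, end - 50), size=2 * (n_ex - 1),
                replace=False,
            ))
            bounds = [start, *cuts.tolist(), end]
            exons = [
                (int(bounds[2 * i]), int(bounds[2 * i + 1]))
                for i in range(n_ex)
            ]
            tss, tts = (start, end) if strand == "+" else (end, start)
            gid += 1
            genes.append(GeneModel(f"g{gid:04d}", chrom, strand, tss, tts, exons))

    expr_rng = stage_rng(cfg.seed, "expression")
    values = expr_rng.lognormal(cfg.expression_mu, cfg.expression_sigma,
                                size=len(genes))
    expression = ExpressionTable(
        {g.gene_id: float(v) for g, v in zip(genes, values)}
    )

    # sticky propensity: logistic in expression rank percentile
    order = np.argsort(values, kind="stable")
    rank_pct = np.empty(len(genes))
    rank_pct[order] = (np.arange(len(genes)) + 0.5) / len(genes)
    logit = cfg.sticky_intercept + cfg.sticky_slope * rank_pct
    p_sticky = 1.0 / (1.0 + np.exp(-logit))
    sticky_rng = stage_rng(cfg.seed, "sticky")
    is_sticky = sticky_rng.random(len(genes)) < p_sticky

    half = cfg.peak_width // 2
    sticky_rows, sticky_ids = [], []
    for g, s in zip(genes, is_sticky):
        if s:
            lo = max(0, g.tss - half)
            sticky_rows.append((g.chrom, lo, lo + cfg.peak_width))
            sticky_ids.append(g.gene_id)
    sticky = IntervalSet(sticky_rows, name="sticky_truth")

    # genuine loci per factor: uniform over space clear of sticky loci,
    # other genuine loci of the same factor, and a guard margin
    genuine: dict[str, IntervalSet] = {}
    for factor in cfg.factors:
        g_rng = stage_rng(cfg.seed, f"genuine:{factor}")
        rows = _place_disjoint(
            n=cfg.n_genuine_per_factor,
            width=cfg.peak_width,
            sizes=sizes,
            avoid=sticky,
            margin=cfg.peak_width,
            rng=g_rng,
        )
        genuine[factor] = IntervalSet(rows, name=f"genuine_{factor}")

    hdr_rng = stage_rng(cfg.seed, "hdr")
    genome_bp = sum(sizes.values())
    n_hdr = max(1, int(round(cfg.hdr_fraction * genome_bp / cfg.hdr_region_width)))
    hdr_rows = _place_disjoint(
        n=n_hdr, width=cfg.hdr_region_width, sizes=sizes,
        avoid=None, margin=cfg.hdr_region_width, rng=hdr_rng,
    )
    hdr = merge_intervals(IntervalSet(hdr_rows, name="hdr_truth"))

    return SyntheticTruth(
        config=cfg,
        genes=genes,
        expression=expression,
        sticky_loci=sticky,
        sticky_gene_ids=sticky_ids,
        genuine_loci=genuine,
        hdr_loci=hdr,
    )


def _split_counts(total: int, parts: int, rng: np.random.Generator) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _place_disjoint(
    n: int,
    width: int,
    sizes: dict[str, int],
    avoid: IntervalSet | None,
    margin: int,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> list[tuple[str, int, int]]:
    """Rejection-sample n width-bp intervals disjoint from each other and
    from ``avoid`` (with a margin on both)."""
    chroms = sorted(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    if avoid is not None:
        for c in chroms:
            s, e = avoid.arrays(c)
            taken[c] = list(zip((s - margin).tolist(), (e + margin).tolist()))
    rows: list[tuple[str, int, int]] = []
    for _ in range(n):
        for attempt in range(max_tries):
            c = chroms[int(rng.choice(len(chroms), p=weights))]
            start = int(rng.integers(0, sizes[c] - width))
            end = start + width
            if not any(start < e and s < end for s, e in taken[c]):
                taken[c].append((start - margin, end + margin))
                rows.append((c, start, end))
                break
        else:
            raise ValueError(
                f"could not place interval {len(rows) + 1}/{n}: too dense"
            )
    return rows


def simulate_peak_sets(
    truth: SyntheticTruth,
    genotype: str,
    factor: str,
    n_replicates: int = 3,
) -> list[IntervalSet]:
    """Replicate peak sets for one factor/genotype.

    WT replicates contain sticky + genuine loci; antigen-null mutant
    replicates contain sticky loci only (no antigen, no genuine signal).
    Every emitted peak is center-jittered N(0, jitter_sd), dropped with the
    dropout probability, and Poisson-many background false peaks are added
    uniformly over positions clear of every planted locus (so planted truth
    stays identifiable: a mutant replicate never carries a peak at a genuine
    locus). True loci score ~10x above background.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; use one of {GENOTYPES}")
    if factor not in truth.genuine_loci:
        raise ValueError(f"factor {factor!r} has no genuine loci in truth")
    cfg = truth.config
    sizes = cfg.chrom_sizes()
    base = [
        (c, int(s), int(e))
        for c, s, e in truth.sticky_loci.df[["chrom", "start", "end"]]
        .itertuples(index=False)
    ]
    if genotype == "WT":
        base += [
            (c, int(s), int(e))
            for c, s, e in truth.genuine_loci[factor]
            .df[["chrom", "start", "end"]].itertuples(index=False)
        ]
    avoid: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
    for lset in [truth.sticky_loci, *truth.genuine_loci.values()]:
        for c in sizes:
            s_arr, e_arr = lset.arrays(c)
            avoid[c].extend(zip(s_arr.tolist(), e_arr.tolist()))
    out = []
    genome_mb = sum(sizes.values()) / 1e6
    for r in range(n_replicates):
        rng = stage_rng(cfg.seed, f"peaks:{factor}:{genotype}:rep{r}")
        rows = []
        for chrom, start, end in base:
            if rng.random() < cfg.replicate_dropout:
                continue
            w = end - start
            center = (start + end) // 2 + int(
                round(rng.normal(0, cfg.replicate_jitter_sd))
            )
            lo = max(0, min(center - w // 2, sizes[chrom] - w))
            rows.append((chrom, lo, lo + w, 10.0 + float(rng.exponential(2.0))))
        n_bg = rng.poisson(cfg.background_peak_rate * genome_mb)
        chroms = sorted(sizes)
        weights = np.array([sizes[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        for _ in range(int(n_bg)):
            for _try in range(100):
                c = chroms[int(rng.choice(len(chroms), p=weights))]
                start = int(rng.integers(0, sizes[c] - cfg.peak_width))
                end = start + cfg.peak_width
                if not any(start < e and s < end for s, e in avoid[c]):
                    rows.append((c, start, end,
                                 1.0 + float(rng.exponential(1.0))))
                    break
        records = [
            (c, s, e, f"{factor}_{genotype}_r{r + 1}_p{i + 1}", sc)
            for i, (c, s, e, sc) in enumerate(
                sorted(rows, key=lambda t: (t[0], t[1]))
            )
        ]
        out.append(
            IntervalSet(records, name=f"{factor}_{genotype}_rep{r + 1}")
        )
    return out


def simulate_coverage(
    truth: SyntheticTruth,
    role: str,
    genotype: str = "WT",
    factor: str | None = None,
) -> CoverageTrack:
    """Poisson per-bin coverage for an input or ChIP library.

    Input: mean ``coverage_depth`` everywhere, 10x at planted HDR bins.
    ChIP: same baseline (HDRs included) plus ``chip_enrichment_fold`` x
    depth at the genotype's peak loci (sticky, plus genuine for WT).
    """
    if role not in ("chip", "input"):
        raise ValueError(f"role must be 'chip' or 'input', got {role!r}")
    cfg = truth.config
    sizes = cfg.chrom_sizes()
    bs = cfg.bin_size
    label = f"{role}_{genotype}" + (f"_{factor}" if factor else "")
    rng = stage_rng(cfg.seed, f"coverage:{label}")
    mean = {
        c: np.full(-(-sizes[c] // bs), float(cfg.coverage_depth))
        for c in sizes
    }
    for c in sizes:
        hs, he = truth.hdr_loci.arrays(c)
        for s, e in zip(hs, he):
            mean[c][s // bs: -(-e // bs)] *= 10.0
    if role == "chip":
        if genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {genotype!r}")
        loci = [truth.sticky_loci]
        if genotype == "WT":
            if factor is None:
                raise ValueError("chip coverage for WT needs a factor")
            loci.append(truth.genuine_loci[factor])
        for lset in loci:
            for c in sizes:
                ls, le = lset.arrays(c)
                for s, e in zip(ls, le):
                    mean[c][s // bs: -(-e // bs)] += (
                        cfg.chip_enrichment_fold * cfg.coverage_depth
                    )
    data = {c: rng.poisson(mean[c]).astype(float) for c in sorted(sizes)}
    return CoverageTrack(bs, data, library_label=label)


def simulate_damid(
    truth: SyntheticTruth,
    target_loci: IntervalSet | None = None,
) -> DamIdProbeTable:
    """Tile probes at the configured spacing; scores are N(0, 1) with a +4
    shift for probes inside ``target_loci`` (no targets -> pure noise)."""
    cfg = truth.config
    sizes = cfg.chrom_sizes()
    rng = stage_rng(cfg.seed, "damid")
    if target_loci is not None and len(target_loci) and not target_loci.is_merged():
        target_loci = merge_intervals(target_loci)
    rows = []
    pid = 0
    for c in sorted(sizes):
        positions = np.arange(0, sizes[c], cfg.damid_probe_spacing)
        scores = rng.normal(0.0, 1.0, size=len(positions))
        if target_loci is not None:
            ts, te = target_loci.arrays(c)
            if len(ts):
                idx = np.searchsorted(ts, positions, side="right") - 1
                inside = (idx >= 0) & (positions < te[np.clip(idx, 0, None)])
                scores[inside] += 4.0
        for pos, sc in zip(positions, scores):
            pid += 1
            rows.append((c, int(pos), float(sc), f"probe_{pid:06d}"))
    df = pd.DataFrame(rows, columns=["chrom", "position", "score", "probe_id"])
    return DamIdProbeTable(df)
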