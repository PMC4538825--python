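"""End-to-end orchestration: simulate (optional) -> peaks -> consensus ->
common -> catalog -> HDR -> annotate -> screen -> DamID.

``run_full_analysis`` reads a single YAML config with one section per stage
(every field optional; defaults mirror the stage functions), writes every
stage artifact to the output directory as BED/TSV/JSON with a provenance
header, and records per-stage counts in ``run_log.json``. Stage outputs on
disk are exactly the stage functions' outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotate import expression_quintile_prevalence, feature_distribution, tss_window_fraction
from .damid import damid_peaks, damid_vs_catalog
from .intervals import IntervalSet
from .io import (
    read_bed,
    write_bed,
    write_bedgraph,
    write_damid,
    write_expression,
    write_gene_models,
)
from .overlap_stats import ReferenceRegions, screen_profiles
from .peakcall import PeakCallConfig, call_fixed_width_peaks, consensus_peaks
from .phantom import build_catalog, common_peaks, derive_hdrs, hdr_genome_fraction, hdr_overlap_fraction
from .simulate import (
    SyntheticConfig,
    generate_world,
    simulate_coverage,
    simulate_damid,
    simulate_peak_sets,
)

log = logging.getLogger("phantompeaks")


class ConfigError(ValueError):
    """A missing or malformed configuration field, named."""


def _provenance(stage: str, params: dict, seed) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"phantompeaks v{__version__} stage={stage} {kv} seed={seed}"


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def run_full_analysis(config, outdir=None) -> dict:
    """Run the full pipeline from a config path or dict; returns the run log.

    The config must contain either a ``simulate`` section (synthetic world;
    may be empty to take all defaults) or an ``inputs`` section naming
    wild-type and mutant replicate peak BEDs per factor. Validation happens
    before any stage runs; any stage failure aborts with the stage name,
    retaining partial artifacts.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    out = Path(outdir or cfg.get("outdir", "phantom_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    runlog: dict = {"seed": seed, "stages": {}}

    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs a 'simulate' or an 'inputs' section")

    stage = "setup"
    try:
        if "simulate" in cfg:
            sim_fields = dict(cfg["simulate"] or {})
            sim_fields.setdefault("seed", seed)
            sim = SyntheticConfig(**sim_fields)
            stage = "simulate"
            truth = generate_world(sim)
            write_gene_models(truth.genes, out / "genes.tsv")
            write_expression(truth.expression, out / "expr.tsv")
            write_bed(truth.sticky_loci, out / "truth_sticky.bed",
                      _provenance("simulate", {}, seed))
            for factor, loci in truth.genuine_loci.items():
                write_bed(loci, out / f"truth_genuine_{factor}.bed",
                          _provenance("simulate", {"factor": factor}, seed))
            write_bed(truth.hdr_loci, out / "truth_hdr.bed",
                      _provenance("simulate", {}, seed))
            factors = list(sim.factors)
            n_rep = int(cfg.get("n_replicates", 3))
            replicate_sets = {}
            for factor in factors:
                for genotype in ("WT", "mutant"):
                    reps = simulate_peak_sets(truth, genotype, factor, n_rep)
                    replicate_sets[(factor, genotype)] = reps
                    for i, r in enumerate(reps):
                        write_bed(
                            r,
                            out / f"{factor}_{genotype}_rep{i + 1}.bed".lower(),
                            _provenance("simulate", {
                                "factor": factor, "genotype": genotype,
                            }, seed),
                        )
            input_track = simulate_coverage(truth, "input")
            chip_track = simulate_coverage(truth, "chip", "WT", factors[0])
            write_bedgraph(input_track, out / "input.bedgraph")
            write_bedgraph(chip_track, out / "chip.bedgraph")
            damid_probes = None  # built later against the catalog
            genes = truth.genes
            expr = truth.expression
            chrom_sizes = sim.chrom_sizes()
            runlog["stages"]["simulate"] = {
                "n_genes": len(genes),
                "n_sticky": len(truth.sticky_loci),
                "n_genuine": {f: len(s) for f, s in truth.genuine_loci.items()},
            }
        else:
            inputs = cfg["inputs"]
            for key in ("factors",):
                if key not in inputs:
                    raise ConfigError(f"inputs.{key} is required")
            truth = None
            replicate_sets = {}
            factors = list(inputs["factors"])
            for factor in factors:
                for genotype in ("WT", "mutant"):
                    key = f"{factor}_{genotype}"
                    if key not in inputs:
                        raise ConfigError(f"inputs.{key} is required")
                    replicate_sets[(factor, genotype)] = [
                        read_bed(p) for p in inputs[key]
                    ]
            from .io import read_bedgraph, read_expression, read_gene_models
            input_track = (
                read_bedgraph(inputs["input_bedgraph"])
                if "input_bedgraph" in inputs else None
            )
            chip_track = None
            genes = (
                read_gene_models(inputs["genes"])
                if "genes" in inputs else None
            )
            expr = (
                read_expression(inputs["expression"])
                if "expression" in inputs else None
            )
            damid_probes = None
            chrom_sizes = None

        # optional demonstration of the internal caller on coverage
        if chip_track is not None and input_track is not None:
            stage = "call_peaks"
            pc_cfg = PeakCallConfig(**(cfg.get("peakcall") or {}))
            called = call_fixed_width_peaks(chip_track, input_track, pc_cfg)
            write_bed(called, out / "called_peaks.bed",
                      _provenance("call-peaks", asdict(pc_cfg), seed))
            runlog["stages"]["call_peaks"] = {"n_peaks": len(called)}

        stage = "consensus"
        cons_cfg = cfg.get("consensus") or {}
        min_support = int(cons_cfg.get("min_support", 3))
        cons_overlap = int(cons_cfg.get("min_overlap", 50))
        consensus = {}
        for (factor, genotype), reps in replicate_sets.items():
            consensus[(factor, genotype)] = consensus_peaks(
                reps, min_support=min(min_support, len(reps)),
                min_overlap=cons_overlap,
            )
            write_bed(
                consensus[(factor, genotype)],
                out / f"consensus_{factor}_{genotype}.bed".lower(),
                _provenance("consensus", cons_cfg, seed),
            )
        runlog["stages"]["consensus"] = {
            f"{f}_{g}": len(s) for (f, g), s in consensus.items()
        }

        stage = "common_peaks"
        cat_cfg = cfg.get("catalog") or {}
        min_overlap = int(cat_cfg.get("min_overlap", 50))
        common_sets = []
        for factor in factors:
            res = common_peaks(
                consensus[(factor, "WT")], consensus[(factor, "mutant")],
                min_overlap=min_overlap,
            )
            write_bed(res.common, out / f"common_{factor}.bed".lower(),
                      _provenance("derive", {"min_overlap": min_overlap}, seed))
            common_sets.append((factor, res.common))
            runlog["stages"].setdefault("common_peaks", {})[factor] = {
                "n_common": res.n_common,
                "n_wt_only": res.n_wt_only,
                "n_mutant_only": res.n_mutant_only,
            }

        stage = "catalog"
        catalog = build_catalog(common_sets,
                                merge_gap=int(cat_cfg.get("merge_gap", 0)))
        cat_bed = IntervalSet(
            catalog.loci.df.assign(
                name=[",".join(p) for p in catalog.provenance]
            ),
            name="phantom_catalog",
        )
        write_bed(cat_bed, out / "catalog.bed",
                  _provenance("catalog", catalog.parameters, seed))
        runlog["stages"]["catalog"] = {"n_loci": len(catalog)}

        if input_track is not None:
            stage = "hdr"
            hdr_cfg = cfg.get("hdr") or {}
            hdrs = derive_hdrs(
                input_track,
                top_fraction=float(hdr_cfg.get("top_fraction", 0.01)),
            )
            write_bed(hdrs.regions, out / "hdrs.bed",
                      _provenance("hdr", hdr_cfg, seed))
            genome_bp = sum(
                len(v) * input_track.bin_size
                for v in input_track.data.values()
            )
            runlog["stages"]["hdr"] = {
                "n_regions": len(hdrs),
                "genome_fraction": hdr_genome_fraction(hdrs, genome_bp),
                "catalog_overlap_fraction": hdr_overlap_fraction(catalog, hdrs),
            }

        if genes:
            stage = "annotate"
            ann_cfg = cfg.get("annotate") or {}
            halfwidth = int(ann_cfg.get("promoter_halfwidth", 1000))
            report = {
                "feature_fractions": feature_distribution(
                    catalog, genes, promoter_halfwidth=halfwidth
                ),
                "tss_window_fraction": tss_window_fraction(
                    catalog, genes,
                    window_total=int(ann_cfg.get("tss_window_total", 4000)),
                    chrom_sizes=chrom_sizes,
                ),
            }
            if expr is not None:
                q = expression_quintile_prevalence(
                    genes, expr, catalog, promoter_halfwidth=halfwidth
                )
                report["quintile_prevalence"] = q["prevalence"]
                report["quintile_mean_expression"] = q["mean_expression"]
            with open(out / "annotation.json", "w") as fh:
                json.dump(report, fh, indent=2)
            runlog["stages"]["annotate"] = report

        if genes:
            stage = "screen"
            scr_cfg = cfg.get("screen") or {}
            ref = ReferenceRegions.from_tss(
                genes,
                window_total=int(scr_cfg.get("ref_width", 4000)),
                chrom_sizes=chrom_sizes,
            )
            profiles = [
                (f"{factor}_WT_consensus", consensus[(factor, "WT")])
                for factor in factors
            ]
            table = screen_profiles(
                profiles, catalog, ref,
                min_overlap=int(scr_cfg.get("min_overlap", 50)),
                n_perm=int(scr_cfg.get("n_perm", 1000)),
                seed=seed,
            )
            table.to_csv(out / "screen_report.tsv", sep="\t", index=False)
            runlog["stages"]["screen"] = {
                "n_profiles": len(table),
                "n_flagged": int(table["flagged"].sum()),
            }

            if truth is not None:
                stage = "damid"
                dm_cfg = cfg.get("damid") or {}
                # target a subset of the catalog so the overlap is planted
                frac = float(dm_cfg.get("target_catalog_fraction", 0.3))
                rng = np.random.default_rng(seed)
                n_t = max(1, int(round(frac * len(catalog))))
                pick = np.sort(rng.choice(len(catalog), size=n_t, replace=False))
                targets = IntervalSet(catalog.loci.df.iloc[pick],
                                      name="damid_targets")
                probes = simulate_damid(truth, targets)
                write_damid(probes, out / "damid_probes.tsv")
                regions = damid_peaks(
                    probes,
                    top_fraction=float(dm_cfg.get("top_fraction", 0.01)),
                    extend_to=int(dm_cfg.get("extend_to", 1000)),
                )
                write_bed(regions, out / "damid_peaks.bed",
                          _provenance("damid", dm_cfg, seed))
                rep = damid_vs_catalog(
                    regions, catalog, ref,
                    min_overlap=int(dm_cfg.get("min_overlap", 50)),
                    n_perm=int(scr_cfg.get("n_perm", 1000)),
                    seed=seed + 1,
                )
                runlog["stages"]["damid"] = {
                    "n_regions": len(regions),
                    "fraction_overlapping": rep.fraction_overlapping,
                    "p_perm": rep.p_perm,
                }
    except (ConfigError,):
        raise
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump(runlog, fh, indent=2)
    for name, counts in runlog["stages"].items():
        log.info("stage %s: %s", name, counts)
    return runlog
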