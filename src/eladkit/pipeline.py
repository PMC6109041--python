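"""End-to-end driver: simulate (optional) → sites → eLADs → Hi-C → stats.

The JSON report is the single machine-readable surface: it carries every
summary number the individual stages produce, plus the seed and the full
parameter set needed to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .domains import call_elads, compare_elad_sets, domain_summary, interval_overlap_stats
from .genome import GenomeModel
from .hic import (
    balance_matrix,
    border_peak_occupancy,
    call_borders,
    classify_bin_changes,
    compartment_pc1,
    insulation,
    match_borders,
)
from .simulate import SimulationConfig, simulate_chip_tracks, simulate_expression, simulate_genome, simulate_hic
from .signal import assign_target_genes, call_sites, stratify_expression
from .stats import (
    binarize_feature,
    border_enrichment_pvalue,
    de_target_overlap,
    feature_landmark_log_odds,
    timepoint_dynamics,
)

log = logging.getLogger("eladkit")

__all__ = ["PipelineConfig", "run_pipeline", "validate_report"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; unknown YAML keys are rejected."""

    seed: int = 0
    outdir: str = "eladkit_out"
    simulate: bool = True
    run_hic: bool = True
    # simulator
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    depth: int = 1_000_000
    enrichment: float = 4.0
    bin_size: int = 1000
    # site caller
    fdr: float = 0.05
    min_fold: float = 2.0
    tss_window: int = 2000
    silent_threshold: float = 0.5
    # eLAD caller
    max_gap: int = 100_000
    min_sites: int = 3
    # Hi-C
    compartment_resolution: int = 100_000
    tad_resolution: int = 40_000
    insulation_window: int = 5
    prominence_min: float = 0.5
    border_tol: int = 2
    border_span: int = 1
    min_abs_pc1: float = 0.0

    def __post_init__(self):
        if self.fdr <= 0 or self.fdr >= 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.bin_size <= 0 or self.max_gap <= 0 or self.min_sites < 1:
            raise ValueError("parameter out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
        if "chromosomes" in sim_raw:
            sim_raw["chromosomes"] = tuple(
                (c, int(l)) for c, l in sim_raw["chromosomes"]
            )
        if "conditions" in sim_raw:
            sim_raw["conditions"] = tuple(sim_raw["conditions"])
        return cls(sim=SimulationConfig(**sim_raw), **raw)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: PipelineConfig, genome: GenomeModel | None = None) -> dict:
    """Run every stage the configuration enables and return the report.

    With ``simulate=True`` (the default and only fully wired mode, since
    the package ships no real data) inputs are generated in memory; any
    stage failure aborts with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": _jsonify(dataclasses.asdict(config)),
        "stages": {},
    }
    stage = "simulate"
    try:
        if not config.simulate:
            raise NotImplementedError(
                "external-input mode requires calling the library functions directly"
            )
        genome, truth = simulate_genome(config.sim, config.seed)
        conds = list(config.sim.conditions)
        log.info("simulated genome: %d genes, %d conditions", len(genome.genes), len(conds))

        stage = "call_sites"
        peaksets, targets = {}, {}
        for i, cond in enumerate(conds):
            chip, ctrl = simulate_chip_tracks(
                genome, truth, cond, depth=config.depth,
                enrichment=config.enrichment, bin_size=config.bin_size,
                seed=config.seed + 1000 + i,
            )
            peaksets[cond] = call_sites(chip, ctrl, fdr=config.fdr,
                                        min_fold=config.min_fold, condition=cond)
            targets[cond] = assign_target_genes(peaksets[cond], genome, config.tss_window)
        report["stages"]["call_sites"] = {
            c: {"n_peaks": len(peaksets[c]), "n_target_genes": len(targets[c])}
            for c in conds
        }

        stage = "expression"
        expr = simulate_expression(genome, truth, seed=config.seed + 2000)
        strata = {c: stratify_expression(expr, c, config.silent_threshold) for c in conds}
        report["stages"]["expression"] = {
            c: strata[c].value_counts().to_dict() for c in conds
        }

        stage = "call_elads"
        elads = {c: call_elads(peaksets[c], config.max_gap, config.min_sites, genome)
                 for c in conds}
        summaries = {c: domain_summary(elads[c], genome) for c in conds}
        report["stages"]["elads"] = {
            c: {"n_domains": s[0], "mean_size_bp": s[1], "coverage_fraction": s[2]}
            for c, s in summaries.items()
        }
        frac, jacc, _ = interval_overlap_stats(
            {ch: elads[conds[0]].intervals(ch) for ch in elads[conds[0]].chroms()},
            genome.clads,
        )
        report["stages"]["elads"]["clad_overlap"] = {
            "fraction_of_elads_in_clads": frac, "jaccard": jacc
        }
        dyn_domains = compare_elad_sets(list(elads.values()))
        report["stages"]["elads"]["dynamics"] = {
            c: {k: len(v) for k, v in d.items()} for c, d in dyn_domains.items()
        }

        stage = "dynamics"
        dyn = timepoint_dynamics(targets)
        report["stages"]["dynamics"] = {
            "union": dyn.union_size, "maintained": dyn.maintained,
            "changed": dyn.changed, "maintained_pct": dyn.maintained_pct,
            "changed_pct": dyn.changed_pct, "venn": dyn.venn,
        }
        report["stages"]["de_overlap"] = {}
        for cond in conds[1:]:
            ov, pct_t, pct_d, _ = de_target_overlap(truth.de_genes[cond], targets[conds[0]])
            report["stages"]["de_overlap"][cond] = {
                "overlap": ov, "pct_targets_de": pct_t, "pct_de_targets": pct_d
            }

        if config.run_hic:
            stage = "compartments"
            chrom = genome.chromosomes[0][0]
            dens100 = genome.gene_density(chrom, config.compartment_resolution)
            profiles, partitions = {}, {}
            for i, cond in enumerate(conds):
                m = simulate_hic(genome, truth, cond, config.compartment_resolution,
                                 seed=config.seed + 3000 + i)
                dens = dens100[: m.n_bins]
                profiles[cond] = compartment_pc1(balance_matrix(m), dens)
                mt = simulate_hic(genome, truth, cond, config.tad_resolution,
                                  seed=config.seed + 4000 + i)
                ins = insulation(balance_matrix(mt), config.insulation_window)
                partitions[cond] = call_borders(ins, config.prominence_min,
                                                chrom, config.tad_resolution,
                                                config.insulation_window)
            changes = {}
            for cond in conds[1:]:
                _, counts = classify_bin_changes(profiles[conds[0]], profiles[cond],
                                                 config.min_abs_pc1)
                changes[cond] = counts
            report["stages"]["compartments"] = {
                "changes_vs_" + conds[0]: changes,
                "n_bins": {c: len(profiles[c].pc1) for c in conds},
            }

            stage = "borders"
            conserved_bins, conserved_frac, _ = match_borders(
                list(partitions.values()), config.border_tol
            )
            occupancy = {
                c: border_peak_occupancy(partitions[c], peaksets[c], config.border_span)[1]
                for c in conds
            }
            enr = {}
            for c in conds:
                p, fold, obs, npk = border_enrichment_pvalue(
                    peaksets[c], partitions[c], genome,
                    border_span=config.border_span,
                )
                enr[c] = {"p_value": p, "fold": fold, "peaks_in_borders": obs,
                          "n_peaks": npk}
            report["stages"]["borders"] = {
                "n_borders": {c: len(partitions[c].borders) for c in conds},
                "conserved_fraction": conserved_frac,
                "n_conserved": len(conserved_bins),
                "occupancy": occupancy,
                "enrichment": enr,
            }

            stage = "integrate"
            res100 = config.compartment_resolution
            n100 = len(profiles[conds[0]].pc1)
            landmarks = {}
            base_prof = profiles[conds[0]]
            evaluated = ~np.isnan(base_prof.pc1)
            landmarks["A"] = base_prof.labels == "A"
            landmarks["B"] = base_prof.labels == "B"
            border_iv = {
                chrom: np.array(
                    [[max(b - config.border_span, 0) * config.tad_resolution,
                      (b + config.border_span + 1) * config.tad_resolution]
                     for b in partitions[conds[0]].border_bins()]
                ).reshape(-1, 2)
            }
            landmarks["border"] = binarize_feature(border_iv, chrom, n100, res100)
            features = {
                "laminB1_sites": {chrom: peaksets[conds[0]].intervals(chrom)},
                "eLADs": {chrom: elads[conds[0]].intervals(chrom)},
                "cLADs": genome.clads,
            }
            contingency = {}
            for fname, fiv in features.items():
                fbins = binarize_feature(fiv, chrom, n100, res100)
                contingency[fname] = {}
                for lname, lbins in landmarks.items():
                    try:
                        r = feature_landmark_log_odds(fbins, lbins, evaluated,
                                                      fname, lname)
                        contingency[fname][lname] = {
                            "log_odds": r.log_odds, "p_value": r.p_value,
                            "table": [r.a, r.b, r.c, r.d],
                        }
                    except ValueError as exc:
                        contingency[fname][lname] = {"error": str(exc)}
            report["stages"]["integrate"] = contingency
        else:
            report["stages"]["compartments"] = {"skipped": True}
            report["stages"]["borders"] = {"skipped": True}
            report["stages"]["integrate"] = {"skipped": True}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = _jsonify(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("report written to %s", outdir / "report.json")
    return report


REQUIRED_STAGES = ("call_sites", "expression", "elads", "dynamics",
                   "compartments", "borders", "integrate")


def validate_report(report: dict) -> None:
    """Schema check: required top-level keys and stages are present."""
    for key in ("version", "seed", "parameters", "stages"):
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
    for st in REQUIRED_STAGES:
        if st not in report["stages"]:
            raise ValueError(f"report missing stage {st!r}")
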