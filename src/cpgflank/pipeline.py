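"""End-to-end pipeline: simulate (or ingest) -> call -> stats -> words.

A :class:`PipelineConfig` captures every knob of a run (region source,
preference model, simulation parameters, analysis thresholds, output
directory, seed) and round-trips through YAML.  ``run_pipeline`` executes
the stages in order, writes every table as TSV/FASTA under the output
directory plus a JSON run log with stage-level counts, and is byte-identical
under a fixed config (every stochastic stage derives its seed from the
top-level seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, io, patterns, simulate, words

logger = logging.getLogger("cpgflank")


@dataclass
class PipelineConfig:
    """Plain-text configuration of one pipeline run."""

    # region: FASTA path, or generator parameters
    reference_fasta: str | None = None
    region_length: int = 500
    region_gc: float = 0.6
    region_min_cpg: int = 40

    # planted preference model
    profile: str = "3A-like"
    strength: float = 1.0
    baseline: float = -1.7
    flank_k: int = 2

    # simulation
    n_molecules: int = 100
    maintenance_efficiency: float = 0.95
    conversion_rate: float = 0.991
    inappropriate_conversion: float = 0.0
    dcm_plus_fraction: float = 0.5
    dnmt3l_exponent: float = 1.0  # > 1 adds a paired +DNMT3L run

    # analysis
    extreme_fraction: float = 0.10
    conversion_threshold: float = 0.95
    n_min: int = 10
    word_patterns: list[str] = field(default_factory=lambda: ["NTCGGN", "NGCGCN"])

    outdir: str = "cpgflank_run"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sim_params(config: PipelineConfig, exponent: float, seed: int) -> simulate.SimulationParams:
    return simulate.SimulationParams(
        n_molecules=config.n_molecules,
        maintenance_efficiency=config.maintenance_efficiency,
        dnmt3l_exponent=exponent,
        conversion_rate=config.conversion_rate,
        inappropriate_conversion=config.inappropriate_conversion,
        dcm_plus_fraction=config.dcm_plus_fraction,
        seed=seed,
    )


def _flank_analysis(
    region, matrix, config: PipelineConfig
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Per-strand extremes -> pooled oriented flanks -> hot/cold enrichment."""
    background = patterns.pooled_background(region, config.flank_k)
    hot_flanks: list[patterns.Flank] = []
    cold_flanks: list[patterns.Flank] = []
    for strand in ("top", "bottom"):
        table = patterns.rank_sites(
            patterns.site_efficiencies(matrix, strand=strand, n_min=config.n_min)
        )
        hot, cold = patterns.select_extremes(table, config.extreme_fraction, config.n_min)
        hot_flanks += patterns.extract_flanks(region, hot, strand, config.flank_k)
        cold_flanks += patterns.extract_flanks(region, cold, strand, config.flank_k)
    hot_oriented, _ = patterns.orient_flanks(hot_flanks)
    cold_oriented, _ = patterns.orient_flanks(cold_flanks)
    enr_hot = patterns.position_enrichment(hot_oriented, background)
    enr_cold = patterns.position_enrichment(cold_oriented, background)
    info = {
        "n_hot_flanks": len(hot_flanks),
        "n_cold_flanks": len(cold_flanks),
        "background": background,
    }
    return info, enr_hot, enr_cold


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all outputs under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name):
        logger.info("stage %s", name)
        report["stages"][name] = {}
        return report["stages"][name]

    try:
        info = stage("reference")
        if config.reference_fasta:
            records = io.read_fasta(config.reference_fasta)
            name, seq = records[0]
            region = simulate.ReferenceRegion.from_sequence(name, seq)
        else:
            region = simulate.generate_reference(
                config.region_length, config.region_gc, config.region_min_cpg,
                seed=config.seed, name="simulated_region",
            )
        io.write_fasta(outdir / "reference.fasta", [(region.name, region.sequence)])
        io.write_site_bed(region.cpg_sites, region.name, outdir / "cpg_sites.bed")
        info.update(n_cpg=region.n_cpg, length=len(region), name=region.name)
    except Exception as err:
        raise RuntimeError(f"stage 'reference' failed: {err}") from err

    model = simulate.build_preference_model(
        config.profile, config.strength, config.baseline, config.flank_k
    )
    runs = {"alone": 1.0}
    if config.dnmt3l_exponent > 1.0:
        runs["dnmt3l"] = config.dnmt3l_exponent

    matrices = {}
    for label, exponent in runs.items():
        try:
            info = stage(f"simulate_{label}")
            params = _sim_params(config, exponent, config.seed + (1 if label == "alone" else 2))
            molecules, truth = simulate.simulate_molecules(region, model, params)
            io.write_fasta(
                outdir / f"clones_{label}.fasta",
                [(m.fasta_header, m.read) for m in molecules],
            )
            io.write_tsv(truth["sites"], outdir / f"truth_sites_{label}.tsv")
            info.update(n_molecules=params.n_molecules, n_reads=len(molecules))
        except Exception as err:
            raise RuntimeError(f"stage 'simulate_{label}' failed: {err}") from err

        try:
            info = stage(f"call_{label}")
            reads = [(m.fasta_header, m.read) for m in molecules]
            matrix = calling.call_clones(
                reads, region, conversion_threshold=config.conversion_threshold
            )
            io.write_call_matrix(matrix, outdir / f"calls_{label}.tsv")
            matrices[label] = matrix
            info.update(
                reads_in=len(reads),
                called=len(matrix),
                passing=int(matrix.df["pass_filter"].sum()),
                filtered=int((~matrix.df["pass_filter"]).sum()),
                unparseable=len(reads) - len(matrix),
            )
            assert info["reads_in"] == info["called"] + info["unparseable"]
        except Exception as err:
            raise RuntimeError(f"stage 'call_{label}' failed: {err}") from err

    try:
        info = stage("site_stats")
        tables = {}
        for strand in ("top", "bottom"):
            table = patterns.rank_sites(
                patterns.site_efficiencies(
                    matrices["alone"], strand=strand, n_min=config.n_min
                )
            )
            io.write_tsv(table, outdir / f"site_efficiency_{strand}.tsv")
            tables[strand] = table
            info[f"overall_{strand}"] = table.attrs["overall"]
        sym = patterns.strand_symmetry(tables["top"], tables["bottom"])
        info["strand_symmetry_r"] = sym["r"]
        report["site_tables"] = tables
    except Exception as err:
        raise RuntimeError(f"stage 'site_stats' failed: {err}") from err

    try:
        info = stage("enrichment")
        flank_info, enr_hot, enr_cold = _flank_analysis(region, matrices["alone"], config)
        io.write_tsv(enr_hot, outdir / "enrichment_hot.tsv")
        io.write_tsv(enr_cold, outdir / "enrichment_cold.tsv")
        io.write_tsv(
            patterns.logo_matrix(enr_hot).reset_index(), outdir / "logo_hot.tsv"
        )
        io.write_tsv(
            patterns.logo_matrix(enr_cold).reset_index(), outdir / "logo_cold.tsv"
        )
        info.update(
            n_hot_flanks=flank_info["n_hot_flanks"],
            n_cold_flanks=flank_info["n_cold_flanks"],
        )
        report["enrichment_hot"] = enr_hot
        report["enrichment_cold"] = enr_cold
    except Exception as err:
        raise RuntimeError(f"stage 'enrichment' failed: {err}") from err

    if "dnmt3l" in matrices:
        try:
            info = stage("stimulation")
            alone = patterns.site_efficiencies(matrices["alone"], strand="top",
                                               n_min=config.n_min)
            with3l = patterns.site_efficiencies(matrices["dnmt3l"], strand="top",
                                                n_min=config.n_min)
            stim = patterns.fold_stimulation(alone, with3l)
            io.write_tsv(stim, outdir / "stimulation.tsv")
            info.update(
                trend_rho=stim.attrs["trend_rho"],
                fold_range_before=stim.attrs["fold_range_before"],
                fold_range_after=stim.attrs["fold_range_after"],
            )
            for dcm_class in ("dcm+", "dcm-"):
                try:
                    test = patterns.group_stimulation_test(
                        patterns.molecule_efficiencies(matrices["alone"], dcm_class=dcm_class),
                        patterns.molecule_efficiencies(matrices["dnmt3l"], dcm_class=dcm_class),
                    )
                    info[dcm_class] = {k: test[k] for k in ("pvalue", "stars",
                                                            "mean_alone", "mean_3l")}
                except ValueError as err:
                    warnings.warn(f"stimulation test skipped for {dcm_class}: {err}")
            report["stimulation"] = stim
        except Exception as err:
            raise RuntimeError(f"stage 'stimulation' failed: {err}") from err

    try:
        info = stage("words")
        rows = []
        for pattern in config.word_patterns:
            results, agg = words.scan_words(region.sequence, pattern)
            for r in results + [agg]:
                rows.append(
                    {
                        "pattern": pattern,
                        "word": r.word,
                        "observed": r.observed,
                        "expected": r.expected,
                        "sd": r.sd,
                        "score": r.score,
                        "pvalue": r.pvalue,
                    }
                )
        if rows:
            io.write_tsv(pd.DataFrame(rows), outdir / "words.tsv")
        metrics = words.island_metrics(region.sequence)
        info.update(
            gc_fraction=metrics.gc_fraction,
            obs_exp_cpg=metrics.obs_exp_cpg,
            is_island=metrics.is_island,
        )
    except Exception as err:
        raise RuntimeError(f"stage 'words' failed: {err}") from err

    run_log = {
        "config": dataclasses.asdict(config),
        "stages": report["stages"],
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=_jsonable))
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
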