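"""End-to-end runs: simulate -> DE -> persistence, simulate -> methylation stats.

A run is fully described by a :class:`RunConfig` (JSON-serializable) and is
deterministic given its seed: every output file is regenerated byte-identical
on a rerun, and the emitted report JSON contains the complete configuration,
so feeding a report back as a config reproduces the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .bsas import call_sites, test_sites, test_total, total_methylation
from .diffexp import call_degs
from .persistence import classify_persistence
from .simulate import (
    ExpressionScenario,
    MethylationScenario,
    make_amplicon,
    simulate_bisulfite_reads,
    simulate_counts,
    uniform_site_methylation,
    write_fastq,
)

__all__ = ["ConfigError", "DataError", "RunConfig",
           "run_expression_pipeline", "run_methylation_pipeline"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Inputs that fail validation at run time (CLI exit code 3)."""


@dataclass(frozen=True)
class RunConfig:
    """Thresholds plus scenario parameters for the two pipelines."""

    seed: int = 0
    alpha: float = 0.05
    fc_threshold: float = 1.25
    pseudocount: float = 0.5
    min_coverage: int = 1000
    max_mm: float = 0.1
    weighting: str = "site-mean"
    lenient: bool = False
    expression: Mapping | None = None
    methylation: Mapping | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.fc_threshold < 1:
            raise ConfigError("fc_threshold must be >= 1")
        if self.min_coverage < 1:
            raise ConfigError("min_coverage must be positive")
        if not 0 <= self.max_mm <= 1:
            raise ConfigError("max_mm must be in [0, 1]")
        if self.weighting not in ("site-mean", "read-weighted"):
            raise ConfigError("weighting must be 'site-mean' or 'read-weighted'")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        raw.pop("version", None)
        raw.pop("outputs", None)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _expression_scenario(config: RunConfig) -> ExpressionScenario:
    params = dict(config.expression or {})
    params.setdefault("seed", config.seed)
    try:
        return ExpressionScenario(**{
            **params,
            "groups": tuple(params.get("groups", ("AL", "DR", "DR-AL"))),
            "library_size_per_group": tuple(
                params.get("library_size_per_group", (30_000_000,) * 3)),
        })
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid expression scenario: {exc}") from exc


def run_expression_pipeline(config: RunConfig, outdir) -> dict:
    """Simulate pooled counts, call DEGs for both diet contrasts, classify
    persistence, and write all tables plus a rerunnable JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc = _expression_scenario(config)

    table, truth = simulate_counts(sc)
    table.to_tsv(outdir / "counts.tsv", outdir / "totals.json")
    truth.to_json(outdir / "truth.json")

    al, dr, dral = sc.groups
    deg_dr = call_degs(table, (al, dr), alpha=config.alpha,
                       fc_threshold=config.fc_threshold,
                       pseudocount=config.pseudocount)
    deg_dral = call_degs(table, (al, dral), alpha=config.alpha,
                         fc_threshold=config.fc_threshold,
                         pseudocount=config.pseudocount)
    deg_dr.to_tsv(outdir / f"deg_{dr}_vs_{al}.tsv")
    deg_dral.to_tsv(outdir / f"deg_{dral}_vs_{al}.tsv")

    summary = classify_persistence(deg_dr, deg_dral, lenient=config.lenient)
    _write_json(summary.to_dict(), outdir / "persistence.json")
    for cat in ("persist_up", "persist_down", "new_up", "new_down"):
        genes = sorted(getattr(summary, cat))
        pd.Series(genes, name="gene").to_csv(
            outdir / f"genes_{cat}.tsv", sep="\t", index=False)

    report = {
        "pipeline": "expression",
        "version": __version__,
        "config": config.to_dict(),
        "scenario": asdict(sc),
        "n_genes_tested": int(deg_dr.table["tested"].sum()),
        "persistence": {
            "n_up_DR": summary.n_up_dr,
            "n_down_DR": summary.n_down_dr,
            "n_persist_up": summary.n_persist_up,
            "n_persist_down": summary.n_persist_down,
        },
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    _write_json(report, outdir / "report.json")
    return report


def _methylation_scenario(config: RunConfig) -> MethylationScenario:
    params = dict(config.methylation or {})
    try:
        length = params["amplicon_length"]
        cg_positions = params["cg_positions"]
        cg_meth = params["group_cg_methylation"]
        ch_meth = params.get(
            "group_ch_methylation", {g: 0.02 for g in cg_meth})
    except KeyError as exc:
        raise ConfigError(f"methylation config missing {exc}") from exc
    try:
        amp = make_amplicon(length, cg_positions, seed=params.get(
            "amplicon_seed", config.seed), name=params.get("name", "amplicon"))
        site_meth = {}
        for group in cg_meth:
            cg_level = cg_meth[group]
            ch_level = ch_meth.get(group, 0.02)
            fracs = list(uniform_site_methylation(amp, cg_level, ch_level))
            for off_str, value in params.get(
                    "site_overrides", {}).get(group, {}).items():
                offsets = [s.offset for s in amp.sites]
                fracs[offsets.index(int(off_str))] = value
            site_meth[group] = tuple(fracs)
        return MethylationScenario(
            amplicon=amp,
            group_site_methylation=site_meth,
            depth=params.get("depth", 2000),
            conversion_efficiency=params.get("conversion_efficiency", 1.0),
            base_error_rate=params.get("base_error_rate", 0.0),
            n_samples_per_group=params.get("n_samples_per_group", 5),
            seed=params.get("seed", config.seed),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid methylation scenario: {exc}") from exc


def run_methylation_pipeline(config: RunConfig, outdir) -> dict:
    """Simulate bisulfite amplicon reads, call per-site methylation, and run
    total (ANOVA + Tukey) and per-site (ANOVA + BH) group statistics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc = _methylation_scenario(config)

    sc.amplicon.to_fasta(outdir / "amplicon.fasta")
    sc.amplicon.sites_to_json(outdir / "sites.json")
    reads_by_sample, truth = simulate_bisulfite_reads(sc)
    _write_json(truth, outdir / "truth.json")
    fastq_dir = outdir / "fastq"
    fastq_dir.mkdir(exist_ok=True)
    sheet_rows = []
    for group, samples in truth["samples_by_group"].items():
        for sample in samples:
            path = fastq_dir / f"{sample}.fastq"
            write_fastq(reads_by_sample[sample], path, sample=sample,
                        quality_char=sc.quality_char)
            sheet_rows.append((sample, group, str(path.relative_to(outdir))))
    pd.DataFrame(sheet_rows, columns=["sample", "group", "fastq"]).to_csv(
        outdir / "samplesheet.tsv", sep="\t", index=False)

    matrices = {}
    for group, samples in truth["samples_by_group"].items():
        matrices[group] = call_sites(
            {s: reads_by_sample[s] for s in samples}, sc.amplicon,
            min_coverage=config.min_coverage, max_mm=config.max_mm)
    combined = call_sites(reads_by_sample, sc.amplicon,
                          min_coverage=config.min_coverage,
                          max_mm=config.max_mm)
    combined.to_tsv(outdir / "site_calls.tsv")

    stats_report: dict = {"total": {}, "sites": None}
    for context in ("CG", "CH"):
        try:
            totals = {g: total_methylation(m, context, config.weighting).to_numpy()
                      for g, m in matrices.items()}
        except ValueError:
            continue  # no covered sites of this context
        res = test_total(totals, context=context)
        stats_report["total"][context] = res.to_dict()

    site_res = test_sites(matrices, alpha=config.alpha)
    site_res.to_tsv(outdir / "site_stats.tsv")
    _write_bed(site_res, sc.amplicon.name, outdir / "site_stats.bed")
    stats_report["sites"] = {
        "n_tested": int(len(site_res.table)),
        "flagged_CG": site_res.flagged_offsets("CG"),
        "flagged_CH": site_res.flagged_offsets("CH"),
    }
    _write_json(stats_report, outdir / "stats.json")

    report = {
        "pipeline": "methylation",
        "version": __version__,
        "config": config.to_dict(),
        "amplicon": {"name": sc.amplicon.name, "length": len(sc.amplicon),
                     "n_cg": len(sc.amplicon.cg_offsets),
                     "n_ch": len(sc.amplicon.ch_offsets)},
        "stats": stats_report,
        "outputs": sorted(str(p.relative_to(outdir))
                          for p in outdir.rglob("*") if p.is_file()),
    }
    _write_json(report, outdir / "report.json")
    return report


def _write_bed(site_res, chrom: str, path: Path) -> None:
    """BED-like track of per-site results in amplicon-local coordinates."""
    with open(path, "w") as fh:
        for _, row in site_res.table.iterrows():
            off = int(row["offset"])
            name = f"{row['context']}_q{row['q']:.4g}"
            score = int(min(1000, round(-10 * _log10(row["q"]))))
            fh.write(f"{chrom}\t{off}\t{off + 1}\t{name}\t{score}\n")


def _log10(q: float) -> float:
    import math

    return math.log10(q) if q > 0 else -30.0
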