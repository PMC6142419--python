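"""End-to-end QC runs: simulate or ingest VCFs, filter, then compute
replicate concordance, het-AF SNR and CNA calls into one report.

Stages are pure with respect to each other: each consumes the filtered
replicates and writes only into the report, so any stage can fail (e.g.
a single replicate per cell count makes concordance unavailable) while
the others still run.  A (config, seed) pair fully determines the JSON
report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .af_statistics import compute_snr, het_af_values, snr_trend, test_normality
from .cna_imbalance import CNAConfig, call_segments
from .errors import ConfigError, SparseCellQCError, UndefinedStatisticError
from .replicate_concordance import (
    compare_str,
    fit_exponential,
    genotype_likelihood_correlation,
    mismatch_curve,
    mismatch_fraction,
    read_reference_variants,
    variant_set_overlap,
)
from .synthetic_data import (
    SimulationConfig,
    read_str_table,
    write_fixture_set,
)
from .variant_io import (
    AssayReplicate,
    RegionSet,
    filter_depth,
    filter_pass,
    read_vcf,
    restrict_to_regions,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mode: str = "simulate"  # "simulate" | "analyze"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    vcf_paths: list[str] = field(default_factory=list)
    str_tables: list[str] = field(default_factory=list)
    str_reference: str | None = None
    reference_variants: str | None = None
    regions_bed: str | None = None
    min_depth: int = 30
    neutral_chromosomes: list[str] = field(default_factory=lambda: ["chr2", "chr3"])
    str_ratio_threshold: float = 3.0
    cna: CNAConfig = field(default_factory=CNAConfig)
    out_dir: str = "sparsecellqc_out"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("simulate", "analyze"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "analyze":
            missing = [p for p in self.vcf_paths if not Path(p).exists()]
            if missing:
                raise ConfigError(f"input VCFs not found: {missing}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "cna" in d and isinstance(d["cna"], dict):
            cna = dict(d["cna"])
            if "mid_band" in cna:
                cna["mid_band"] = tuple(cna["mid_band"])
            d["cna"] = CNAConfig(**cna)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    d = dataclasses.asdict(config)
    d.pop("out_dir", None)  # output location is not analysis configuration
    blob = json.dumps(d, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(config: RunConfig) -> dict:
    """Execute a full QC run and return the report as a plain dict.

    Report sections: ``concordance`` (per-cell-count mismatch summaries
    + exponential fit + genotype-likelihood correlations),
    ``snr`` (per-replicate het-AF statistics + log-linear trend),
    ``str_dropout``, ``cna_calls``, ``overlap`` and a ``provenance``
    block.  Sections whose inputs are unavailable carry an
    ``"unavailable"`` marker instead of numbers.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "provenance": {
            "package_version": __version__,
            "mode": config.mode,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "min_depth": config.min_depth,
            "neutral_chromosomes": config.neutral_chromosomes,
        }
    }

    str_tables: dict[tuple[int, int], list] = {}
    str_reference = None
    if config.mode == "simulate":
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        manifest = write_fixture_set(sim, out_dir / "fixtures")
        vcf_paths = list(manifest["vcfs"].values())
        str_reference = read_str_table(manifest["str_reference"])
        str_tables = {k: read_str_table(p) for k, p in manifest["str_tables"].items()}
    else:
        vcf_paths = list(config.vcf_paths)
        if config.str_reference:
            str_reference = read_str_table(config.str_reference)
            for p in config.str_tables:
                str_tables[(None, len(str_tables))] = read_str_table(p)

    replicates = [read_vcf(p) for p in vcf_paths]
    regions = RegionSet.from_bed(config.regions_bed) if config.regions_bed else None
    filtered: list[AssayReplicate] = []
    for rep in replicates:
        r = filter_pass(rep)
        if regions is not None:
            r = restrict_to_regions(r, regions)
        filtered.append(r)

    by_count: dict[int, list[AssayReplicate]] = {}
    for rep in filtered:
        if rep.cell_count is None:
            logger.warning("replicate %s has no cell count; concordance skipped for it", rep.sample_id)
            continue
        by_count.setdefault(rep.cell_count, []).append(rep)

    report["concordance"] = _concordance_section(by_count)
    report["snr"] = _snr_section(by_count, config)
    report["str_dropout"] = _str_section(str_reference, str_tables, config)
    report["cna_calls"] = _cna_section(by_count, config)
    report["overlap"] = _overlap_section(filtered, config)
    return report


def _concordance_section(by_count) -> dict:
    pairs = []
    for cc, reps in sorted(by_count.items()):
        for i in range(0, len(reps) - 1, 2):
            pairs.append((reps[i], reps[i + 1]))
    if not pairs:
        return {"unavailable": "need two replicates per cell count"}
    summaries = []
    correlations = []
    for a, b in pairs:
        try:
            summaries.append(mismatch_fraction(a, b).as_dict())
        except UndefinedStatisticError as exc:
            logger.warning("mismatch unavailable for %s/%s: %s", a.sample_id, b.sample_id, exc)
        try:
            rho, n = genotype_likelihood_correlation(a, b)
            correlations.append({"cell_count": a.cell_count, "spearman_rho": rho, "n_shared": n})
        except UndefinedStatisticError:
            pass
    section: dict = {"summaries": summaries, "gl_correlations": correlations}
    if len({s["cell_count"] for s in summaries}) >= 3:
        curve = mismatch_curve(pairs)
        fit = fit_exponential(curve)
        section["curve"] = [{"cell_count": c, "mismatch_fraction": f} for c, f in curve]
        section["exponential_fit"] = {
            "amplitude": fit.amplitude,
            "decay_rate": fit.decay_rate,
            "floor": fit.floor,
            "r_squared": fit.r_squared,
        }
    return section


def _snr_section(by_count, config: RunConfig) -> dict:
    rows = []
    trend_points = []
    for cc, reps in sorted(by_count.items()):
        for rep in reps:
            vals = het_af_values(rep, config.neutral_chromosomes, min_depth=config.min_depth)
            if vals.size < 2:
                continue
            stats = compute_snr(vals, chromosomes=config.neutral_chromosomes)
            row = {"sample": rep.sample_id, "cell_count": cc}
            try:
                ad_stat, ad_pass = test_normality(vals)
                stats.anderson_darling_statistic = ad_stat
                stats.normality_pass = ad_pass
            except UndefinedStatisticError:
                pass
            row.update(stats.as_dict())
            rows.append(row)
            trend_points.append((cc, stats.snr))
    if not rows:
        return {"unavailable": "no heterozygous VAFs on the designated neutral chromosomes"}
    section: dict = {"per_replicate": rows}
    if len({c for c, _ in trend_points}) >= 3:
        trend = snr_trend(trend_points)
        section["trend"] = {
            "slope": trend.slope,
            "intercept": trend.intercept,
            "r_squared": trend.r_squared,
            "snr_ratio_extremes": trend.snr_ratio_extremes,
        }
    return section


def _str_section(reference, str_tables, config: RunConfig) -> dict:
    if reference is None or not str_tables:
        return {"unavailable": "no STR tables provided"}
    rows = []
    for key, panel in sorted(str_tables.items(), key=lambda kv: str(kv[0])):
        comparisons, affected = compare_str(
            reference, panel, imbalance_ratio_threshold=config.str_ratio_threshold
        )
        cc = key[0] if isinstance(key, tuple) else None
        rows.append(
            {
                "assay": str(key),
                "cell_count": cc,
                "affected_loci": affected,
                "n_loci": len(comparisons),
                "by_status": {
                    s.value: sum(1 for c in comparisons if c.status is s)
                    for s in {c.status for c in comparisons}
                },
            }
        )
    return {"per_assay": rows}


def _cna_section(by_count, config: RunConfig) -> dict:
    rows = []
    for cc, reps in sorted(by_count.items()):
        group = reps[:2] if len(reps) >= 2 else reps[0]
        chroms = sorted(
            {c for rep in (group if isinstance(group, list) else [group]) for c in rep.chromosomes()},
        )
        try:
            calls = call_segments(
                group, chroms, config.neutral_chromosomes, config=config.cna
            )
        except SparseCellQCError as exc:
            logger.warning("CNA calling unavailable at %d cells: %s", cc, exc)
            continue
        for c in calls:
            rows.append(
                {
                    "cell_count": cc,
                    "chrom": c.chrom,
                    "start_pos": c.start_pos,
                    "end_pos": c.end_pos,
                    "call": c.call,
                    "n_variants": c.n_variants,
                    "evidence": c.evidence,
                }
            )
    return {"calls": rows}


def _overlap_section(filtered, config: RunConfig) -> dict:
    if not config.reference_variants:
        return {"unavailable": "no reference variant list provided"}
    reference = read_reference_variants(config.reference_variants)
    rows = []
    for rep in filtered:
        try:
            res = variant_set_overlap(rep, reference)
        except UndefinedStatisticError as exc:
            return {"unavailable": str(exc)}
        rows.append(
            {
                "sample": rep.sample_id,
                "cell_count": rep.cell_count,
                "reference_size": res.reference_size,
                "intersection": res.intersection,
                "overlap_fraction": res.overlap_fraction,
            }
        )
    return {"per_replicate": rows}


# ---------------------------------------------------------------------------
# rendering


def render_report(report: dict, fmt: str, out_dir) -> list[Path]:
    """Serialise a report. ``json`` is canonical and lossless; the
    ``tsv-bundle`` writes one file per table; ``markdown`` is a
    human-readable summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path = out_dir / "qc_report.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        return [path]
    if fmt == "tsv-bundle":
        return _render_tsv(report, out_dir)
    if fmt == "markdown":
        path = out_dir / "qc_report.md"
        path.write_text(_render_markdown(report))
        return [path]
    raise ValueError(f"unknown report format {fmt!r}")


def _render_tsv(report: dict, out_dir: Path) -> list[Path]:
    import pandas as pd

    written = []
    tables = {
        "mismatch": report.get("concordance", {}).get("summaries"),
        "gl_correlation": report.get("concordance", {}).get("gl_correlations"),
        "snr": report.get("snr", {}).get("per_replicate"),
        "str_dropout": report.get("str_dropout", {}).get("per_assay"),
        "cna_calls": report.get("cna_calls", {}).get("calls"),
        "overlap": report.get("overlap", {}).get("per_replicate"),
    }
    for name, rows in tables.items():
        if not rows:
            continue
        path = out_dir / f"{name}.tsv"
        pd.json_normalize(rows).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def _render_markdown(report: dict) -> str:
    lines = ["# sparse-cell sequencing QC report", ""]
    prov = report.get("provenance", {})
    lines.append(f"seed: {prov.get('seed')} | config: {prov.get('config_hash')} | "
                 f"version: {prov.get('package_version')}")
    conc = report.get("concordance", {})
    if "summaries" in conc:
        lines += ["", "## Replicate allelic mismatch", "",
                  "| cells | sites | mismatch | loh | allele_change | total_dropout |",
                  "|---|---|---|---|---|---|"]
        for s in conc["summaries"]:
            lines.append(
                f"| {s['cell_count']} | {s['n_sites']} | {s['mismatch_fraction']:.3f} "
                f"| {s['loh']} | {s['allele_change']} | {s['total_dropout']} |"
            )
        if "exponential_fit" in conc:
            f = conc["exponential_fit"]
            lines.append(
                f"\nexponential fit: {f['amplitude']:.3f}*exp(-{f['decay_rate']:.3f}x)"
                f" + {f['floor']:.3f} (R^2 = {f['r_squared']:.3f})"
            )
    snr = report.get("snr", {})
    if "per_replicate" in snr:
        lines += ["", "## Heterozygous allele-frequency SNR", "",
                  "| sample | cells | n | mu | sigma | SNR | CV | AD pass |",
                  "|---|---|---|---|---|---|---|---|"]
        for r in snr["per_replicate"]:
            lines.append(
                f"| {r['sample']} | {r['cell_count']} | {r['n']} | {r['mean']:.3f} "
                f"| {r['std']:.3f} | {r['snr']:.2f} | {r['cv']:.3f} | {r['normality_pass']} |"
            )
        if "trend" in snr:
            t = snr["trend"]
            lines.append(
                f"\nlog-linear trend: SNR = {t['slope']:.2f}*ln(cells) + {t['intercept']:.2f} "
                f"(R^2 = {t['r_squared']:.3f}); SNR ratio max/min cells = "
                f"{t['snr_ratio_extremes']:.2f}"
            )
    cna = report.get("cna_calls", {})
    if cna.get("calls"):
        lines += ["", "## CNA calls from allelic imbalance", "",
                  "| cells | chrom | span | call | variants |", "|---|---|---|---|---|"]
        for c in cna["calls"]:
            lines.append(
                f"| {c['cell_count']} | {c['chrom']} | {c['start_pos']}-{c['end_pos']} "
                f"| {c['call']} | {c['n_variants']} |"
            )
    strd = report.get("str_dropout", {})
    if "per_assay" in strd:
        lines += ["", "## STR dropout", "", "| assay | affected loci / total |", "|---|---|"]
        for r in strd["per_assay"]:
            lines.append(f"| {r['assay']} | {r['affected_loci']} / {r['n_loci']} |")
    return "\n".join(lines) + "\n"
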