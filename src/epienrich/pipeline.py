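"""End-to-end orchestration of the three analysis phases.

Given one or two cohorts, the pipeline runs the exhaustive pairwise MDR scan
(Phase I) with its permutation null, maps SNPs to genes and tests per-gene
SNP overabundance (Phase II), tests gene-set overabundance (Phase III), and
— when a replication cohort is supplied — reports the genes and sets
significant in both cohorts.  Every stage writes its TSV so any phase can be
re-run in isolation; a JSON run report captures the config, per-stage counts
and wall time.  With a fixed config and seed the result tables are
byte-identical across runs (only report timing fields differ).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .enrichment import (
    gene_enrichment,
    map_snps_to_genes,
    replicate,
    set_enrichment,
)
from .io import (
    read_bed_genes,
    read_genotypes,
    read_gmt,
    read_snp_map,
    write_results_table,
    write_snp_pvalues,
)
from .mdr import pairwise_scan
from .permutation import attach_pair_pvalues, assign_snp_pvalues, build_null
from .types import CohortData, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and knobs for one pipeline run (TOML- and flag-loadable)."""

    detection_genotypes: str = ""
    replication_genotypes: Optional[str] = None
    genotype_dialect: str = "tsv"
    snp_map: Optional[str] = None
    snp_map_dialect: str = "map"
    genes_bed: str = ""
    sets_gmt: str = ""
    n_permutations: int = 1000
    null_mode: str = "pooled"
    window: int = 500_000
    alpha: float = 0.05
    maf_min: float = 0.0
    seed: int = 0
    out_dir: str = "epienrich_out"

    @classmethod
    def from_toml(cls, path: str, **overrides) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return one problem string per violated precondition (empty = runnable)."""
    problems: list[str] = []

    def _readable(path: Optional[str], name: str, required: bool) -> None:
        if not path:
            if required:
                problems.append(f"{name}: path is required")
            return
        if not Path(path).is_file():
            problems.append(f"{name}: {path!r} is not a readable file")

    _readable(config.detection_genotypes, "detection_genotypes", required=True)
    if config.replication_genotypes is not None:
        _readable(config.replication_genotypes, "replication_genotypes", required=True)
    _readable(config.snp_map, "snp_map", required=False)
    _readable(config.genes_bed, "genes_bed", required=True)
    _readable(config.sets_gmt, "sets_gmt", required=True)
    if config.genotype_dialect not in ("tsv", "plink_raw"):
        problems.append(f"genotype_dialect: unknown dialect {config.genotype_dialect!r}")
    if config.snp_map_dialect not in ("bim", "map", "tsv"):
        problems.append(f"snp_map_dialect: unknown dialect {config.snp_map_dialect!r}")
    if config.n_permutations < 1:
        problems.append("n_permutations: must be >= 1")
    if config.null_mode not in ("pooled", "max"):
        problems.append(f"null_mode: must be 'pooled' or 'max', got {config.null_mode!r}")
    if config.window < 0:
        problems.append("window: must be >= 0")
    if not 0 < config.alpha < 1:
        problems.append("alpha: must lie in (0, 1)")
    if not 0 <= config.maf_min <= 0.5:
        problems.append("maf_min: must lie in [0, 0.5]")
    return problems


def _analyse_cohort(
    cohort: CohortData, config: PipelineConfig, out: Path, tag: str, report: dict
) -> tuple[dict[str, float], list, list]:
    """Phase I–III for one cohort; returns (snp p-values, gene results, set results)."""
    t0 = time.perf_counter()
    logger.info("[%s] Phase I: exhaustive pairwise MDR scan (%d SNPs, %d samples)",
                tag, cohort.n_snps, cohort.n_samples)
    pairs = pairwise_scan(cohort, maf_min=config.maf_min)
    null = build_null(
        cohort,
        n_permutations=config.n_permutations,
        mode=config.null_mode,
        seed=config.seed,
    )
    attach_pair_pvalues(pairs, null)
    write_results_table(pairs, out / f"pairs_{tag}.tsv")
    snp_p = assign_snp_pvalues(pairs)
    write_snp_pvalues(snp_p, out / f"snp_pvalues_{tag}.tsv")

    logger.info("[%s] Phase II: SNP->gene mapping (window %d bp) and gene enrichment",
                tag, config.window)
    genes = read_bed_genes(config.genes_bed)
    mapping = map_snps_to_genes(cohort.snps, genes, window=config.window)
    gene_res = gene_enrichment(mapping, snp_p, genes, alpha=config.alpha)
    write_results_table(gene_res, out / f"gene_enrichment_{tag}.tsv")

    logger.info("[%s] Phase III: gene-set enrichment", tag)
    sets = read_gmt(config.sets_gmt)
    gene_p = {r.entity_id: r.p_value for r in gene_res}
    set_res = set_enrichment(sets, gene_p, alpha=config.alpha)
    write_results_table(set_res, out / f"set_enrichment_{tag}.tsv")

    report["cohorts"][tag] = {
        "n_samples": cohort.n_samples,
        "n_cases": cohort.n_cases,
        "n_controls": cohort.n_controls,
        "n_snps": cohort.n_snps,
        "n_pairs": len(pairs),
        "null_size": null.size,
        "n_snps_with_p": len(snp_p),
        "n_snps_significant": sum(1 for p in snp_p.values() if p <= config.alpha),
        "n_genes": len(gene_res),
        "n_genes_significant": sum(1 for r in gene_res if r.p_value <= config.alpha),
        "n_sets": len(set_res),
        "n_sets_significant": sum(1 for r in set_res if r.p_value <= config.alpha),
        "wall_seconds": round(time.perf_counter() - t0, 3),
    }
    return snp_p, gene_res, set_res


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all phases per cohort, then replication when two cohorts are given.

    Returns the run report (also written to ``<out_dir>/report.json``).  Any
    stage failure aborts with the stage name; a MANIFEST file lists which
    outputs were completed.
    """
    problems = validate_config(config)
    if problems:
        raise ValidationError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snps = (
        read_snp_map(config.snp_map, dialect=config.snp_map_dialect)
        if config.snp_map
        else None
    )
    report: dict = {
        "tool": "epienrich",
        "version": __version__,
        "config": asdict(config),
        "cohorts": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest: list[str] = []
    stage = "read detection cohort"
    try:
        detection = read_genotypes(
            config.detection_genotypes,
            dialect=config.genotype_dialect,
            snps=snps,
            cohort_id="detection",
        )
        stage = "detection analysis"
        det_snp_p, det_genes, det_sets = _analyse_cohort(
            detection, config, out, "detection", report
        )
        manifest += [
            f"pairs_detection.tsv",
            f"snp_pvalues_detection.tsv",
            f"gene_enrichment_detection.tsv",
            f"set_enrichment_detection.tsv",
        ]
        if config.replication_genotypes:
            stage = "read replication cohort"
            replication = read_genotypes(
                config.replication_genotypes,
                dialect=config.genotype_dialect,
                snps=snps,
                cohort_id="replication",
            )
            stage = "replication analysis"
            rep_snp_p, rep_genes, rep_sets = _analyse_cohort(
                replication, config, out, "replication", report
            )
            manifest += [
                f"pairs_replication.tsv",
                f"snp_pvalues_replication.tsv",
                f"gene_enrichment_replication.tsv",
                f"set_enrichment_replication.tsv",
            ]
            stage = "replication comparison"
            rep_gene_hits = replicate(det_genes, rep_genes, alpha=config.alpha)
            rep_set_hits = replicate(det_sets, rep_sets, alpha=config.alpha)
            _write_replicated(rep_gene_hits, out / "replicated_genes.tsv")
            _write_replicated(rep_set_hits, out / "replicated_sets.tsv")
            manifest += ["replicated_genes.tsv", "replicated_sets.tsv"]
            report["replicated_genes"] = [
                {"entity_id": e, "p_detection": pd, "p_replication": pr}
                for e, pd, pr in rep_gene_hits
            ]
            report["replicated_sets"] = [
                {"entity_id": e, "p_detection": pd, "p_replication": pr}
                for e, pd, pr in rep_set_hits
            ]
    except Exception as exc:
        (out / "MANIFEST").write_text(
            "\n".join(manifest + [f"INCOMPLETE: failed at stage '{stage}': {exc}"]) + "\n"
        )
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    report["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "MANIFEST").write_text("\n".join(manifest + ["report.json"]) + "\n")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _write_replicated(hits: list[tuple[str, float, float]], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("entity_id\tp_detection\tp_replication\n")
        for eid, pd, pr in hits:
            fh.write(f"{eid}\t{pd:.12e}\t{pr:.12e}\n")
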