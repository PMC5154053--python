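"""Readers and writers for the file formats the pipeline touches.

Dialects
--------
* plain TSV genotype matrix: header ``sample_id  phenotype  rs1  rs2 ...``,
  one sample per row, genotype codes 0/1/2 or NA, phenotype in {0,1} (0 =
  control) or {1,2} (PLINK-style, 1 = control, 2 = case).
* PLINK ``.raw`` (``--recode A``): header ``FID IID PAT MAT SEX PHENOTYPE
  snp1_A snp2_C ...``; phenotype 1 = control, 2 = case, 0/-9 = missing
  (samples with missing phenotype are dropped and counted in the log).
* PLINK ``.bim`` / ``.map`` and a headered TSV dialect for SNP maps.
* BED (3 columns + name) for gene regions — half-open 0-based coordinates
  are converted to the 1-based inclusive convention used internally.
* GMT for gene sets, and TSV result tables for pair/enrichment results.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .types import (
    MISSING,
    CohortData,
    EnrichmentResult,
    GeneRegion,
    GeneSet,
    PairResult,
    SnpRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_MISSING_TOKENS = {"na", "nan", "n/a", ".", "-9", ""}


class ParseError(ValueError):
    """A file could not be parsed under the named dialect."""

    def __init__(self, path: PathLike, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


def _parse_genotype(token: str, path: PathLike, line_no: int) -> int:
    t = token.strip()
    if t.lower() in _MISSING_TOKENS:
        return MISSING
    if t in ("0", "1", "2"):
        return int(t)
    raise ParseError(path, line_no, f"genotype code {token!r} outside {{0,1,2,NA}}")


def _check_unique_snp_ids(ids: Sequence[str], path: PathLike) -> None:
    seen: set[str] = set()
    for sid in ids:
        if sid in seen:
            raise ValidationError(f"{path}: duplicate snp_id {sid!r}")
        seen.add(sid)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def read_genotypes(
    path: PathLike,
    dialect: str = "tsv",
    snps: Sequence[SnpRecord] | None = None,
    cohort_id: str | None = None,
) -> CohortData:
    """Read a case–control genotype matrix into a :class:`CohortData`.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"tsv"`` or ``"plink_raw"`` (see module docstring).
    snps
        Optional SNP map to attach; must match the file's SNP ids in order.
        When omitted, placeholder records (chrom "0", pos = column index + 1)
        are attached so the matrix is usable for Phase I alone.
    """
    if dialect == "tsv":
        sample_ids, phenotype, snp_ids, G = _read_genotypes_tsv(path)
    elif dialect == "plink_raw":
        sample_ids, phenotype, snp_ids, G = _read_genotypes_raw(path)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    _check_unique_snp_ids(snp_ids, path)
    if snps is not None:
        if [s.snp_id for s in snps] != list(snp_ids):
            raise ValidationError(
                f"{path}: SNP map does not match file header SNP ids (order-sensitive)"
            )
        records = list(snps)
    else:
        records = [SnpRecord(sid, "0", j + 1) for j, sid in enumerate(snp_ids)]
    return CohortData(
        genotypes=G,
        phenotype=phenotype,
        snps=records,
        cohort_id=cohort_id or Path(path).stem,
        sample_ids=sample_ids,
    )


def _map_phenotype_column(raw: list[str], path: PathLike) -> tuple[np.ndarray, list[int]]:
    """Map file phenotype tokens to internal 0/1; return (codes, missing rows)."""
    vals = [v.strip() for v in raw]
    missing_rows = [i for i, v in enumerate(vals) if v.lower() in ("-9", "0na", "na", "")]
    present = {v for i, v in enumerate(vals) if i not in missing_rows}
    if present <= {"0", "1"}:
        coding = {"0": 0, "1": 1}
    elif present <= {"1", "2"}:
        coding = {"1": 0, "2": 1}  # PLINK: 1=control, 2=case
    else:
        raise ValidationError(
            f"{path}: phenotype values {sorted(present)} are neither 0/1 nor 1/2 coded"
        )
    codes = np.array(
        [coding[v] if i not in missing_rows else 255 for i, v in enumerate(vals)],
        dtype=np.uint8,
    )
    return codes, missing_rows


def _read_genotypes_tsv(path: PathLike):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(path, 1, "empty genotype file")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 3 or header[0] != "sample_id" or header[1] != "phenotype":
        raise ParseError(
            path, 1, "TSV genotype header must start with 'sample_id\\tphenotype'"
        )
    snp_ids = header[2:]
    sample_ids: list[str] = []
    pheno_raw: list[str] = []
    rows: list[list[int]] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                path, ln, f"expected {len(header)} fields, found {len(parts)}"
            )
        sample_ids.append(parts[0])
        pheno_raw.append(parts[1])
        rows.append([_parse_genotype(t, path, ln) for t in parts[2:]])
    phenotype, missing_rows = _map_phenotype_column(pheno_raw, path)
    if missing_rows:
        logger.info("%s: dropped %d samples with missing phenotype", path, len(missing_rows))
        keep = [i for i in range(len(sample_ids)) if i not in set(missing_rows)]
        sample_ids = [sample_ids[i] for i in keep]
        phenotype = phenotype[keep]
        rows = [rows[i] for i in keep]
    G = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(snp_ids)), np.int8)
    return sample_ids, phenotype, snp_ids, G


def _strip_allele_suffix(col: str) -> str:
    """PLINK .raw columns are '<snp>_<counted allele>'; strip the suffix."""
    if "_" in col:
        stem, suffix = col.rsplit("_", 1)
        if len(suffix) == 1:
            return stem
    return col


def _read_genotypes_raw(path: PathLike):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(path, 1, "empty .raw file")
    header = lines[0].split()
    fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if header[: len(fixed)] != fixed:
        raise ParseError(path, 1, f".raw header must start with {' '.join(fixed)}")
    snp_ids = [_strip_allele_suffix(c) for c in header[len(fixed) :]]
    if not snp_ids:
        raise ParseError(path, 1, ".raw file contains no SNP columns")
    sample_ids: list[str] = []
    pheno_raw: list[str] = []
    rows: list[list[int]] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != len(header):
            raise ParseError(
                path, ln, f"expected {len(header)} fields, found {len(parts)}"
            )
        sample_ids.append(f"{parts[0]}:{parts[1]}")
        pheno_raw.append(parts[5])
        rows.append([_parse_genotype(t, path, ln) for t in parts[6:]])
    phenotype, missing_rows = _map_phenotype_column(pheno_raw, path)
    if missing_rows:
        logger.info("%s: dropped %d samples with missing phenotype", path, len(missing_rows))
        keep = [i for i in range(len(sample_ids)) if i not in set(missing_rows)]
        sample_ids = [sample_ids[i] for i in keep]
        phenotype = phenotype[keep]
        rows = [rows[i] for i in keep]
    G = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(snp_ids)), np.int8)
    return sample_ids, phenotype, snp_ids, G


def write_genotypes_tsv(cohort: CohortData, path: PathLike) -> None:
    """Write a cohort in the plain TSV dialect (inverse of ``dialect='tsv'``)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tphenotype\t" + "\t".join(cohort.snp_ids) + "\n")
        for i in range(cohort.n_samples):
            row = cohort.genotypes[i]
            codes = ["NA" if g == MISSING else str(int(g)) for g in row]
            fh.write(
                f"{cohort.sample_ids[i]}\t{int(cohort.phenotype[i])}\t" + "\t".join(codes) + "\n"
            )


# ---------------------------------------------------------------------------
# SNP maps
# ---------------------------------------------------------------------------


def read_snp_map(path: PathLike, dialect: str = "bim") -> list[SnpRecord]:
    """Read a SNP map (.bim, .map, or headered TSV) in file order.

    .bim columns: chrom, snp_id, cM, pos, allele1, allele2.
    .map columns: chrom, snp_id, cM, pos.
    tsv columns (with header): snp_id, chrom, pos.
    """
    records: list[SnpRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if dialect == "tsv":
        if not lines:
            return []
        header = lines[0].split("\t")
        if header[:3] != ["snp_id", "chrom", "pos"]:
            raise ParseError(path, 1, "TSV map header must be snp_id\\tchrom\\tpos")
        start = 1
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split()
        try:
            if dialect == "bim":
                if len(parts) != 6:
                    raise ParseError(path, ln, f".bim line has {len(parts)} fields, expected 6")
                chrom, sid, _cm, pos, a1, a2 = parts
                records.append(SnpRecord(sid, chrom, _parse_pos(pos, path, ln), a1, a2))
            elif dialect == "map":
                if len(parts) != 4:
                    raise ParseError(path, ln, f".map line has {len(parts)} fields, expected 4")
                chrom, sid, _cm, pos = parts
                records.append(SnpRecord(sid, chrom, _parse_pos(pos, path, ln)))
            elif dialect == "tsv":
                sid, chrom, pos = parts[0], parts[1], parts[2]
                records.append(SnpRecord(sid, chrom, _parse_pos(pos, path, ln)))
            else:
                raise ValueError(f"unknown SNP map dialect {dialect!r}")
        except ValidationError as exc:
            raise ParseError(path, ln, str(exc)) from exc
    return records


def _parse_pos(token: str, path: PathLike, ln: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(path, ln, f"non-integer position {token!r}") from None


def write_snp_map(snps: Iterable[SnpRecord], path: PathLike, dialect: str = "map") -> None:
    """Write a SNP map in .map or headered TSV form."""
    with open(path, "w") as fh:
        if dialect == "map":
            for s in snps:
                fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")
        elif dialect == "tsv":
            fh.write("snp_id\tchrom\tpos\n")
            for s in snps:
                fh.write(f"{s.snp_id}\t{s.chrom}\t{s.pos}\n")
        else:
            raise ValueError(f"unknown SNP map dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Genes (BED) and gene sets (GMT)
# ---------------------------------------------------------------------------


def read_bed_genes(path: PathLike) -> list[GeneRegion]:
    """Read gene regions from BED (3 cols + name), converting to 1-based inclusive."""
    regions: list[GeneRegion] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(path, ln, "BED gene line needs chrom,start,end,name")
            chrom, start_s, end_s, name = parts[0], parts[1], parts[2], parts[3]
            start0, end0 = _parse_pos(start_s, path, ln), _parse_pos(end_s, path, ln)
            if start0 >= end0:
                raise ParseError(path, ln, f"BED start {start0} >= end {end0}")
            regions.append(GeneRegion(name, chrom, start0 + 1, end0))
    return regions


def write_bed_genes(genes: Iterable[GeneRegion], path: PathLike) -> None:
    """Write gene regions as BED (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.stop}\t{g.gene_id}\n")


def read_gmt(path: PathLike) -> list[GeneSet]:
    """Read gene sets from GMT: ``set_id <TAB> description <TAB> gene...``."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(path, ln, f"GMT line has {len(parts)} fields, expected >= 3")
            set_id, name = parts[0], parts[1]
            if set_id in seen:
                raise ParseError(path, ln, f"duplicate set_id {set_id!r}")
            seen.add(set_id)
            members = frozenset(g for g in parts[2:] if g)
            if not members:
                raise ParseError(path, ln, f"gene set {set_id!r} has no member genes")
            sets.append(GeneSet(set_id, name, members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: PathLike) -> None:
    """Write gene sets in GMT form (members in sorted order for determinism)."""
    with open(path, "w") as fh:
        for s in sets:
            fh.write(s.set_id + "\t" + s.name + "\t" + "\t".join(sorted(s.members)) + "\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def _fmt_p(p: float | None) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "NA"
    return f"{p:.12e}"


def write_results_table(
    results: Sequence[PairResult] | Sequence[EnrichmentResult], path: PathLike
) -> None:
    """Write a homogeneous result list as TSV.

    Rows are sorted by ascending p-value (statistic descending when no
    p-values are attached yet), ties broken by entity identifier, so repeated
    runs produce byte-identical files.
    """
    results = list(results)
    kinds = {type(r) for r in results}
    if len(kinds) > 1:
        raise ValidationError("write_results_table requires a homogeneous result list")
    with open(path, "w") as fh:
        if not results or isinstance(results[0], PairResult):
            fh.write("snp_i\tsnp_j\tstatistic\tn_cases_used\tn_controls_used\tp_value\n")
            key = lambda r: (  # noqa: E731
                r.p_value if r.p_value is not None else -r.statistic,
                r.snp_i,
                r.snp_j,
            )
            for r in sorted(results, key=key):
                fh.write(
                    f"{r.snp_i}\t{r.snp_j}\t{r.statistic:.12e}\t"
                    f"{r.n_cases_used}\t{r.n_controls_used}\t{_fmt_p(r.p_value)}\n"
                )
        else:
            fh.write("entity_id\tlevel\ta\tb\tc\td\tp_value\tflagged\n")
            for r in sorted(results, key=lambda r: (r.p_value, r.entity_id)):
                fh.write(
                    f"{r.entity_id}\t{r.level}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t"
                    f"{_fmt_p(r.p_value)}\t{int(r.flagged)}\n"
                )


def read_results_table(path: PathLike) -> list[PairResult] | list[EnrichmentResult]:
    """Read back a table written by :func:`write_results_table`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(path, 1, "empty results table")
    header = lines[0].split("\t")
    out: list = []
    if header[0] == "snp_i":
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            si, sj, stat, nca, nct, p = line.split("\t")
            out.append(
                PairResult(
                    snp_i=si,
                    snp_j=sj,
                    statistic=float(stat),
                    n_cases_used=int(nca),
                    n_controls_used=int(nct),
                    p_value=None if p == "NA" else float(p),
                )
            )
    elif header[0] == "entity_id":
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            eid, level, a, b, c, d, p, flagged = line.split("\t")
            out.append(
                EnrichmentResult(
                    entity_id=eid,
                    a=int(a),
                    b=int(b),
                    c=int(c),
                    d=int(d),
                    p_value=float(p),
                    level=level,
                    flagged=bool(int(flagged)),
                )
            )
    else:
        raise ParseError(path, 1, f"unrecognized results header {header[0]!r}")
    return out


def write_snp_pvalues(snp_pvalues: dict[str, float], path: PathLike) -> None:
    """Write per-SNP p-values as TSV sorted by (p, snp_id)."""
    with open(path, "w") as fh:
        fh.write("snp_id\tp_value\n")
        for sid, p in sorted(snp_pvalues.items(), key=lambda kv: (kv[1], kv[0])):
            fh.write(f"{sid}\t{_fmt_p(p)}\n")


def read_snp_pvalues(path: PathLike) -> dict[str, float]:
    """Read a per-SNP p-value table written by :func:`write_snp_pvalues`."""
    out: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["snp_id", "p_value"]:
        raise ParseError(path, 1, "expected header snp_id\\tp_value")
    for line in lines[1:]:
        if not line.strip():
            continue
        sid, p = line.split("\t")
        out[sid] = float(p)
    return out
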