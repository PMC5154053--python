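"""Core data model shared by every stage of the pipeline.

Genotypes are biallelic minor-allele dosage codes 0/1/2 stored as ``int8``;
missing calls are :data:`MISSING` (−1).  Phenotypes are stored as ``uint8``
with 1 = case and 0 = control.  Genomic coordinates are 1-based inclusive
throughout (BED input is converted on read).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Sentinel for a missing genotype call in the int8 genotype matrix.
MISSING: int = -1

#: Phenotype codes in the internal model.
CASE: int = 1
CONTROL: int = 0


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


@dataclass(frozen=True)
class SnpRecord:
    """One SNP of the panel: identifier, chromosome and 1-based position."""

    snp_id: str
    chrom: str
    pos: int
    allele_a: Optional[str] = None
    allele_b: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be non-empty")
        if not self.chrom:
            raise ValidationError(f"SNP {self.snp_id}: chrom must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"SNP {self.snp_id}: pos must be >= 1, got {self.pos}")


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label for comparison ('chr2' and '2' match)."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass
class CohortData:
    """One case–control cohort: genotype matrix, phenotype and SNP map.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_snps)`` int8 matrix of codes {0, 1, 2, MISSING}.
    phenotype
        Per-sample labels, 1 = case and 0 = control.
    snps
        Ordered SNP records, one per genotype column.
    cohort_id
        Free-text cohort label.
    sample_ids
        Optional per-sample identifiers (generated if omitted).
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snps: list[SnpRecord]
    cohort_id: str = "cohort"
    sample_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.uint8)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotypes must be a 2-D matrix")
        n, m = self.genotypes.shape
        if m != len(self.snps):
            raise ValidationError(
                f"genotype matrix has {m} columns but SNP map has {len(self.snps)} records"
            )
        if self.phenotype.shape != (n,):
            raise ValidationError(
                f"phenotype length {self.phenotype.shape} does not match {n} samples"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype code {self.genotypes[i, j]} at sample {i}, SNP {j} "
                "outside {0,1,2,missing}"
            )
        if not np.isin(self.phenotype, (CASE, CONTROL)).all():
            raise ValidationError("phenotype codes must be 0 (control) or 1 (case)")
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValidationError("cohort needs at least one case and one control")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            dup = sorted({x for x in ids if ids.count(x) > 1})
            raise ValidationError(f"duplicate snp_id(s) in cohort map: {dup[:5]}")
        if self.sample_ids is None:
            self.sample_ids = [f"S{i + 1}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == CONTROL).sum())

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]


@dataclass(frozen=True)
class GeneRegion:
    """A gene's genomic interval, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > stop {self.stop}"
            )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (e.g. one GO category from a GMT file)."""

    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.set_id} has no members")


# ---------------------------------------------------------------------------
# Phase I result containers
# ---------------------------------------------------------------------------

#: MDR cell labels.
HIGH, LOW, EMPTY = 1, 0, -1


@dataclass
class PairContingency:
    """3×3 case/control contingency table for one SNP pair (complete cases).

    ``cells[gi, gj] = (case_count, control_count)`` indexed by genotype codes.
    """

    cells: np.ndarray  # (3, 3, 2) int64
    n_cases_used: int
    n_controls_used: int

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.shape != (3, 3, 2):
            raise ValidationError("cells must be a 3x3x2 array")
        if (self.cells < 0).any():
            raise ValidationError("contingency counts must be non-negative")
        if int(self.cells[..., 0].sum()) != self.n_cases_used:
            raise ValidationError("case counts do not sum to n_cases_used")
        if int(self.cells[..., 1].sum()) != self.n_controls_used:
            raise ValidationError("control counts do not sum to n_controls_used")


@dataclass
class PairResult:
    """One evaluated SNP pair: MDR labels, balanced accuracy and p-value."""

    snp_i: str
    snp_j: str
    statistic: float
    labels: Optional[np.ndarray] = None  # (3,3) int8 over {HIGH, LOW, EMPTY}
    p_value: Optional[float] = None
    n_cases_used: int = 0
    n_controls_used: int = 0

    @property
    def n_used(self) -> int:
        return self.n_cases_used + self.n_controls_used


@dataclass
class NullDistribution:
    """Sorted permutation-null statistics (pooled over pairs, or per-run maxima)."""

    values: np.ndarray
    n_permutations: int
    mode: str  # {"pooled", "max"}
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=np.float64))
        if self.mode not in ("pooled", "max"):
            raise ValidationError(f"unknown null mode {self.mode!r}")
        if self.values.size == 0:
            raise ValidationError("null distribution is empty")

    @property
    def size(self) -> int:
        return int(self.values.size)


# ---------------------------------------------------------------------------
# Phase II/III result containers
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """Right-tailed Fisher 2×2 result for a gene or a gene set.

    ``a`` = significant items inside the entity, ``b`` = non-significant
    inside, ``c``/``d`` the same outside; the universe is everything tested.
    """

    entity_id: str
    a: int
    b: int
    c: int
    d: int
    p_value: float
    level: str  # {"gene", "set"}
    flagged: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("2x2 counts must be non-negative")
        if self.level not in ("gene", "set"):
            raise ValidationError(f"unknown enrichment level {self.level!r}")


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PenetranceModel:
    """3×3 disease-probability table over two-SNP genotype combinations.

    ``table[ga, gb]`` is P(disease | ga, gb); ``maf_a``/``maf_b`` give the
    HWE genotype weights used for margins and prevalence.
    """

    table: tuple  # 3x3 nested tuple of floats
    maf_a: float
    maf_b: float

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=np.float64)
        if t.shape != (3, 3):
            raise ValidationError("penetrance table must be 3x3")
        if (t < 0).any() or (t > 1).any():
            raise ValidationError("penetrance entries must lie in [0, 1]")
        for q, name in ((self.maf_a, "maf_a"), (self.maf_b, "maf_b")):
            if not (0 < q <= 0.5):
                raise ValidationError(f"{name} must lie in (0, 0.5], got {q}")
        object.__setattr__(self, "table", tuple(map(tuple, t.tolist())))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.table, dtype=np.float64)

    @staticmethod
    def hwe_weights(maf: float) -> np.ndarray:
        """HWE genotype probabilities (p², 2pq, q²) for minor-allele dosage 0/1/2."""
        q = maf
        p = 1.0 - q
        return np.array([p * p, 2 * p * q, q * q])

    @property
    def prevalence(self) -> float:
        """Population disease probability under HWE at the two MAFs."""
        wa = self.hwe_weights(self.maf_a)
        wb = self.hwe_weights(self.maf_b)
        return float(wa @ self.array @ wb)

    @property
    def marginal_deviation(self) -> float:
        """Max |single-SNP HWE-margin penetrance − prevalence| over both loci.

        Zero (to rounding) for purely epistatic models: neither locus shows a
        marginal effect, so single-locus tests are blind to the pair.
        """
        wa = self.hwe_weights(self.maf_a)
        wb = self.hwe_weights(self.maf_b)
        k = self.prevalence
        margin_a = self.array @ wb       # penetrance by genotype at locus A
        margin_b = wa @ self.array       # by genotype at locus B
        return float(
            max(np.abs(margin_a - k).max(), np.abs(margin_b - k).max())
        )


@dataclass(frozen=True)
class PlantedPair:
    """Ground-truth record for one planted epistatic pair."""

    model: PenetranceModel
    snp_indices: tuple[int, int]
    gene_ids: tuple[str, str]
    set_id: str


@dataclass(frozen=True)
class SimConfig:
    """Everything the synthetic-cohort generator needs; output is a pure
    function of this object (including ``seed``).

    Layout defaults place each gene on its own synthetic chromosome with SNPs
    on a ``snp_spacing`` grid and a ``gene_length`` body centred on the
    block, so a ±500 kb window maps a handful of SNPs per gene and the rest
    of the panel stays intergenic.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    planted: tuple[PlantedPair, ...] = ()
    n_genes: int = 10
    n_sets: int = 4
    gene_length: int = 100_000
    snp_spacing: int = 400_000
    seed: int = 0
    cohort_id: str = "synthetic"
    ld_decay: float = 0.0  # 0 = independent SNPs; in (0,1) = block-LD copy prob
    max_draw_factor: int = 1000

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("n_cases and n_controls must be >= 1")
        if self.n_snps < 2:
            raise ValidationError("n_snps must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        idx = [i for pp in self.planted for i in pp.snp_indices]
        if len(set(idx)) != len(idx):
            raise ValidationError("planted SNP indices must be distinct")
        if idx and (min(idx) < 0 or max(idx) >= self.n_snps):
            raise ValidationError("planted SNP indices must lie in [0, n_snps)")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValidationError("ld_decay must lie in [0, 1)")
        if self.n_genes < 1 or self.n_sets < 1:
            raise ValidationError("n_genes and n_sets must be >= 1")


@dataclass
class Annotation:
    """Synthetic gene regions plus gene sets, with ground-truth bookkeeping."""

    genes: list[GeneRegion]
    sets: list[GeneSet]
    truth_sets: list[str] = field(default_factory=list)
    truth_genes: list[str] = field(default_factory=list)


@dataclass
class GroundTruth:
    """What was planted where, for verifying recovery."""

    planted: tuple[PlantedPair, ...]
    mafs: np.ndarray
    annotation: Optional[Annotation] = None

    @property
    def planted_index_pairs(self) -> list[tuple[int, int]]:
        return [tuple(sorted(pp.snp_indices)) for pp in self.planted]


def as_labels(phenotype: Sequence[str] | np.ndarray) -> np.ndarray:
    """Coerce 'case'/'control' strings or 0/1 codes to the internal uint8 coding."""
    arr = np.asarray(phenotype)
    if arr.dtype.kind in "ui" or arr.dtype.kind == "b":
        return arr.astype(np.uint8)
    out = np.empty(arr.shape, dtype=np.uint8)
    for i, v in enumerate(arr):
        s = str(v).strip().lower()
        if s in ("case", "1"):
            out[i] = CASE
        elif s in ("control", "0"):
            out[i] = CONTROL
        else:
            raise ValidationError(f"unrecognized phenotype label {v!r}")
    return out
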