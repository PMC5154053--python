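"""Multifactor dimensionality reduction (MDR) for pairwise epistasis scans.

For every SNP pair the 3×3 multilocus genotype table is reduced to one
dimension by labelling each cell high-risk when its case:control ratio
reaches the cohort ratio (constructive induction), and the resulting
two-class rule is scored by balanced accuracy, (sensitivity + specificity)/2.
The statistic is computed on the full cohort — significance comes from the
phenotype-permutation test in :mod:`epienrich.permutation`, which reruns the
identical (overfit) statistic under shuffled labels.

Samples missing a genotype at either SNP of a pair are excluded from that
pair's table only (complete-case per pair).  The exhaustive scan is a
BLAS-backed kernel over one-hot genotype indicators; the per-pair functions
(`build_contingency`, `label_cells`, `balanced_accuracy`) implement the same
definitions directly and are cross-checked against the kernel in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .types import (
    EMPTY,
    HIGH,
    LOW,
    CohortData,
    PairContingency,
    PairResult,
    ValidationError,
)

logger = logging.getLogger(__name__)


class DegeneratePairError(ValueError):
    """A pair has no usable cases or controls after missing-data exclusion."""


# ---------------------------------------------------------------------------
# Per-pair definitional operations
# ---------------------------------------------------------------------------


def build_contingency(
    genotypes_i: np.ndarray, genotypes_j: np.ndarray, phenotype: np.ndarray
) -> PairContingency:
    """Count cases/controls per two-SNP genotype cell (complete cases only)."""
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    y = np.asarray(phenotype)
    if not (gi.shape == gj.shape == y.shape):
        raise ValidationError("genotype and phenotype vectors must have equal length")
    ok = (gi >= 0) & (gj >= 0)
    gi, gj, y = gi[ok], gj[ok], y[ok]
    cells = np.zeros((3, 3, 2), dtype=np.int64)
    # column 0 = cases, column 1 = controls
    np.add.at(cells, (gi, gj, 1 - y.astype(np.int64)), 1)
    n_cases = int(cells[..., 0].sum())
    n_controls = int(cells[..., 1].sum())
    if n_cases == 0 and n_controls == 0:
        raise DegeneratePairError("all samples excluded for this pair")
    return PairContingency(cells, n_cases, n_controls)


def label_cells(table: PairContingency, threshold: Optional[float] = None) -> np.ndarray:
    """Label each genotype cell HIGH/LOW/EMPTY by its case:control ratio.

    A cell is HIGH when ``cases / controls >= threshold`` (a cell with cases
    and no controls is HIGH; ratio exactly at threshold is HIGH).  The
    default threshold is the pair's complete-case case:control ratio.
    """
    if threshold is None:
        if table.n_controls_used == 0:
            raise DegeneratePairError("no controls: default threshold undefined")
        threshold = table.n_cases_used / table.n_controls_used
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    cases = table.cells[..., 0].astype(np.float64)
    controls = table.cells[..., 1].astype(np.float64)
    labels = np.where(cases >= threshold * controls, HIGH, LOW).astype(np.int8)
    labels[(cases == 0) & (controls == 0)] = EMPTY
    return labels


def balanced_accuracy(table: PairContingency, labels: np.ndarray) -> float:
    """Balanced accuracy of the rule 'predict case in HIGH cells, control in LOW'."""
    if table.n_cases_used == 0 or table.n_controls_used == 0:
        raise DegeneratePairError("balanced accuracy needs at least one case and one control")
    labels = np.asarray(labels)
    high = labels == HIGH
    low = labels == LOW
    tp = int(table.cells[..., 0][high].sum())
    tn = int(table.cells[..., 1][low].sum())
    sensitivity = tp / table.n_cases_used
    specificity = tn / table.n_controls_used
    return 0.5 * (sensitivity + specificity)


def mdr_statistic(
    genotypes_i: np.ndarray, genotypes_j: np.ndarray, phenotype: np.ndarray
) -> PairResult:
    """Full per-pair MDR evaluation via the definitional path."""
    table = build_contingency(genotypes_i, genotypes_j, phenotype)
    labels = label_cells(table)
    stat = balanced_accuracy(table, labels)
    return PairResult(
        snp_i="i",
        snp_j="j",
        statistic=stat,
        labels=labels,
        n_cases_used=table.n_cases_used,
        n_controls_used=table.n_controls_used,
    )


# ---------------------------------------------------------------------------
# Vectorized exhaustive scan
# ---------------------------------------------------------------------------


@dataclass
class ScanKernel:
    """Precomputed one-hot encodings for repeated scans of one genotype matrix.

    Builds, once per cohort, the per-genotype indicator stack ``Z[a]`` and the
    validity matrix ``V`` (non-missing indicator), plus the phenotype-free
    cell totals ``T[a,b] = Z[a]ᵀ Z[b]``.  A scan for any phenotype vector then
    costs ten (m × n)(n × m) products — cheap enough to rerun hundreds of
    times for the permutation test.
    """

    Z: np.ndarray        # (3, n, m) float32 one-hot genotype indicators
    V: np.ndarray        # (n, m) float32 validity (genotype present)
    totals: np.ndarray   # (3, 3, m, m) float32 cell totals (cases + controls)
    n_valid: np.ndarray  # (m, m) float32 complete-case counts per pair

    @classmethod
    def from_genotypes(cls, G: np.ndarray) -> "ScanKernel":
        G = np.asarray(G)
        n, m = G.shape
        Z = np.empty((3, n, m), dtype=np.float32)
        for a in range(3):
            Z[a] = G == a
        V = (G >= 0).astype(np.float32)
        totals = np.empty((3, 3, m, m), dtype=np.float32)
        for a in range(3):
            for b in range(3):
                totals[a, b] = Z[a].T @ Z[b]
        n_valid = V.T @ V
        return cls(Z=Z, V=V, totals=totals, n_valid=n_valid)

    @property
    def n_snps(self) -> int:
        return self.Z.shape[2]

    def case_counts(self, case_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-pair case cell counts (3,3,m,m) and case complete-case counts (m,m)."""
        y = np.asarray(case_mask, dtype=np.float32)
        Zy = self.Z * y[None, :, None]
        cases = np.empty_like(self.totals)
        for a in range(3):
            for b in range(3):
                cases[a, b] = Zy[a].T @ self.Z[b]
        n_cases = (self.V * y[:, None]).T @ self.V
        return cases, n_cases

    def statistics(self, case_mask: np.ndarray) -> np.ndarray:
        """Balanced-accuracy matrix (m, m) for one phenotype assignment.

        Entry (i, j) with i < j is the pair's MDR statistic; the diagonal and
        lower triangle are NaN, as are degenerate pairs (no usable cases or
        controls).  Counts stay below 2^24 so float32 arithmetic — including
        the threshold tie comparison by cross-multiplication — is exact.
        """
        cases, n_cases = self.case_counts(case_mask)
        controls = self.totals - cases
        n_controls = self.n_valid - n_cases
        # HIGH iff cases/controls >= n_cases/n_controls, by cross-multiplication
        # (ties -> HIGH; cells with controls == 0 and cases > 0 -> HIGH; empty
        # cells get HIGH too but contribute nothing to either sum below).
        high = cases * n_controls[None, None] >= controls * n_cases[None, None]
        # counts are exact integers in float32; divide in float64 so the
        # statistic is bit-identical to the per-pair definitional path
        tp = np.where(high, cases, 0).sum(axis=(0, 1), dtype=np.float64)
        tn_high = np.where(high, controls, 0).sum(axis=(0, 1), dtype=np.float64)
        nca = n_cases.astype(np.float64)
        nct = n_controls.astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            sens = tp / nca
            spec = (nct - tn_high) / nct
            ba = 0.5 * (sens + spec)
        m = self.n_snps
        ba[np.tril_indices(m)] = np.nan
        ba[(n_cases == 0) | (n_controls == 0)] = np.nan
        return ba.astype(np.float64)


def scan_statistics(
    cohort: CohortData, kernel: Optional[ScanKernel] = None
) -> np.ndarray:
    """Upper-triangular (m, m) matrix of observed pair statistics (NaN elsewhere)."""
    if cohort.n_snps < 2:
        raise ValidationError("pairwise scan needs at least 2 SNPs")
    kern = kernel or ScanKernel.from_genotypes(cohort.genotypes)
    return kern.statistics(cohort.phenotype == 1)


def pairwise_scan(
    cohort: CohortData,
    pair_filter: Optional[Callable[[int, int], bool]] = None,
    maf_min: float = 0.0,
    with_labels: bool = False,
) -> list[PairResult]:
    """Exhaustively evaluate all C(m, 2) SNP pairs by MDR.

    Returns one :class:`PairResult` per pair in lexicographic (i, j), i < j
    order; degenerate pairs (no usable case or control after missing-data
    exclusion) are skipped with a log entry.  ``maf_min`` > 0 restricts the
    scan to SNPs at or above that minor-allele frequency (off by default —
    no marker QC is applied unless asked for).  ``pair_filter(i, j)`` may
    restrict the enumerated pairs.  ``with_labels`` attaches each pair's 3×3
    HIGH/LOW/EMPTY label array (slower; labels are recomputed per pair).
    """
    if cohort.n_snps < 2:
        raise ValidationError("pairwise scan needs at least 2 SNPs")
    keep = np.arange(cohort.n_snps)
    if maf_min > 0:
        mafs = _empirical_maf(cohort.genotypes)
        keep = keep[mafs >= maf_min]
        if keep.size < 2:
            raise ValidationError("fewer than 2 SNPs pass the MAF filter")
    sub = cohort.genotypes[:, keep]
    kern = ScanKernel.from_genotypes(sub)
    ba = kern.statistics(cohort.phenotype == 1)
    cases, n_cases = kern.case_counts(cohort.phenotype == 1)
    n_controls = kern.n_valid - n_cases
    ids = cohort.snp_ids
    results: list[PairResult] = []
    n_skipped = 0
    msub = keep.size
    for a in range(msub):
        for b in range(a + 1, msub):
            i, j = int(keep[a]), int(keep[b])
            if pair_filter is not None and not pair_filter(i, j):
                continue
            stat = ba[a, b]
            if np.isnan(stat):
                n_skipped += 1
                continue
            labels = None
            if with_labels:
                table = PairContingency(
                    np.stack(
                        [cases[:, :, a, b], kern.totals[:, :, a, b] - cases[:, :, a, b]],
                        axis=-1,
                    ).astype(np.int64),
                    int(n_cases[a, b]),
                    int(n_controls[a, b]),
                )
                labels = label_cells(table)
            results.append(
                PairResult(
                    snp_i=ids[i],
                    snp_j=ids[j],
                    statistic=float(stat),
                    labels=labels,
                    n_cases_used=int(n_cases[a, b]),
                    n_controls_used=int(n_controls[a, b]),
                )
            )
    if n_skipped:
        logger.info("pairwise_scan: skipped %d degenerate pair(s)", n_skipped)
    return results


def best_per_snp(results: list[PairResult]) -> dict[str, tuple[float, str]]:
    """Per SNP, the maximum statistic over all pairs containing it.

    Returns ``{snp_id: (best_statistic, partner_id)}``; ties broken by the
    lexicographically smallest partner id.  SNPs appearing in no surviving
    pair are simply absent.
    """
    if not results:
        raise ValidationError("best_per_snp needs at least one pair result")
    best: dict[str, tuple[float, str]] = {}
    for r in results:
        for snp, partner in ((r.snp_i, r.snp_j), (r.snp_j, r.snp_i)):
            cur = best.get(snp)
            if cur is None or r.statistic > cur[0] or (
                r.statistic == cur[0] and partner < cur[1]
            ):
                best[snp] = (r.statistic, partner)
    return best


def _empirical_maf(G: np.ndarray) -> np.ndarray:
    """Per-SNP minor-allele frequency over non-missing calls (folded to <= 0.5)."""
    valid = G >= 0
    with np.errstate(invalid="ignore"):
        freq = np.where(
            valid.sum(axis=0) > 0,
            (G * valid).sum(axis=0) / (2.0 * np.maximum(valid.sum(axis=0), 1)),
            0.0,
        )
    return np.minimum(freq, 1.0 - freq)
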