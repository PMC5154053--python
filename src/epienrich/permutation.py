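"""Phenotype-permutation null distributions and empirical p-values.

Shuffling case/control labels breaks every genotype–phenotype link while
preserving the genotype matrix, its missingness pattern and the case:control
totals, so rerunning the exhaustive MDR scan under permuted labels samples
the statistic's null distribution *including* its finite-sample overfitting
bias.  Two nulls are supported:

``pooled``
    every pair's statistic from every permutation forms one empirical null;
    gives per-pair p-values with resolution 1/(n_permutations × n_pairs).
``max``
    only each permutation's maximum statistic is kept; p-values are
    family-wise (probability any null pair scores this high).

Labels are permuted once per round and the whole scan rerun, so the
between-pair dependence structure of a real dataset-wide permutation test is
preserved.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .mdr import ScanKernel, best_per_snp
from .types import CohortData, NullDistribution, PairResult, ValidationError

logger = logging.getLogger(__name__)


def permute_phenotype(phenotype: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of the label vector (totals conserved)."""
    phenotype = np.asarray(phenotype)
    if phenotype.size < 2:
        raise ValidationError("need at least 2 samples to permute")
    return phenotype[rng.permutation(phenotype.size)]


def build_null(
    cohort: CohortData,
    n_permutations: int = 1000,
    mode: str = "pooled",
    seed: Optional[int] = None,
    kernel: Optional[ScanKernel] = None,
) -> NullDistribution:
    """Permutation null for the pairwise MDR statistic of one cohort.

    Reruns the exhaustive scan ``n_permutations`` times under shuffled
    phenotypes.  Degenerate pairs (NaN statistics) are dropped from the null,
    mirroring their exclusion from the observed scan.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if mode not in ("pooled", "max"):
        raise ValidationError(f"unknown null mode {mode!r}")
    kern = kernel or ScanKernel.from_genotypes(cohort.genotypes)
    rng = np.random.default_rng(seed)
    y = (cohort.phenotype == 1).astype(np.uint8)
    out: list[np.ndarray] = []
    for _ in range(n_permutations):
        perm = permute_phenotype(y, rng)
        ba = kern.statistics(perm == 1)
        vals = ba[np.isfinite(ba)]
        if vals.size == 0:
            raise ValidationError("every pair degenerate under permutation")
        out.append(vals.max(keepdims=True) if mode == "max" else vals)
    values = np.concatenate(out)
    return NullDistribution(values, n_permutations=n_permutations, mode=mode, seed=seed)


def empirical_pvalue(observed: float, null: NullDistribution) -> float:
    """Add-one empirical p-value: (1 + #{null >= observed}) / (1 + N)."""
    n_ge = null.size - int(np.searchsorted(null.values, observed, side="left"))
    return (1 + n_ge) / (1 + null.size)


def attach_pair_pvalues(
    results: list[PairResult], null: NullDistribution
) -> list[PairResult]:
    """Fill each pair's ``p_value`` from the shared null (in place; returned)."""
    stats = np.array([r.statistic for r in results])
    n_ge = null.size - np.searchsorted(null.values, stats, side="left")
    for r, k in zip(results, n_ge):
        r.p_value = (1 + int(k)) / (1 + null.size)
    return results


def assign_snp_pvalues(results: list[PairResult]) -> dict[str, float]:
    """Assign each SNP the p-value of its strongest pairwise association.

    With a null shared across pairs this is the minimum p over the SNP's
    pairs, which equals the p-value of its best statistic.
    """
    if not results:
        raise ValidationError("assign_snp_pvalues needs at least one pair result")
    missing = [r for r in results if r.p_value is None]
    if missing:
        raise ValidationError("every pair needs a p-value; run attach_pair_pvalues first")
    out: dict[str, float] = {}
    for r in results:
        for snp in (r.snp_i, r.snp_j):
            cur = out.get(snp)
            if cur is None or r.p_value < cur:
                out[snp] = r.p_value
    return out


def scan_with_significance(
    cohort: CohortData,
    n_permutations: int = 1000,
    mode: str = "pooled",
    seed: Optional[int] = None,
    maf_min: float = 0.0,
) -> tuple[list[PairResult], dict[str, float], NullDistribution]:
    """Phase I in one call: scan, permutation null, pair and SNP p-values."""
    from .mdr import pairwise_scan

    results = pairwise_scan(cohort, maf_min=maf_min)
    kern = None
    if maf_min == 0.0:
        kern = ScanKernel.from_genotypes(cohort.genotypes)
    else:
        ids = {r.snp_i for r in results} | {r.snp_j for r in results}
        keep = [k for k, s in enumerate(cohort.snps) if s.snp_id in ids]
        kern = ScanKernel.from_genotypes(cohort.genotypes[:, keep])
    null = build_null(cohort, n_permutations=n_permutations, mode=mode, seed=seed, kernel=kern)
    attach_pair_pvalues(results, null)
    snp_p = assign_snp_pvalues(results)
    # sanity: min-p per SNP equals p of the per-SNP best statistic
    best = best_per_snp(results)
    for snp, (stat, _) in best.items():
        assert abs(snp_p[snp] - empirical_pvalue(stat, null)) < 1e-12
    return results, snp_p, null
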