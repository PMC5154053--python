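"""scikit-learn-style estimators wrapping the Phase I core.

``PairwiseMDR`` and ``MDRPermutationTest`` take the conventional ``(X, y)``
interface — ``X`` a samples × SNPs dosage matrix (0/1/2, −1 or NaN missing),
``y`` binary case/control labels — expose fitted attributes with trailing
underscores and compose with sklearn model selection.  The module-level
functions in :mod:`epienrich.mdr` and :mod:`epienrich.permutation` are thin
wrappers over the same kernels.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .mdr import ScanKernel
from .permutation import permute_phenotype
from .types import MISSING, NullDistribution, ValidationError


def _validate_X_y(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("X must be a 2-D matrix with at least 2 SNP columns")
    if np.issubdtype(X.dtype, np.floating):
        G = np.where(np.isnan(X), MISSING, X).astype(np.int8)
    else:
        G = X.astype(np.int8)
    if not np.isin(G, (0, 1, 2, MISSING)).all():
        raise ValidationError("genotype codes must lie in {0, 1, 2, missing}")
    y = np.asarray(y).astype(np.uint8).ravel()
    if y.shape[0] != G.shape[0]:
        raise ValidationError("X and y have mismatched sample counts")
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("y must be binary (1 = case, 0 = control)")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValidationError("need at least one case and one control")
    return G, y


class PairwiseMDR(BaseEstimator):
    """Exhaustive pairwise MDR scan as a fit-shaped estimator.

    After ``fit(X, y)``:

    Attributes
    ----------
    statistic_matrix_ : (m, m) ndarray
        Balanced accuracy per pair in the upper triangle, NaN elsewhere.
    pairs_ : (k, 2) ndarray of int
        Column-index pairs (i < j) of the non-degenerate pairs.
    statistics_ : (k,) ndarray
        Their statistics, aligned with ``pairs_``.
    best_stat_per_snp_ : (m,) ndarray
        Per SNP, the maximum statistic over pairs containing it (NaN for a
        SNP in no surviving pair).
    """

    def fit(self, X, y) -> "PairwiseMDR":
        G, y = _validate_X_y(X, y)
        kernel = ScanKernel.from_genotypes(G)
        ba = kernel.statistics(y == 1)
        iu = np.triu_indices(G.shape[1], k=1)
        vals = ba[iu]
        ok = np.isfinite(vals)
        self.statistic_matrix_ = ba
        self.pairs_ = np.column_stack([iu[0][ok], iu[1][ok]])
        self.statistics_ = vals[ok]
        full = np.where(np.isnan(ba), -np.inf, ba)
        best = np.maximum(full.max(axis=0), full.max(axis=1))
        self.best_stat_per_snp_ = np.where(np.isinf(best), np.nan, best)
        self.n_features_in_ = G.shape[1]
        self._kernel = kernel
        return self

    def top_pair(self) -> tuple[int, int]:
        """Column indices of the highest-scoring pair (lexicographic tie-break)."""
        check_is_fitted(self, "statistics_")
        order = np.lexsort((self.pairs_[:, 1], self.pairs_[:, 0], -self.statistics_))
        i, j = self.pairs_[order[0]]
        return int(i), int(j)


class MDRPermutationTest(BaseEstimator):
    """Pairwise MDR scan plus phenotype-permutation significance.

    Parameters
    ----------
    n_permutations : int, default 1000
        Label shuffles used to build the empirical null.
    mode : {"pooled", "max"}, default "pooled"
        Pooled per-pair null, or family-wise per-permutation-maximum null.
    random_state : int or None
        Seed for the permutation stream.

    After ``fit(X, y)``: everything from :class:`PairwiseMDR` plus
    ``pair_pvalues_`` (aligned with ``pairs_``), ``snp_pvalues_`` (per
    column: the p-value of the column's strongest pair, NaN if none) and
    ``null_`` (the :class:`~epienrich.types.NullDistribution`).
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        mode: str = "pooled",
        random_state: Optional[int] = None,
    ):
        self.n_permutations = n_permutations
        self.mode = mode
        self.random_state = random_state

    def fit(self, X, y) -> "MDRPermutationTest":
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.mode not in ("pooled", "max"):
            raise ValidationError(f"unknown null mode {self.mode!r}")
        G, y = _validate_X_y(X, y)
        scan = PairwiseMDR().fit(G, y)
        kernel = scan._kernel
        rng = np.random.default_rng(self.random_state)
        chunks = []
        for _ in range(self.n_permutations):
            perm = permute_phenotype(y, rng)
            ba = kernel.statistics(perm == 1)
            vals = ba[np.isfinite(ba)]
            chunks.append(vals.max(keepdims=True) if self.mode == "max" else vals)
        self.null_ = NullDistribution(
            np.concatenate(chunks),
            n_permutations=self.n_permutations,
            mode=self.mode,
            seed=self.random_state,
        )
        n = self.null_.size
        n_ge = n - np.searchsorted(self.null_.values, scan.statistics_, side="left")
        self.pair_pvalues_ = (1 + n_ge) / (1 + n)
        best = scan.best_stat_per_snp_
        snp_p = np.full(best.shape, np.nan)
        ok = np.isfinite(best)
        snp_p[ok] = (1 + n - np.searchsorted(self.null_.values, best[ok], side="left")) / (1 + n)
        self.snp_pvalues_ = snp_p
        self.statistic_matrix_ = scan.statistic_matrix_
        self.pairs_ = scan.pairs_
        self.statistics_ = scan.statistics_
        self.best_stat_per_snp_ = best
        self.n_features_in_ = G.shape[1]
        return self
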