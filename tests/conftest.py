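"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately re-derive everything from first principles (per-sample
classification, exact rational hypergeometric sums) without touching the
package's vectorized implementations.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from epienrich.types import CohortData, SnpRecord


def mdr_oracle(gi, gj, y):
    """Brute-force per-sample MDR balanced accuracy.

    Labels each observed genotype cell high-risk iff its case:control ratio
    reaches the complete-case cohort ratio (exact integer cross-products),
    classifies every sample individually, and reads sensitivity/specificity
    off the confusion matrix.  Returns None for degenerate pairs.
    """
    rows = [
        (int(a), int(b), int(l))
        for a, b, l in zip(gi, gj, y)
        if int(a) >= 0 and int(b) >= 0
    ]
    n_case = sum(1 for *_, l in rows if l == 1)
    n_ctrl = len(rows) - n_case
    if n_case == 0 or n_ctrl == 0:
        return None
    cells: dict[tuple[int, int], list[int]] = {}
    for a, b, l in rows:
        c = cells.setdefault((a, b), [0, 0])
        c[0 if l == 1 else 1] += 1
    # high iff cases/controls >= n_case/n_ctrl, ties high, controls=0 -> high
    high = {cell: ca * n_ctrl >= co * n_case for cell, (ca, co) in cells.items()}
    tp = fn = tn = fp = 0
    for a, b, l in rows:
        pred_case = high[(a, b)]
        if l == 1:
            tp += pred_case
            fn += not pred_case
        else:
            fp += pred_case
            tn += not pred_case
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def fisher_oracle(a, b, c, d) -> Fraction:
    """Right Fisher tail by exhaustive enumeration, as an exact rational."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    k_max = min(r1, c1)
    num = sum(comb(r1, k) * comb(n - r1, c1 - k) for k in range(a, k_max + 1))
    return Fraction(num, comb(n, c1))


def random_cohort(rng, n_min=6, n_max=50, m_min=2, m_max=6, miss=0.1):
    """Small random cohort (guaranteed >= 1 case and >= 1 control)."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        m = int(rng.integers(m_min, m_max + 1))
        G = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        if miss:
            G[rng.random((n, m)) < miss] = -1
        y = (rng.random(n) < 0.5).astype(np.uint8)
        if 0 < y.sum() < n:
            break
    snps = [SnpRecord(f"rs{j + 1}", "1", 1000 * (j + 1)) for j in range(m)]
    return CohortData(genotypes=G, phenotype=y, snps=snps, cohort_id="rand")


@pytest.fixture
def tiny_cohort() -> CohortData:
    """4 samples x 3 SNPs, fully deterministic, no missing data."""
    G = np.array(
        [
            [0, 0, 2],
            [0, 1, 1],
            [1, 2, 0],
            [1, 2, 2],
        ],
        dtype=np.int8,
    )
    y = np.array([1, 0, 1, 1], dtype=np.uint8)
    snps = [
        SnpRecord("rsA", "1", 100),
        SnpRecord("rsB", "1", 200),
        SnpRecord("rsC", "2", 300),
    ]
    return CohortData(genotypes=G, phenotype=y, snps=snps, cohort_id="tiny")
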