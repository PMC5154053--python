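"""SNP→gene window mapping, gene-level and set-level Fisher enrichment,
and two-cohort replication.

A SNP belongs to a gene's region when it lies within ``window`` base pairs
(default 500 kb, boundaries inclusive) of the gene's start/stop — wide
enough to sweep in regulatory variants; strand is ignored.  At each level a
right-tailed Fisher's exact test asks whether significant items (SNPs with
p ≤ α inside a gene's region; genes with p ≤ α inside a set) are
over-represented relative to the rest of the tested universe, so a region's
size enters through its non-significant count.  An entity replicates when
its enrichment p-value is ≤ α in both the detection and replication cohort.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.special import gammaln

from .types import (
    EnrichmentResult,
    GeneRegion,
    GeneSet,
    SnpRecord,
    ValidationError,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 500_000
DEFAULT_ALPHA = 0.05


class SnpGeneMap:
    """Multimap SNP id → set of gene ids within the mapping window."""

    def __init__(self, assignments: Mapping[str, set[str]], window: int):
        self.assignments = {k: set(v) for k, v in assignments.items()}
        self.window = window

    def genes_for(self, snp_id: str) -> set[str]:
        return self.assignments.get(snp_id, set())

    def snps_for_gene(self, gene_id: str) -> set[str]:
        return {s for s, gs in self.assignments.items() if gene_id in gs}

    @property
    def n_assigned(self) -> int:
        return len(self.assignments)


def map_snps_to_genes(
    snps: Iterable[SnpRecord],
    genes: Iterable[GeneRegion],
    window: int = DEFAULT_WINDOW,
) -> SnpGeneMap:
    """Assign each SNP to every gene whose ±window region contains it.

    Boundaries are inclusive: a SNP exactly ``window`` bp from a gene
    boundary is assigned.  Chromosome labels are compared with an optional
    'chr' prefix stripped.  SNPs covered by no region stay unassigned (they
    still count toward the enrichment universe).
    """
    if window < 0:
        raise ValidationError("window must be >= 0")
    by_chrom: dict[str, list[GeneRegion]] = defaultdict(list)
    for g in genes:
        by_chrom[normalize_chrom(g.chrom)].append(g)
    assignments: dict[str, set[str]] = {}
    for s in snps:
        hits = {
            g.gene_id
            for g in by_chrom.get(normalize_chrom(s.chrom), ())
            if g.start - window <= s.pos <= g.stop + window
        }
        if hits:
            assignments[s.snp_id] = hits
    return SnpGeneMap(assignments, window)


def fisher_right_tail(a: int, b: int, c: int, d: int) -> float:
    """Right-tailed Fisher's exact test on a 2×2 table.

    Probability, under the hypergeometric distribution with the table's
    margins fixed, of a first cell at least as large as ``a``:

        p = Σ_{k >= a} C(a+b, k) C(c+d, a+c-k) / C(N, a+c)

    computed as a log-gamma-stabilised sum of hypergeometric point masses
    (relative error ≲ 1e-10 over the supported count range).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValidationError("2x2 counts must be non-negative")
        if x != int(x):
            raise ValidationError("2x2 counts must be integers")
    n = a + b + c + d
    if n < 1:
        raise ValidationError("table must contain at least one observation")
    row1, col1 = a + b, a + c
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    if a <= k_min:
        return 1.0
    ks = np.arange(a, k_max + 1)
    log_p = (
        _lchoose(row1, ks)
        + _lchoose(n - row1, col1 - ks)
        - _lchoose(n, col1)
    )
    # sum point masses from the tail end inward for accuracy
    return float(min(1.0, np.exp(log_p).sum()))


def _lchoose(n, k):
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def gene_enrichment(
    snp_gene_map: SnpGeneMap,
    snp_pvalues: Mapping[str, float],
    genes: Iterable[GeneRegion],
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Per-gene overabundance of significant SNPs (right-tailed Fisher).

    The universe is every SNP with a p-value; for gene G the 2×2 is
    (significant/non-significant) × (mapped to G / not mapped to G), so a
    larger region enters through its larger non-significant count.  A SNP
    mapped to several genes is "inside" for each of their tests but counts
    once in the universe.  Genes whose window covers no SNP are emitted with
    a = b = 0, p = 1 and ``flagged=True``.
    """
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must lie in (0, 1]")
    universe = set(snp_pvalues)
    unmapped = {
        s for s in snp_gene_map.assignments if s not in universe
    }
    if unmapped:
        raise ValidationError(
            f"{len(unmapped)} mapped SNP(s) lack p-values, e.g. {sorted(unmapped)[:3]}"
        )
    sig = {s for s, p in snp_pvalues.items() if p <= alpha}
    n_sig, n_tot = len(sig), len(universe)
    gene_to_snps: dict[str, set[str]] = defaultdict(set)
    for s, gs in snp_gene_map.assignments.items():
        if s in universe:
            for g in gs:
                gene_to_snps[g].add(s)
    results = []
    for gene in genes:
        inside = gene_to_snps.get(gene.gene_id, set())
        a = len(inside & sig)
        b = len(inside) - a
        c = n_sig - a
        d = (n_tot - len(inside)) - c
        flagged = len(inside) == 0
        p = 1.0 if flagged else fisher_right_tail(a, b, c, d)
        if flagged:
            logger.info("gene %s: no SNPs mapped; emitted with p = 1", gene.gene_id)
        results.append(
            EnrichmentResult(gene.gene_id, a, b, c, d, p, level="gene", flagged=flagged)
        )
    return results


def set_enrichment(
    sets: Iterable[GeneSet],
    gene_pvalues: Mapping[str, float],
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Per-set overabundance of significant genes (right-tailed Fisher).

    The universe is every gene with a gene-level p-value; set members outside
    it are dropped with a log entry.  Sets with no members in the universe
    are emitted with p = 1 and ``flagged=True``.
    """
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must lie in (0, 1]")
    universe = set(gene_pvalues)
    sig = {g for g, p in gene_pvalues.items() if p <= alpha}
    n_sig, n_tot = len(sig), len(universe)
    results = []
    for gs in sets:
        members = gs.members & universe
        dropped = len(gs.members) - len(members)
        if dropped:
            logger.info("set %s: %d member gene(s) outside the tested universe", gs.set_id, dropped)
        a = len(members & sig)
        b = len(members) - a
        c = n_sig - a
        d = (n_tot - len(members)) - c
        flagged = len(members) == 0
        p = 1.0 if flagged else fisher_right_tail(a, b, c, d)
        results.append(
            EnrichmentResult(gs.set_id, a, b, c, d, p, level="set", flagged=flagged)
        )
    return results


def replicate(
    detection: list[EnrichmentResult],
    replication: list[EnrichmentResult],
    alpha: float = DEFAULT_ALPHA,
) -> list[tuple[str, float, float]]:
    """Entities significant (p ≤ α) in both cohorts.

    Returns ``(entity_id, p_detection, p_replication)`` sorted by the worse
    of the two p-values (ascending), ties by entity id.  Both inputs must be
    at the same level (gene or set).
    """
    levels = {r.level for r in detection} | {r.level for r in replication}
    if len(levels) > 1:
        raise ValidationError(f"mixed enrichment levels in replicate: {sorted(levels)}")
    p_det = {r.entity_id: r.p_value for r in detection}
    p_rep = {r.entity_id: r.p_value for r in replication}
    out = [
        (eid, p_det[eid], p_rep[eid])
        for eid in p_det.keys() & p_rep.keys()
        if p_det[eid] <= alpha and p_rep[eid] <= alpha
    ]
    out.sort(key=lambda t: (max(t[1], t[2]), t[0]))
    return out


def benjamini_hochberg(pvalues: Mapping[str, float]) -> dict[str, float]:
    """Benjamini–Hochberg adjusted p-values (optional, off by default upstream)."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    n = len(items)
    adj: dict[str, float] = {}
    running = 1.0
    for rank in range(n, 0, -1):
        eid, p = items[rank - 1]
        running = min(running, p * n / rank)
        adj[eid] = running
    return adj
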