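"""Window mapping, Fisher right tail, gene/set enrichment and replication."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epienrich.enrichment import (
    benjamini_hochberg,
    fisher_right_tail,
    gene_enrichment,
    map_snps_to_genes,
    replicate,
    set_enrichment,
)
from epienrich.types import EnrichmentResult, GeneRegion, GeneSet, SnpRecord, ValidationError

from conftest import fisher_oracle

GENE = GeneRegion("G", "chr1", 1_000_000, 1_050_000)


class TestMapping:
    def test_boundary_inclusive_at_window(self):
        snp = SnpRecord("rs1", "chr1", 500_000)  # exactly 500 kb upstream
        m = map_snps_to_genes([snp], [GENE], window=500_000)
        assert m.genes_for("rs1") == {"G"}

    def test_one_bp_beyond_window_excluded(self):
        snp = SnpRecord("rs1", "chr1", 499_999)
        m = map_snps_to_genes([snp], [GENE], window=500_000)
        assert m.genes_for("rs1") == set()

    def test_downstream_boundary(self):
        inside = SnpRecord("rs1", "chr1", 1_550_000)
        outside = SnpRecord("rs2", "chr1", 1_550_001)
        m = map_snps_to_genes([inside, outside], [GENE], window=500_000)
        assert m.genes_for("rs1") == {"G"}
        assert m.genes_for("rs2") == set()

    def test_multiple_genes(self):
        g2 = GeneRegion("H", "chr1", 1_040_000, 1_200_000)
        snp = SnpRecord("rs1", "chr1", 1_045_000)
        m = map_snps_to_genes([snp], [GENE, g2], window=0)
        assert m.genes_for("rs1") == {"G", "H"}

    def test_chromosome_prefix_normalized(self):
        snp = SnpRecord("rs1", "1", 1_000_010)
        m = map_snps_to_genes([snp], [GENE], window=0)
        assert m.genes_for("rs1") == {"G"}

    def test_other_chromosome_never_mapped(self):
        snp = SnpRecord("rs1", "chr2", 1_000_010)
        m = map_snps_to_genes([snp], [GENE], window=10_000_000)
        assert m.genes_for("rs1") == set()


class TestFisher:
    def test_known_values(self):
        assert fisher_right_tail(3, 1, 1, 3) == pytest.approx(17 / 70, rel=1e-10)
        assert fisher_right_tail(4, 0, 0, 4) == pytest.approx(1 / 70, rel=1e-10)

    def test_minimum_support_is_one(self):
        assert fisher_right_tail(0, 5, 3, 2) == 1.0

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 40, 4)
            if a + b + c + d == 0:
                continue
            ours = fisher_right_tail(int(a), int(b), int(c), int(d))
            ref = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert ours == pytest.approx(ref, rel=1e-9)

    @given(st.tuples(*(st.integers(0, 12),) * 4).filter(lambda t: sum(t) > 0))
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        assert fisher_right_tail(a, b, c, d) == pytest.approx(
            float(fisher_oracle(a, b, c, d)), rel=1e-10)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            fisher_right_tail(-1, 1, 1, 1)


def _snp(i, pos, chrom="chr1"):
    return SnpRecord(f"rs{i}", chrom, pos)


class TestGeneEnrichment:
    def setup_method(self):
        # gene A covers rs1-rs3 (positions 100-300), 17 background SNPs far away
        self.genes = [GeneRegion("A", "chr1", 100, 300)]
        self.snps = [_snp(1, 100), _snp(2, 200), _snp(3, 300)] + [
            _snp(i, 10_000_000 + i * 2_000_000) for i in range(4, 21)
        ]
        self.mapping = map_snps_to_genes(self.snps, self.genes, window=0)

    def test_counts_and_direction(self):
        pvals = {s.snp_id: 0.5 for s in self.snps}
        pvals["rs1"] = pvals["rs2"] = 0.01  # 2 of 3 inside significant
        pvals["rs7"] = 0.01                 # 1 of 17 outside
        (res,) = gene_enrichment(self.mapping, pvals, self.genes)
        assert (res.a, res.b, res.c, res.d) == (2, 1, 1, 16)
        assert res.p_value == pytest.approx(
            float(fisher_oracle(2, 1, 1, 16)), rel=1e-10)
        assert res.p_value < 0.05

    def test_margin_conservation(self):
        rng = np.random.default_rng(0)
        pvals = {s.snp_id: float(p) for s, p in zip(self.snps, rng.random(20))}
        (res,) = gene_enrichment(self.mapping, pvals, self.genes, alpha=0.3)
        n_sig = sum(1 for p in pvals.values() if p <= 0.3)
        assert res.a + res.c == n_sig
        assert res.a + res.b == 3
        assert res.a + res.b + res.c + res.d == 20

    def test_alpha_one_degenerate(self):
        pvals = {s.snp_id: 0.5 for s in self.snps}
        (res,) = gene_enrichment(self.mapping, pvals, self.genes, alpha=1.0)
        # every SNP is "significant": no contrast left, p degenerates to 1
        assert (res.b, res.d) == (0, 0)
        assert (res.a, res.c) == (3, 17)
        assert res.p_value == 1.0

    def test_monotone_in_significant_snps(self):
        """Turning one more mapped SNP significant never raises the gene p."""
        pvals = {s.snp_id: 0.5 for s in self.snps}
        last = 1.1
        for k in (1, 2, 3):
            pvals[f"rs{k}"] = 0.01
            (res,) = gene_enrichment(self.mapping, pvals, self.genes)
            assert res.p_value <= last + 1e-15
            last = res.p_value

    def test_gene_with_no_snps_flagged(self):
        genes = self.genes + [GeneRegion("B", "chr9", 10, 20)]
        mapping = map_snps_to_genes(self.snps, genes, window=0)
        pvals = {s.snp_id: 0.5 for s in self.snps}
        res = {r.entity_id: r for r in gene_enrichment(mapping, pvals, genes)}
        assert res["B"].flagged and res["B"].p_value == 1.0 and res["B"].a == 0

    def test_null_calibration_conservative(self):
        """Random significance labels at rate alpha yield at most ~alpha
        significant genes (Fisher is conservative on discrete tables)."""
        rng = np.random.default_rng(5)
        genes = [
            GeneRegion(f"G{k}", f"chr{k}", 1000, 2000) for k in range(40)
        ]
        snps = [
            _snp(f"{k}_{i}", 1000 + i * 100, chrom=f"chr{k}")
            for k in range(40)
            for i in range(5)
        ]
        mapping = map_snps_to_genes(snps, genes, window=0)
        hits = 0
        n_tests = 0
        for _ in range(25):
            pvals = {s.snp_id: float(rng.random()) for s in snps}
            for r in gene_enrichment(mapping, pvals, genes):
                n_tests += 1
                hits += r.p_value <= 0.05
        # 99% binomial envelope upper bound around 0.05
        rate = hits / n_tests
        assert rate <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n_tests)


class TestSetEnrichment:
    def test_definition_unwinding(self):
        """Universe of 20 genes; set of 5 with 3 significant; 2 significant
        among the other 15 -> Fisher(3, 2, 2, 13)."""
        gene_p = {f"G{i}": 0.5 for i in range(20)}
        for g in ("G0", "G1", "G2", "G5", "G6"):
            gene_p[g] = 0.01
        sets = [GeneSet("S", "s", frozenset({"G0", "G1", "G2", "G3", "G4"}))]
        (res,) = set_enrichment(sets, gene_p)
        assert (res.a, res.b, res.c, res.d) == (3, 2, 2, 13)
        assert res.p_value == pytest.approx(
            float(fisher_oracle(3, 2, 2, 13)), rel=1e-10)

    def test_no_significant_genes(self):
        gene_p = {f"G{i}": 0.5 for i in range(10)}
        sets = [GeneSet("S", "s", frozenset({"G0", "G1"}))]
        (res,) = set_enrichment(sets, gene_p, alpha=0.01)
        assert res.p_value == 1.0

    def test_members_outside_universe_dropped(self):
        gene_p = {"G0": 0.01, "G1": 0.5}
        sets = [GeneSet("S", "s", frozenset({"G0", "UNKNOWN"}))]
        (res,) = set_enrichment(sets, gene_p)
        assert res.a + res.b == 1

    def test_empty_in_universe_flagged(self):
        gene_p = {"G0": 0.01}
        sets = [GeneSet("S", "s", frozenset({"X", "Y"}))]
        (res,) = set_enrichment(sets, gene_p)
        assert res.flagged and res.p_value == 1.0


class TestReplicate:
    def _res(self, eid, p, level="set"):
        return EnrichmentResult(eid, 1, 1, 1, 1, p, level)

    def test_both_cohorts_must_clear_alpha(self):
        det = [self._res("GO:0016831", 0.023), self._res("X", 0.03)]
        rep = [self._res("GO:0016831", 0.043), self._res("X", 0.06)]
        hits = replicate(det, rep, alpha=0.05)
        assert hits == [("GO:0016831", 0.023, 0.043)]

    def test_empty_intersection(self):
        assert replicate([self._res("A", 0.5)], [self._res("A", 0.01)]) == []

    def test_sorted_by_worse_pvalue(self):
        det = [self._res("A", 0.01), self._res("B", 0.02)]
        rep = [self._res("A", 0.04), self._res("B", 0.03)]
        hits = replicate(det, rep)
        assert [h[0] for h in hits] == ["B", "A"]

    def test_mixed_levels_rejected(self):
        with pytest.raises(ValidationError, match="level"):
            replicate([self._res("A", 0.01)], [self._res("A", 0.01, level="gene")])


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(8)
    pvals = {f"e{i}": float(p) for i, p in enumerate(rng.random(25))}
    adj = benjamini_hochberg(pvals)
    keys = list(pvals)
    ref = multipletests([pvals[k] for k in keys], method="fdr_bh")[1]
    for k, r in zip(keys, ref):
        assert adj[k] == pytest.approx(r, rel=1e-12)
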