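"""Synthetic-data generator: penetrance models, HWE genotypes, planted
signal, annotation layout, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from epienrich.simulate import (
    ParameterError,
    SimulationError,
    default_paired_config,
    simulate_annotation,
    simulate_cohort,
    simulate_paired_cohorts,
    snp_panel,
    xor_model,
)
from epienrich.enrichment import map_snps_to_genes
from epienrich.types import PenetranceModel, PlantedPair, SimConfig, ValidationError


class TestXorModel:
    def test_zero_effect_uniform(self):
        m = xor_model(0.3, 0.0, 0.25, 0.25)
        assert np.allclose(m.array, 0.3)
        assert m.marginal_deviation <= 1e-12

    def test_symmetric_half_maf(self):
        """maf = 0.5 gives the plain ±effect checkerboard with flat margins."""
        m = xor_model(0.5, 0.25, 0.5, 0.5)
        t = m.array
        odd = (np.add.outer(np.arange(3), np.arange(3)) % 2).astype(bool)
        assert np.allclose(t[odd], 0.75)
        assert np.allclose(t[~odd], 0.25)
        # hand-computed HWE margins: w = (1/4, 1/2, 1/4) each locus
        w = np.array([0.25, 0.5, 0.25])
        assert np.allclose(w @ t, 0.5) and np.allclose(t @ w, 0.5)
        assert m.marginal_deviation <= 1e-12

    def test_infeasible_raises(self):
        with pytest.raises(ParameterError, match="infeasible"):
            xor_model(0.95, 0.1, 0.5, 0.5)

    def test_unequal_maf_rejected(self):
        with pytest.raises(ParameterError, match="heterozygosity"):
            xor_model(0.5, 0.1, 0.2, 0.4)

    @given(
        maf=st.floats(0.2, 0.5),
        prevalence=st.floats(0.35, 0.65),
        effect=st.floats(0.0, 0.15),
    )
    @settings(max_examples=80, deadline=None)
    def test_margins_always_flat(self, maf, prevalence, effect):
        try:
            m = xor_model(prevalence, effect, maf, maf)
        except ParameterError:
            return
        assert m.marginal_deviation <= 1e-12
        assert m.prevalence == pytest.approx(prevalence, abs=1e-12)


def _null_config(**kw):
    defaults = dict(
        n_cases=150, n_controls=150, n_snps=100, n_genes=5, n_sets=2,
        maf_range=(0.1, 0.5), planted=(), seed=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateCohort:
    def test_determinism(self):
        cfg = default_paired_config(seed=11, n_cases=80, n_controls=80, n_snps=40)
        c1, t1 = simulate_cohort(cfg)
        c2, t2 = simulate_cohort(cfg)
        assert np.array_equal(c1.genotypes, c2.genotypes)
        assert np.array_equal(c1.phenotype, c2.phenotype)
        assert np.array_equal(t1.mafs, t2.mafs)

    def test_quotas(self):
        cfg = default_paired_config(seed=1, n_cases=70, n_controls=30, n_snps=40)
        cohort, _ = simulate_cohort(cfg)
        assert cohort.n_cases == 70
        assert cohort.n_controls == 30

    def test_null_background_hwe(self):
        """Under no planted effect, per-SNP genotype counts follow HWE at the
        drawn MAF (chi-square GoF, alpha = 0.001, ~0.1 expected failures)."""
        cfg = _null_config(n_cases=400, n_controls=400, seed=3)
        cohort, truth = simulate_cohort(cfg)
        failures = 0
        for j in range(cohort.n_snps):
            counts = np.bincount(cohort.genotypes[:, j], minlength=3)
            expected = PenetranceModel.hwe_weights(truth.mafs[j]) * cohort.n_samples
            if chisquare(counts, expected).pvalue < 0.001:
                failures += 1
        assert failures <= 3

    def test_null_effect_no_association(self):
        """effect = 0: case/control allele-frequency differences are noise."""
        model = xor_model(0.5, 0.0, 0.3, 0.3)
        planted = (PlantedPair(model, (2, 7), ("G1", "G2"), "S1"),)
        cfg = _null_config(n_cases=500, n_controls=500, n_snps=20, planted=planted, seed=4)
        cohort, _ = simulate_cohort(cfg)
        case_f = cohort.genotypes[cohort.phenotype == 1].mean(axis=0) / 2
        ctrl_f = cohort.genotypes[cohort.phenotype == 0].mean(axis=0) / 2
        # each difference ~ N(0, ~sqrt(pq/n)); 5 sigma bound with pq<=0.25
        assert np.abs(case_f - ctrl_f).max() < 5 * np.sqrt(0.25 / 500)

    def test_planted_checkerboard_cell_ratios(self):
        """Planted XOR pair: per-cell case fraction tracks the penetrance
        table (retrospective sampling at prevalence 0.5 keeps them equal)."""
        cfg = default_paired_config(seed=8, n_cases=2000, n_controls=2000, n_snps=20,
                                    effect=0.3, maf=0.3)
        cohort, truth = simulate_cohort(cfg)
        (ia, ib) = truth.planted[0].snp_indices
        table = truth.planted[0].model.array
        ga, gb = cohort.genotypes[:, ia], cohort.genotypes[:, ib]
        for a in range(3):
            for b in range(3):
                mask = (ga == a) & (gb == b)
                n = mask.sum()
                if n < 30:
                    continue
                frac = cohort.phenotype[mask].mean()
                # binomial error on the cell fraction, 5 sigma
                assert abs(frac - table[a, b]) < 5 * np.sqrt(0.25 / n)

    def test_background_independent_of_phenotype(self):
        cfg = default_paired_config(seed=2, n_cases=1500, n_controls=1500, n_snps=30)
        cohort, truth = simulate_cohort(cfg)
        planted = set(truth.planted[0].snp_indices)
        case_f = cohort.genotypes[cohort.phenotype == 1].mean(axis=0) / 2
        ctrl_f = cohort.genotypes[cohort.phenotype == 0].mean(axis=0) / 2
        diffs = np.abs(case_f - ctrl_f)
        for j in range(30):
            if j not in planted:
                assert diffs[j] < 5 * np.sqrt(0.25 / 1500)

    def test_draw_budget_error(self):
        model = xor_model(0.98, 0.0, 0.3, 0.3)  # controls are 2% of draws
        planted = (PlantedPair(model, (0, 1), ("G1", "G2"), "S1"),)
        cfg = SimConfig(n_cases=2, n_controls=400, n_snps=10, n_genes=2,
                        planted=planted, seed=0, max_draw_factor=1)
        with pytest.raises(SimulationError, match="draw"):
            simulate_cohort(cfg)

    def test_ld_mode_correlates_adjacent_background(self):
        cfg = _null_config(n_cases=500, n_controls=500, n_snps=30, ld_decay=0.8, seed=6)
        cohort, _ = simulate_cohort(cfg)
        G = cohort.genotypes.astype(float)
        r_adj = np.array([
            np.corrcoef(G[:, j], G[:, j + 1])[0, 1] for j in range(0, 29)
        ])
        assert np.median(r_adj) > 0.5
        cfg0 = _null_config(n_cases=500, n_controls=500, n_snps=30, ld_decay=0.0, seed=6)
        G0 = simulate_cohort(cfg0)[0].genotypes.astype(float)
        r0 = np.array([np.corrcoef(G0[:, j], G0[:, j + 1])[0, 1] for j in range(0, 29)])
        assert np.abs(np.median(r0)) < 0.2


class TestAnnotation:
    def test_truth_set_contains_planted_genes(self):
        cfg = default_paired_config(seed=0, n_sets=2)
        genes, sets, ann = simulate_annotation(cfg, snp_panel(cfg))
        truth = next(s for s in sets if s.set_id == "S1")
        assert truth.members == {"G1", "G2"}
        assert len(sets) == 2

    def test_every_gene_covers_a_snp(self):
        cfg = default_paired_config(seed=0)
        snps = snp_panel(cfg)
        genes, _, _ = simulate_annotation(cfg, snps)
        for g in genes:
            assert any(
                s.chrom == g.chrom and g.start <= s.pos <= g.stop for s in snps
            )

    def test_planted_snps_within_window_of_their_genes(self):
        cfg = default_paired_config(seed=0)
        snps = snp_panel(cfg)
        genes, _, _ = simulate_annotation(cfg, snps)
        mapping = map_snps_to_genes(snps, genes, window=500_000)
        for pp in cfg.planted:
            for idx, gid in zip(pp.snp_indices, pp.gene_ids):
                assert gid in mapping.genes_for(snps[idx].snp_id)

    def test_window_arithmetic(self):
        """At the default 400 kb grid each gene's +-500 kb window holds
        exactly 3 SNPs; the rest of its block stays intergenic."""
        cfg = default_paired_config(seed=0)
        snps = snp_panel(cfg)
        genes, _, _ = simulate_annotation(cfg, snps)
        mapping = map_snps_to_genes(snps, genes, window=500_000)
        for g in genes:
            assert len(mapping.snps_for_gene(g.gene_id)) == 3

    def test_no_planted_pairs_still_valid(self):
        cfg = _null_config()
        genes, sets, ann = simulate_annotation(cfg, snp_panel(cfg))
        assert len(genes) == cfg.n_genes
        assert len(sets) == cfg.n_sets
        assert ann.truth_sets == [] and ann.truth_genes == []

    def test_layout_infeasible(self):
        with pytest.raises(ValidationError, match="layout|genes"):
            simulate_annotation(
                _null_config(n_snps=3, n_genes=5), snp_panel(_null_config(n_snps=3, n_genes=5))
            )


class TestPairedCohorts:
    def test_same_seed_identical_pair(self):
        cfg = default_paired_config(seed=5, n_cases=60, n_controls=60, n_snps=40)
        d1, r1, _, _ = simulate_paired_cohorts(cfg)
        d2, r2, _, _ = simulate_paired_cohorts(cfg)
        assert np.array_equal(d1.genotypes, d2.genotypes)
        assert np.array_equal(r1.genotypes, r2.genotypes)

    def test_cohorts_are_independent_draws(self):
        cfg = default_paired_config(seed=5, n_cases=60, n_controls=60, n_snps=40)
        det, rep, _, _ = simulate_paired_cohorts(cfg)
        assert det.genotypes.shape[0] == 120
        assert rep.genotypes.shape[0] == 60  # default half sizes
        assert not np.array_equal(det.genotypes[:60], rep.genotypes)

    def test_planted_pair_elevated_in_both_cohorts(self):
        """The planted pair's MDR statistic clears the null-pair range in
        detection AND replication."""
        from epienrich.mdr import pairwise_scan

        cfg = default_paired_config(seed=13, n_snps=60)
        det, rep, _, truth = simulate_paired_cohorts(cfg)
        ia, ib = truth.planted[0].snp_indices
        pa, pb = f"rs{ia + 1}", f"rs{ib + 1}"
        for cohort in (det, rep):
            results = pairwise_scan(cohort)
            planted = [r for r in results if (r.snp_i, r.snp_j) == (pa, pb)]
            nulls = [r.statistic for r in results if (r.snp_i, r.snp_j) != (pa, pb)]
            assert planted[0].statistic > np.quantile(nulls, 0.999)
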