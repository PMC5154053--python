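"""Synthetic paired case–control cohorts with planted epistatic SNP pairs.

The generator emulates the statistical skeleton of a two-cohort GWAS: HWE
genotypes at per-SNP minor-allele frequencies, retrospective case/control
ascertainment (quota sampling), a planted SNP pair whose penetrance table is
purely epistatic (flat single-locus margins, so only a pairwise method can
see it), SNPs positioned on synthetic chromosomes, genes over those
positions, and genes grouped into one ground-truth set plus decoys.

Randomness: one ``numpy`` Generator seeded from ``SimConfig.seed``; draws
happen in a fixed documented order (per-cohort: the planted-pair
genotype/status rejection stream until the case and control quotas fill,
then the background genotype matrix column-block by column-block), so the
entire output is a pure function of the config.  For paired cohorts the MAF
vector is drawn once and shared; detection and replication genotypes are
independent streams.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .types import (
    Annotation,
    CohortData,
    GeneRegion,
    GeneSet,
    GroundTruth,
    PenetranceModel,
    PlantedPair,
    SimConfig,
    SnpRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    """Rejection sampling exhausted its draw budget."""


class ParameterError(ValueError):
    """A penetrance model parameterisation is infeasible."""


# ---------------------------------------------------------------------------
# Penetrance models
# ---------------------------------------------------------------------------


def xor_model(
    prevalence: float, effect: float, maf_a: float, maf_b: float
) -> PenetranceModel:
    """Purely epistatic checkerboard (XOR) penetrance table.

    Odd-parity genotype cells (minor-allele dosages summing to an odd number)
    get penetrance ``prevalence + effect``; even cells are lowered so that
    *both* single-locus HWE penetrance margins equal the prevalence exactly:
    corner cells (dosage 0 or 2 at both loci) get ``prevalence −
    effect·h/(1−h)`` and the double-heterozygote ``prevalence −
    effect·(1−h)/h``, where ``h = 2·maf·(1−maf)`` is the heterozygosity.
    The margin constraints of the two loci are jointly solvable with a
    uniform odd-cell effect only when the loci share a heterozygosity, so
    unequal MAFs raise :class:`ParameterError`.

    At ``maf = 0.5`` this is the classic ±effect checkerboard; ``effect = 0``
    gives the uniform no-signal table.
    """
    if not 0 <= prevalence <= 1:
        raise ParameterError(f"prevalence must lie in [0, 1], got {prevalence}")
    if effect < 0:
        raise ParameterError(f"effect must be non-negative, got {effect}")
    for q, name in ((maf_a, "maf_a"), (maf_b, "maf_b")):
        if not 0 < q <= 0.5:
            raise ParameterError(f"{name} must lie in (0, 0.5], got {q}")
    h_a = 2 * maf_a * (1 - maf_a)
    h_b = 2 * maf_b * (1 - maf_b)
    if abs(h_a - h_b) > 1e-12 and effect > 0:
        raise ParameterError(
            "exact flat margins with a uniform odd-cell effect require equal "
            f"heterozygosity at both loci (maf_a={maf_a}, maf_b={maf_b})"
        )
    h = h_a
    table = np.full((3, 3), prevalence, dtype=np.float64)
    if effect > 0:
        odd = (np.add.outer(np.arange(3), np.arange(3)) % 2).astype(bool)
        table[odd] = prevalence + effect
        corners = ~odd
        corners[1, 1] = False
        table[corners] = prevalence - effect * h / (1 - h)
        table[1, 1] = prevalence - effect * (1 - h) / h
    if (table < 0).any() or (table > 1).any():
        raise ParameterError(
            f"infeasible XOR model: penetrance outside [0, 1] "
            f"(prevalence={prevalence}, effect={effect}, maf={maf_a}); "
            "reduce the effect or move prevalence toward 0.5"
        )
    model = PenetranceModel(tuple(map(tuple, table.tolist())), maf_a, maf_b)
    assert model.marginal_deviation <= 1e-12
    return model


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _hwe_draw(rng: np.random.Generator, maf: np.ndarray, n: int) -> np.ndarray:
    """HWE genotype draws: dosage ~ Binomial(2, maf) per SNP, iid samples."""
    return rng.binomial(2, maf, size=(n, maf.size)).astype(np.int8)


def _layout_blocks(config: SimConfig) -> list[np.ndarray]:
    """Contiguous SNP-index blocks, one per gene/chromosome."""
    if config.n_genes > config.n_snps:
        raise ValidationError("layout infeasible: more genes than SNPs")
    return np.array_split(np.arange(config.n_snps), config.n_genes)


def snp_panel(config: SimConfig) -> list[SnpRecord]:
    """SNP records on the synthetic genome: one chromosome per gene block,
    positions on a uniform ``snp_spacing`` grid starting at ``snp_spacing``."""
    records: list[SnpRecord] = []
    for g, block in enumerate(_layout_blocks(config)):
        for k, idx in enumerate(block):
            records.append(
                SnpRecord(f"rs{idx + 1}", f"chr{g + 1}", (k + 1) * config.snp_spacing)
            )
    return records


def _penetrance_for(
    planted: tuple[PlantedPair, ...], genotype_draws: np.ndarray
) -> np.ndarray:
    """Per-individual disease probability from the planted pairs.

    One pair: its table directly.  Several pairs combine multiplicatively on
    the relative-risk scale, f = prev·Π(f_k/prev_k), clipped to [0, 1] —
    with purely epistatic factors and independent pair genotypes the
    single-locus margins stay flat.
    """
    if not planted:
        raise ValidationError("penetrance undefined without planted pairs")
    if len(planted) == 1:
        t = planted[0].model.array
        return t[genotype_draws[:, 0], genotype_draws[:, 1]]
    prevs = [pp.model.prevalence for pp in planted]
    base = float(np.mean(prevs))
    f = np.full(genotype_draws.shape[0], base)
    for k, pp in enumerate(planted):
        t = pp.model.array
        fk = t[genotype_draws[:, 2 * k], genotype_draws[:, 2 * k + 1]]
        f = f * fk / prevs[k]
    return np.clip(f, 0.0, 1.0)


def _draw_mafs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-SNP MAFs ~ U(maf_range); planted columns pinned to their model MAFs."""
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_snps)
    for pp in config.planted:
        ia, ib = pp.snp_indices
        mafs[ia] = pp.model.maf_a
        mafs[ib] = pp.model.maf_b
    return mafs


def _simulate_one(
    config: SimConfig,
    mafs: np.ndarray,
    rng: np.random.Generator,
    n_cases: int,
    n_controls: int,
    cohort_id: str,
    snps: list[SnpRecord],
) -> CohortData:
    n = n_cases + n_controls
    planted_idx = [i for pp in config.planted for i in pp.snp_indices]
    planted_set = set(planted_idx)

    if config.planted:
        planted_mafs = np.array([mafs[i] for i in planted_idx])
        budget = config.max_draw_factor * n
        drawn = 0
        batch = max(256, 4 * n)
        kept_g: list[np.ndarray] = []
        kept_y: list[int] = []
        need_case, need_ctrl = n_cases, n_controls
        while need_case > 0 or need_ctrl > 0:
            if drawn >= budget:
                raise SimulationError(
                    f"rejection sampling used {drawn} draws without filling the "
                    f"case/control quotas; increase effect size, move prevalence "
                    "toward 0.5, or raise max_draw_factor"
                )
            g = _hwe_draw(rng, planted_mafs, batch)
            f = _penetrance_for(config.planted, g)
            is_case = rng.random(batch) < f
            drawn += batch
            for r in range(batch):
                if is_case[r] and need_case > 0:
                    kept_g.append(g[r])
                    kept_y.append(1)
                    need_case -= 1
                elif not is_case[r] and need_ctrl > 0:
                    kept_g.append(g[r])
                    kept_y.append(0)
                    need_ctrl -= 1
                if need_case == 0 and need_ctrl == 0:
                    break
        planted_G = np.vstack(kept_g)
        phenotype = np.array(kept_y, dtype=np.uint8)
    else:
        planted_G = np.empty((n, 0), dtype=np.int8)
        phenotype = np.concatenate(
            [np.ones(n_cases, dtype=np.uint8), np.zeros(n_controls, dtype=np.uint8)]
        )

    # Background genotypes: independent of phenotype by construction.
    G = np.empty((n, config.n_snps), dtype=np.int8)
    background = [j for j in range(config.n_snps) if j not in planted_set]
    if background:
        bg = _hwe_draw(rng, mafs[background], n)
        if config.ld_decay > 0:
            # block LD: within a column block, a sample copies its previous
            # background SNP's genotype with probability ld_decay
            for col in range(1, len(background)):
                if background[col] - 1 == background[col - 1]:
                    copy = rng.random(n) < config.ld_decay
                    bg[copy, col] = bg[copy, col - 1]
        G[:, background] = bg
    for k, j in enumerate(planted_idx):
        G[:, j] = planted_G[:, k]

    return CohortData(
        genotypes=G, phenotype=phenotype, snps=snps, cohort_id=cohort_id
    )


def simulate_cohort(config: SimConfig) -> tuple[CohortData, GroundTruth]:
    """One case–control cohort drawn from the config's generating model."""
    rng = np.random.default_rng(config.seed)
    mafs = _draw_mafs(config, rng)
    snps = snp_panel(config)
    cohort = _simulate_one(
        config, mafs, rng, config.n_cases, config.n_controls, config.cohort_id, snps
    )
    return cohort, GroundTruth(planted=config.planted, mafs=mafs)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def simulate_annotation(
    config: SimConfig, snps: list[SnpRecord]
) -> tuple[list[GeneRegion], list[GeneSet], Annotation]:
    """Gene regions and gene sets over the synthetic genome.

    One gene per chromosome block, its body (``gene_length`` bp) centred on
    the block's middle SNP, so every gene covers at least one SNP and — at
    the default 400 kb grid — its ±500 kb window captures exactly the three
    central SNPs of the block while the rest of the block stays intergenic.
    Genes holding a planted SNP take the planted pair's designated gene ids;
    the designated set contains those genes and the remaining genes fill the
    decoy sets round-robin.
    """
    blocks = _layout_blocks(config)
    if any(len(b) == 0 for b in blocks):
        raise ValidationError("layout infeasible: a gene block holds no SNPs")
    if len(snps) != config.n_snps:
        raise ValidationError("SNP panel size does not match config.n_snps")
    by_index = dict(enumerate(snps))  # panel is in global SNP-index order
    # designated gene id per block, from planted pairs
    block_names: dict[int, str] = {}
    truth_genes: list[str] = []
    for pp in config.planted:
        for idx, gid in zip(pp.snp_indices, pp.gene_ids):
            blk = next(g for g, b in enumerate(blocks) if idx in b)
            if blk in block_names and block_names[blk] != gid:
                raise ValidationError(
                    f"planted SNPs designate conflicting genes for block {blk}"
                )
            block_names[blk] = gid
            truth_genes.append(gid)

    genes: list[GeneRegion] = []
    for g, block in enumerate(blocks):
        mid = block[len(block) // 2]
        center = by_index[int(mid)].pos
        chrom = by_index[int(mid)].chrom
        start = max(1, center - config.gene_length // 2)
        stop = start + config.gene_length - 1
        genes.append(GeneRegion(block_names.get(g, f"G{g + 1}"), chrom, start, stop))

    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError("gene ids collide; pick distinct designated gene ids")

    # verify every planted SNP sits inside (or within 500 kb of) its gene
    from .enrichment import DEFAULT_WINDOW

    for pp in config.planted:
        for idx, gid in zip(pp.snp_indices, pp.gene_ids):
            s = snps[idx]
            gene = next(g for g in genes if g.gene_id == gid)
            if not (
                gene.chrom == s.chrom
                and gene.start - DEFAULT_WINDOW <= s.pos <= gene.stop + DEFAULT_WINDOW
            ):
                raise ValidationError(
                    f"planted SNP {s.snp_id} falls outside the window of gene {gid}"
                )

    truth_set_ids = sorted({pp.set_id for pp in config.planted})
    n_decoys = config.n_sets - len(truth_set_ids)
    if n_decoys < 0:
        raise ValidationError("n_sets smaller than the number of designated truth sets")
    sets: list[GeneSet] = []
    for sid in truth_set_ids:
        members = frozenset(
            gid for pp in config.planted if pp.set_id == sid for gid in pp.gene_ids
        )
        sets.append(GeneSet(sid, f"planted set {sid}", members))
    decoy_pool = [gid for gid in gene_ids if gid not in set(truth_genes)]
    if n_decoys > 0:
        if len(decoy_pool) < n_decoys:
            raise ValidationError("not enough non-planted genes to populate decoy sets")
        buckets: list[list[str]] = [[] for _ in range(n_decoys)]
        for k, gid in enumerate(decoy_pool):
            buckets[k % n_decoys].append(gid)
        for k, bucket in enumerate(buckets):
            sets.append(GeneSet(f"DECOY{k + 1}", f"decoy set {k + 1}", frozenset(bucket)))

    annotation = Annotation(
        genes=genes, sets=sets, truth_sets=truth_set_ids, truth_genes=sorted(set(truth_genes))
    )
    return genes, sets, annotation


# ---------------------------------------------------------------------------
# Paired cohorts
# ---------------------------------------------------------------------------


def simulate_paired_cohorts(
    config: SimConfig,
    replication_fraction: float = 0.5,
) -> tuple[CohortData, CohortData, Annotation, GroundTruth]:
    """Detection + replication cohorts from one generating model.

    Both cohorts share the SNP panel, the MAF vector, the planted models and
    the annotation; genotype and phenotype draws are independent.  The
    replication cohort defaults to half the detection sizes, mirroring the
    roughly 2:1 detection:replication design of two-stage GWAS.
    """
    if not 0 < replication_fraction <= 1:
        raise ValidationError("replication_fraction must lie in (0, 1]")
    ss = np.random.SeedSequence(config.seed)
    rng_maf, rng_det, rng_rep = (np.random.default_rng(s) for s in ss.spawn(3))
    mafs = _draw_mafs(config, rng_maf)
    snps = snp_panel(config)
    detection = _simulate_one(
        config, mafs, rng_det, config.n_cases, config.n_controls,
        f"{config.cohort_id}_detection", snps,
    )
    n_ca = max(1, round(config.n_cases * replication_fraction))
    n_co = max(1, round(config.n_controls * replication_fraction))
    replication = _simulate_one(
        config, mafs, rng_rep, n_ca, n_co, f"{config.cohort_id}_replication", snps
    )
    _, _, annotation = simulate_annotation(config, snps)
    truth = GroundTruth(planted=config.planted, mafs=mafs, annotation=annotation)
    return detection, replication, annotation, truth


def default_paired_config(
    seed: int = 0,
    effect: float = 0.3,
    maf: float = 0.3,
    prevalence: float = 0.5,
    n_cases: int = 500,
    n_controls: int = 500,
    n_snps: int = 200,
    n_genes: int = 10,
    n_sets: int = 4,
    ld_decay: float = 0.0,
) -> SimConfig:
    """Study-condition config: one planted XOR pair in genes G1/G2, set S1.

    The planted SNPs sit at the centres of the first two gene blocks, inside
    their genes' bodies.  Detection totals ``n_cases + n_controls`` samples;
    :func:`simulate_paired_cohorts` halves both quotas for replication.
    """
    if n_genes < 2:
        raise ValidationError("need at least 2 genes to host a planted pair")
    block = n_snps // n_genes
    model = xor_model(prevalence, effect, maf, maf)
    planted = (
        PlantedPair(
            model=model,
            snp_indices=(block // 2, block + block // 2),
            gene_ids=("G1", "G2"),
            set_id="S1",
        ),
    ) if effect >= 0 else ()
    return SimConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        n_snps=n_snps,
        maf_range=(0.05, 0.5),
        planted=planted,
        n_genes=n_genes,
        n_sets=n_sets,
        seed=seed,
        ld_decay=ld_decay,
    )
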