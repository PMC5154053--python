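# Methods

## The statistic

For SNPs *i*, *j* with minor-allele dosages `g ∈ {0,1,2}` and binary
phenotype, the two-locus table has 9 cells. With `n_ca` cases and `n_co`
controls usable for the pair, cell *g* is labelled **high-risk** when

    cases(g) / controls(g) ≥ n_ca / n_co,

evaluated by integer cross-multiplication (so a cell with cases and no
controls is high, and a ratio exactly at the threshold is high — fixed
tie-break for reproducibility). Cells with no samples are empty and
contribute nothing. The pair's score is the balanced accuracy of the rule
"predict case in high cells":

    BA = ½ · (TP / n_ca + TN / n_co),

robust to case:control imbalance because each class is weighted equally.

Two properties shape everything downstream:

* **BA is computed on the full cohort, not cross-validated.** The labelling
  step adapts to noise, so null pairs score above 0.5 on average
  (finite-sample overfitting). Significance must therefore come from a
  procedure that reproduces the same bias under the null — which the
  phenotype-permutation test does exactly, since the permuted scans rerun the
  identical labelling-plus-scoring pipeline. A cross-validated variant is
  deliberately out of scope.
* **Missing genotypes are handled per pair** (complete-case): a sample
  missing at either SNP is dropped from that pair's table only, and the
  labelling threshold uses the pair's own complete-case totals. This avoids
  global sample loss at the cost of slightly different universes per pair.

Monomorphic SNPs are not removed; their genotype dimension simply collapses
to one row of the table. An optional MAF filter exists but is off by
default — the pipeline applies no marker QC unless asked.

## Permutation significance

Labels are permuted uniformly (case/control totals conserved), the whole
exhaustive scan is rerun per permutation, and the same permutation serves
every pair — preserving the between-pair dependence a dataset-wide
permutation test has. Empirical p-values use the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + N)`, so `p > 0` always and the p-value
is monotone non-increasing in the statistic. Each SNP then receives the
p-value of its strongest pair, which (with a null shared across pairs)
equals the minimum p over its pairs.

Two nulls are available:

* **pooled** (library default): every pair's statistic from every
  permutation forms one empirical null, giving per-pair p-values with
  resolution `1/(N_perm · n_pairs + 1)`. This treats all pairs as
  exchangeable — an approximation when MAFs vary widely, exact in aggregate.
* **max** (family-wise): only each permutation's maximum statistic is kept;
  a pair's p-value is the probability that *any* null pair scores as high.

**Which to use depends on the panel size.** The per-SNP p-value is a minimum
over (m−1) pair p-values. Under the pooled null those are marginally
~uniform, so for a panel of a few hundred SNPs nearly every SNP clears a 0.05
screen and the enrichment phases lose all contrast; the pooled screen is the
right liberal filter only when m is large enough (hundreds of thousands)
that resolution near 0.05 matters and the dichotomy stays informative. At
the desk scales this package's simulations run, the family-wise null is the
screen that preserves contrast, so the synthetic end-to-end analyses and the
acceptance script use `mode="max"`; the pooled default remains for
full-scale screening use.

**Discreteness makes p-values conservative, never liberal.** BA takes values
on a grid (spacing `1/n` for balanced cohorts), the null has large atoms, and
ties count toward `#{null ≥ observed}`; together with the add-one estimator
this gives `P(p ≤ t) ≤ t` under the null, with visible shortfall where an
atom straddles the threshold (e.g. measured rejection rates of 2–4.5% at the
nominal 5% level on null cohorts of n = 400). Calibration tests therefore
check uniformity (KS) and one-sided validity of the rejection rate; a
two-sided check against exact uniformity would reject the estimator's own
guaranteed conservativity. Note also that *per-SNP* p-values (minima over
dependent pairs) are not uniform under the null by construction; calibration
is a pair-level property, and pairs sharing a SNP are dependent, so the
tests assert it on SNP-disjoint pairs where independence is exact.

## Enrichment

* **Mapping**: a SNP belongs to a gene when it lies on the same chromosome
  (labels compared with an optional `chr` prefix stripped) within
  `gene.start − w ≤ pos ≤ gene.stop + w`, `w` = 500 kb by default, boundaries
  inclusive and strand ignored. A SNP may map to several genes.
* **Gene test**: universe = all SNPs with a p-value (including unmapped ones,
  which inform the background rate). For gene G the 2×2 is
  significant/non-significant × inside/outside; a multi-mapped SNP is
  "inside" for each of its genes' tests but counts once per universe. Genes
  whose window holds no SNP are emitted flagged with p = 1.
* **Set test**: same dichotomy over genes with gene-level p-values; set
  members outside that universe are dropped with a log entry.
* **Fisher right tail** is computed from log-gamma binomial coefficients
  (`p = Σ_{k ≥ a} C(r₁,k)·C(r₂,c₁−k) / C(n,c₁)`), accurate to ~1e-14
  relative against exact rational enumeration over all tables with n ≤ 30.
* **Replication**: an entity is reported when its enrichment p ≤ α in both
  cohorts, sorted by the worse of the two p-values. No multiple-testing
  correction is applied at any level by default (a Benjamini–Hochberg
  helper exists); the screen's guard against false positives is the
  permutation test plus the two-cohort replication requirement itself.

## The synthetic generator

The generator emulates the statistical skeleton the analysis assumes — it is
the ground-truth instrument for the tests, not a population-genetics
simulator.

* **Genotypes**: HWE dosages, `g ~ Binomial(2, q)`, per-SNP MAF
  `q ~ U(0.05, 0.5)`, independent across SNPs by default. An optional
  block-LD mode copies the previous SNP's genotype with probability
  `ld_decay` per sample, since real SNP panels are locally correlated and the
  pipeline deliberately does not adjust for that.
* **Planted pair**: an XOR penetrance table. Odd-parity cells get
  `prevalence + effect`; even cells are lowered so both single-locus HWE
  margins equal the prevalence exactly (corners by `effect·h/(1−h)`, the
  double-heterozygote by `effect·(1−h)/h`, with `h = 2q(1−q)`). The margin
  constraints admit a uniform odd-cell effect only when both loci share a
  heterozygosity, so the constructor requires equal MAFs and verifies
  marginal deviation ≤ 1e-12 — pure epistasis, invisible to single-locus
  tests. Defaults: prevalence 0.5, effect 0.3, MAF 0.3 (feasibility requires
  `prevalence ≥ effect·(1−h)/h`; 0.5 comfortably clears it at MAF 0.3).
* **Ascertainment**: retrospective quota sampling — individuals are drawn
  (planted genotypes, then disease status from the penetrance), kept until
  the case and control quotas fill, and only then given background genotypes,
  which are therefore phenotype-independent by construction. Default sizes:
  500 cases + 500 controls for detection, half of each for replication,
  mirroring the ~2:1 two-stage design the pipeline targets.
* **Genome layout**: one synthetic chromosome per gene; each gene's block of
  SNPs sits on a 400 kb grid with a 100 kb gene body centred on the block, so
  a ±500 kb window maps exactly the three central SNPs and the rest of the
  block stays intergenic (but inside the enrichment universe). The geometry
  is chosen so that one truly associated SNP is a detectable overabundance at
  desk scale: with 2 significant SNPs among 200 and 3 mapped SNPs per gene,
  the planted gene's Fisher p is ≈ 0.030 (and still 0.045 with one stray
  significant SNP), while a decoy set needs ≥ 2 significant member genes to
  reach 0.05. The planted SNPs are the central (gene-body) SNPs of the first
  two blocks; their genes form the ground-truth set, remaining genes fill
  decoy sets round-robin.
* **Determinism**: one seed; draws occur in a documented order (MAF vector,
  rejection stream, background matrix), and paired cohorts use three child
  streams spawned from the seed, so the entire output is a pure function of
  the configuration.

What the generator does **not** emulate: realistic LD maps, population
stratification, genotyping error, covariates, allele-frequency differences
between cohorts, or marginal-effect loci. Passing tests demonstrate that the
pipeline recovers a planted interaction under its own model assumptions —
not that it is powered for any particular real architecture.

## Numerical and engineering choices

* The exhaustive scan one-hot-encodes genotypes and obtains all 9 cell
  counts for all pairs as matrix products; permutations reuse the
  phenotype-free totals, so each permutation costs ten small GEMMs. Counts
  stay below 2²⁴, so float32 accumulation and the cross-multiplied threshold
  comparison are exact; final divisions are float64, making the vectorized
  statistic bit-identical to the per-pair definitional code (asserted
  exactly against a brute-force per-sample oracle in the tests).
* Pair enumeration is lexicographic (i < j); best-per-SNP ties break to the
  lexicographically smallest partner; result tables sort by (p, identifier);
  degenerate pairs (no usable case or control) are skipped and logged, and
  propagate as absent rather than NaN.
* Test and acceptance problem sizes (panels of 30–200 SNPs, cohorts of
  400–1500 samples, 50–200 permutations, 10–30 replicate simulations) were
  chosen as the smallest sizes at which the planted signal, the null
  calibration, and the enrichment geometry are all comfortably resolved.

## Limitations

Only pairwise interactions are scanned (higher orders face the usual
dimensionality explosion); the statistic is the resubstitution balanced
accuracy, valid for permutation inference but not an unbiased effect
estimate; the pooled null treats pairs as exchangeable across MAFs; SNP
correlation within gene windows is not corrected for; and the α = 0.05
screens at every level are liberal by design, relying on replication rather
than per-level error control.
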