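# Methods

This note documents the models, estimators and numerical choices behind
`crypticsex`, the assumptions they rest on, and what the simulation-based
tests do and do not demonstrate about real data.

## 1. Data model and filtering

Genotypes live in a samples × sites matrix of alternate-allele dosages
(0/1/2; −1 for a missing call) with per-site metadata (linkage group,
1-based bp position, alleles, total depth) and optional per-call genotype
quality (GQ) and allele depths (AD). Sites are kept sorted by (chromosome,
position), without duplicates; missing calls are excluded from every
numerator *and* denominator downstream.

Filter order is fixed and matters:

1. **Genotype-quality masking** — calls with quality ≤ `qual_min` (default
   30) set missing. Per-call GQ is used when present, falling back to the
   record QUAL otherwise; the threshold is applied at call level because
   quality describes the genotype call, and site-level-only VCFs still
   behave sensibly through the fallback.
2. **Site depth** — sites kept iff `dp_min` < DP < `dp_max` (defaults 8 and
   200, strict inequalities; DP = the record's INFO depth). Sites without a
   DP annotation are kept.
3. **Biallelic SNPs** — exactly one alternate allele and single-nucleotide
   ref/alt. Multiallelic records are retained by the reader (flagged via
   `n_alt`) so the removal is attributable to this rule, not to parsing.
4. **Missingness** — sites kept iff ≥ 75 % of calls are non-missing
   (`max_missing_frac=0.25`, the vcftools convention). Quality masking must
   precede this rule because masking changes missingness.

Filtering is idempotent, and the per-rule removal counts in the
`FilterReport` sum exactly to (sites in − sites out). MNP decomposition is
out of scope: input VCFs are assumed pre-decomposed to SNPs.

## 2. Clonal structure

**Distances.** Euclidean distance on dosage vectors with missing-data
rescaling: d(i,j) = √(Σ_shared (xᵢ−xⱼ)² · S/sᵢⱼ), where sᵢⱼ counts sites
called in both samples and S is the total. The rescaling makes distances
comparable between pairs with different missingness (the convention of
`dist`-on-incomplete-data implementations). Pairs sharing no called site
are flagged undefined rather than silently zero.

**Neighbour joining.** Classic Saitou–Nei agglomeration with the final
three-point trifurcation. Negative branch lengths are clamped to zero with
the excess transferred to the sister branch, preserving path lengths
through the joined node. On additive matrices the generating tree is
recovered exactly (verified to 1e-10 against tip-to-tip distances computed
by scikit-bio from the emitted newick). The output is an unrooted newick
tree plus the distance matrix; split networks are out of scope — any
network viewer can be fed the same distance matrix.

**Clone assignment.** Single-linkage clustering: two samples share a
lineage iff connected by a chain of distances each ≤ the threshold. The
automatic threshold takes the *largest gap* in the sorted pairwise
distances with zero prepended as a virtual lower bound, and cuts at its
midpoint. Rationale: a clonal population is bimodal — mutation-scale
distances within lineages, divergence-scale between — and the widest gap
separates the modes *wherever the lineage sizes fall* (a largest-gap-below-
the-median variant was tried first and shatters clones whenever one clone
dominates the sample, because the median then sits at mutation scale). In a
fully sexual population all distances form a tight clump far from zero, so
the widest gap is [0, min) and every genotype stays separate. The threshold
used is always reported; it is a heuristic, and for borderline data a fixed
cutoff can be supplied instead.

The classifier's genotype-diversity criterion uses the number of
*lineages*, not exact distinct genotypes: under realistic mutation nearly
every individual carries some private mutation, so exact-genotype counts
saturate at the sample size even in strictly clonal populations. Both
counts are reported.

## 3. Linkage disequilibrium

**r² estimator.** For two biallelic sites, r² = D²/(p_A p_a p_B p_b) with
D = p_AB − p_A p_B, where the two-locus haplotype frequencies are the
maximum-likelihood estimates from unphased diploid genotypes under random
union of gametes: the 3×3 genotype table determines all haplotype counts
except the double-heterozygote phase, which EM resolves by iterating the
expected coupling fraction w = p_AB p_ab / (p_AB p_ab + p_Ab p_aB)
(convergence when haplotype-frequency changes fall below 1e-10; cap 1000
iterations). This matches the default estimator of plink 1.9, the field's
reference implementation. Properties maintained: symmetry in the two loci,
invariance to allele relabelling, exact equality with direct
haplotype-count r² when no double heterozygotes exist, and agreement to
≤ 1e-4 with a brute-force likelihood grid search on random tables. A
genotype-correlation shortcut (`method="corr"`) is provided for comparison
only. Pairs monomorphic within the complete-call subset are undefined
(NaN), never zero. The implementation is vectorized across pairs, so full
scans of ~10⁵–10⁶ pairs take seconds.

**Pair enumeration.** Sites at minor allele frequency > 0.2 (computed on
called genotypes) enter the scan. Within-chromosome pairs are exhaustive up
to 8 Mb separation (no per-window pair cap); between-chromosome pairs are
exhaustive up to a cap (library default 2×10⁶; the end-to-end
`analyze_population` uses 2×10⁵) beyond which a seeded uniform subsample is
taken — the expectation is identical and the runtime bounded. Sites on the
X chromosome or unplaced contigs are excluded by default (the X's
coordinates are unreliable in the reference assemblies this emulates, and
in the simulator it only determines sex); `include_x` re-admits them to the
between-chromosome pool.

**Summaries.** Per within-chromosome stratum, pooled within, and pooled
between: mean r², SE = sd/√n, and the mean ± 2·SE interval (an approximate
95 % CI). Strata with one pair report the mean with undefined SE; empty
strata are absent, not zero. No r² floor is applied to reported pairs
(plink's report mode defaults to a 0.2 floor; applying one would bias the
stratum means upward).

**Decay.** Per chromosome: ≤ 100 observation points → points only;
101–999 → LOESS (statsmodels lowess, span 0.75 — locally linear rather
than quadratic; the smoother is a display device and does not enter the
decision rule); ≥ 1000 → a cubic smoothing spline with GCV-chosen penalty
(a GAM-equivalent penalized smoother), after averaging duplicate
distances. Fits are evaluated on a 200-point grid. The *quantitative*
decay statistic is Spearman's ρ of r² versus distance with a one-sided
permutation p-value for negative trend (1000 seeded permutations,
distribution-free); constant-r² chromosomes yield ρ = NaN, i.e. no trend.

## 4. Heterozygosity

**Relative heterozygosity** = heterozygous calls / called polymorphic
positions, per individual, computed genome-wide and per chromosome (with
the across-chromosome median also reported, the convention for displays
robust to uneven marker density). The input matrix should first be
restricted to polymorphic sites so the denominator is the number of
informative positions.

**Outlier rule.** Flag samples above max(Q3 + 3·IQR, 0.05). The Tukey
fence adapts to the population's spread; the absolute floor encodes the
empirical ceiling for parthenogenetically produced individuals (0–0.05)
and prevents flagging noise-level variation in all-homozygous populations
where the IQR is ~0. A fixed-threshold rule is exposed as an alternative.

**Cross expectation.** Mendelian per-site offspring heterozygote
probability, averaged over sites called in both parents: parents
homozygous for different alleles → 1; same allele → 0; either parent
heterozygous → ½. Identities maintained: AA×aa = 1, identical homozygotes
= 0, self-cross = own heterozygosity / 2. Population-wide, the
distribution over all candidate (low-heterozygosity) parent pairs gives a
2.5–97.5 % compatibility band: an outlier inside the band is consistent
with a cross *within* the population, as opposed to introgression from a
diverged source, which would overshoot it.

**Ploidy screen.** At a diploid's heterozygous calls the alternate-read
fraction is Binomial(depth, ½); a triploid heterozygote (AAB/ABB) gives ⅓
or ⅔. Per sample, the summed binomial log-likelihood under ½ is compared
with an equal ⅓/⅔ mixture; the verdict requires ≥ 50 heterozygous calls
with allele depths, otherwise `insufficient-data`. This is an
allele-balance diagnostic, not a karyotype: systematic reference bias in
real data shifts the observed fraction slightly below ½ and the comparison
is between idealized models.

**Robustness re-run.** `ld_without_outliers` repeats
MAF-filter → scan → summarize → decay with flagged samples removed and
tabulates the per-stratum change in mean r², verifying that an LD signal is
not driven by a few recent recombinants.

## 5. The forward simulator

The generator emulates the study design it is meant to test: populations
descended from 1–8 fully homozygous founder clones, reproducing by
**gamete-duplication automixis** — one recombinant meiotic product is
doubled, so offspring are homozygous at every site and all maternal
heterozygosity is lost in a single generation. Central/terminal-fusion
variants with partial heterozygosity retention are deliberately out of
scope: the target systems show genome-wide loss of heterozygosity.

- **Genome:** 5000 SNP positions spread over 12 autosomes of 50 Mb
  (uniform random coordinates), plus 100 X-linked positions. A finite
  predefined site grid — no infinite-sites bookkeeping — matching the
  fixed-locus character of RADseq and making VCF emission trivial.
- **Meiosis:** Poisson(1) crossovers per chromosome per meiosis at uniform
  bp positions (so recombination fractions follow Haldane's map function;
  verified by Monte-Carlo against the closed form). Fully homozygous
  parents take a shortcut — any meiotic product equals either homologue —
  which is what makes long clonal simulations fast.
- **Sex determination:** X0. Males arise from parthenogenetic eggs by X
  loss (probability `male_rate` per offspring) or as the nullo-X half of a
  male's sexual offspring; a male's single X is carried mirrored so his
  X genotypes are hemizygous-consistent.
- **Sexual events:** each offspring is sexual with probability `sex_rate`
  *if at least one male is alive*; mothers and fathers are drawn uniformly
  (no mate choice, non-overlapping generations, constant N — the simplest
  demography supporting the claims tested).
- **Mutation:** each haplotype-site flips with probability μ per
  generation (default 10⁻⁶), so parthenogens carry only last-generation
  mutations as heterozygous sites.
- **Founders:** two founders differ at exactly round(d·L) sites (default
  d = 0.2 — divergence on the scale of between-clone differences in real
  parthenogenetic populations); with k > 2 founders, alleles are drawn
  Bernoulli(½) at a 2d fraction of sites so the *expected* pairwise
  divergence is d (exact all-pairs divergence is not constructible in
  general).
- **Population size:** default N = 500 with G = 50 generations and 24
  sampled females. N is the one free parameter the study design does not
  pin down; 500 keeps neutral drift from routinely fixing one founder
  lineage over the simulated timespan (at N = 100 the lineage-frequency sd
  after 50 generations is ≈ 0.31, which regularly destroys the very
  polymorphism the strictly parthenogenetic scenario is supposed to
  display), while remaining cheap to simulate. Analyses that specifically
  probe drift-prone conditions set N = 100 explicitly.
- **Output:** the sampled females' genotypes as a `GenotypeMatrix` (and
  VCF) with synthesized sequencing annotations — INFO and per-call depth
  ~ Poisson(30), allele depths Binomial(depth, ½) at heterozygous calls,
  uniform high GQ — so the filters and the ploidy screen are exercisable;
  plus a truth table (mother, father, production mode, sex, lineage) for
  parameter-recovery tests. Runs are bit-reproducible given the config and
  seed.

Scenario presets: `strict` (σ = 0, m = 0), `rare-sex` (σ = 0.1, m = 0.05),
`sexual` (σ = 1, m = 0.05 to seed the first males). The rare-sex rates are
illustrative — the real frequency of sex in facultative populations is
unknown — so tests phrase power as detection probability under the preset,
not as an estimate of nature's σ.

**What the simulator does not emulate:** selection, demographic change,
population structure or migration, linked loci dropout/allele dropout and
other RADseq genotyping artifacts, reference bias in allele depths,
gene conversion, and partial-LOH automixis. Passing tests therefore show
that the pipeline detects the signatures *its model generates*; on real
data the same signatures can be attenuated (genotyping error inflating
apparent heterozygosity, unmodeled structure inflating LD) and the raw
evidence tables should always be inspected alongside the labels.

## 6. Classification

Evidence per population: lineages/samples, mean within- and
between-chromosome r², number of chromosomes with a significant negative
decay trend (permutation p < 0.01 among chromosomes with fitted curves),
heterozygosity outlier count. Default rules:

- fewer than 2 lineages or 2 genotypes → `indeterminate` (a single clone is
  consistent with no sex, but every LD- and heterozygosity-based statistic
  is uninformative at zero polymorphism);
- low diversity (lineages ≤ 0.25·n) AND no significant decay AND (mean
  within-chromosome r² ≥ 0.8 OR no MAF-passing within-chromosome pairs at
  all) → `no-evidence-of-sex`. The second disjunct keeps the clonal verdict
  when drift has pushed the minor lineage below the MAF cutoff — low
  polymorphism is itself the expected footprint of clonality — and is
  always accompanied by a caveat;
- high diversity (lineages > 0.25·n) AND ≥ half the fitted chromosomes
  decaying → `cryptic-sex`; additionally |within − between| < 0.05 and mean
  within < 0.15 → `sexual-like` (r² at the sampling-noise floor with no
  within/between contrast);
- anything else → `indeterminate`, with the evidence listed.

All thresholds are config-exposed (`ClassificationThresholds`) and were
calibrated on the simulator presets — the verbal criteria they
operationalize ("low diversity", "high LD", "evident decay") have no
canonical numeric values — so the report always shows the raw evidence
next to the label. The classification is a pure function of the stage
outputs, and raising within-chromosome r² alone can never move a
population from `no-evidence-of-sex` to `cryptic-sex`.

## 7. Problem sizes used in the tests

The test suite and acceptance script run entirely on simulated data at the
study's own scale: 24 sampled females, 5000 autosomal SNPs, 50
generations; power checks use 20 replicates per scenario, estimator
oracles use 100–200 random instances, Monte-Carlo checks 10⁴ draws.
Between-chromosome scans inside the end-to-end analysis subsample to
2×10⁵ pairs. These sizes make the whole suite run in a few minutes on one
core while leaving every statistical assertion comfortably outside
Monte-Carlo noise (assertions use 3–4 standard errors).

## 8. Known limitations

- The clone-threshold heuristic assumes a gap between mutation-scale and
  divergence-scale distances; continuously admixed populations (heavy
  ongoing sex) have no such gap, in which case the heuristic correctly
  degrades toward all-singletons but intermediate regimes deserve a manual
  look at the distance distribution.
- EM r² on 24 diploids has an upward bias of order 1/n for unlinked loci;
  between-chromosome means should be read against that floor, not zero.
- The decay permutation test treats pairs as exchangeable, ignoring the
  correlation induced by shared sites; its p-values are approximate and
  are used with a conservative cutoff (0.01).
- The expected-cross-heterozygosity band conditions on the *sampled*
  low-heterozygosity individuals being representative of the actual
  parental pool.
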