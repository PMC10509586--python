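# crypticsex

Detecting **cryptic sex** in putatively obligate parthenogens from SNP
genotypes.

Obligately parthenogenetic animal lineages are expected to be evolutionary
dead ends, yet some persist for over a million years. One resolution is that
"obligate" parthenogens occasionally reproduce sexually. In homozygous
automictic parthenogens — such as *Timema* stick insects, whose gamete
duplication erases heterozygosity every generation — even very rare sex
leaves clear population-genomic footprints:

- **Genotype diversity.** Strict clonality sweeps populations down to one or
  a few clonal lineages; sex shatters genotypes into many independent
  recombinants.
- **Linkage disequilibrium.** Without sex, alleles travel in a single block:
  r² between polymorphic sites is ~1 within *and* between chromosomes, with
  no relation to distance. Recombination during sex erodes r² — fastest for
  unlinked sites — producing the diagnostic **decay of r² with physical
  distance**.
- **Heterozygosity.** Parthenogenetically produced individuals are (nearly)
  fully homozygous; a sexually produced individual is heterozygous wherever
  its parents' genomes differ.

`crypticsex` implements this detection pipeline end to end, starting from a
called multi-sample VCF, together with a forward simulator of automictic
parthenogenesis (with rare X-loss males and rare sexual crosses) so every
stage is verifiable against ground truth without any sequencing data.

## Methods at a glance

- **Filtering** (RADseq conventions): genotype calls with quality ≤ 30
  masked; sites kept with depth 8 < DP < 200, ≥ 75 % called genotypes,
  biallelic SNPs only.
- **Clonal structure:** Euclidean distances on dosage vectors with
  missing-data rescaling, d(i,j) = √(Σ(xᵢ−xⱼ)² · S/sᵢⱼ); Saitou–Nei
  neighbour joining; single-linkage clone assignment with an automatic
  largest-gap distance cutoff.
- **LD:** plink-style r² = D²/(p_A p_a p_B p_b) with two-locus haplotype
  frequencies estimated by EM from unphased diploid genotypes (Hill's
  likelihood); sites at minor allele frequency > 0.2; within-chromosome
  pairs to 8 Mb separation, between-chromosome pairs exhaustive or
  subsampled; per-stratum mean ± 2·SE; decay curves smoothed by LOESS
  (< 1000 points) or a penalized spline (≥ 1000), fitted only above 100
  points, with a one-sided Spearman permutation test for negative trend.
- **Heterozygosity:** per individual, heterozygous calls / called
  polymorphic positions (genome-wide and median across chromosomes); Tukey
  outlier fence with an absolute floor of 0.05; Mendelian
  expected-offspring-heterozygosity for every candidate parent pair; a
  binomial allele-balance screen separating diploid (alt fraction ½) from
  triploid (⅓ or ⅔) heterozygotes.
- **Classification:** the evidence is combined into one of
  `no-evidence-of-sex`, `cryptic-sex`, `sexual-like` or `indeterminate`,
  always reported alongside the raw evidence table.

## Worked example

`examples/05_classify_end_to_end.py` simulates the three reproductive
scenarios, runs the full pipeline on each and classifies them:

```python
from crypticsex import analyze_population, preset_config, run_simulation

res = run_simulation(preset_config("rare-sex", seed=5))
out = analyze_population(res.genotypes, seed=5)
print(out["classification"].label, out["classification"].evidence)
```

Running the script prints:

```
[strict   ] -> no-evidence-of-sex
            lineages 2/24, mean r2 within 1.000 / between 1.000, decaying chromosomes 0/12, het outliers 0
[rare-sex ] -> cryptic-sex
            lineages 17/24, mean r2 within 0.726 / between 0.152, decaying chromosomes 12/12, het outliers 0
[sexual   ] -> cryptic-sex
            lineages 24/24, mean r2 within 0.179 / between 0.043, decaying chromosomes 12/12, het outliers 0
```

Read: the strict parthenogen collapses to 2 clonal lineages in complete LD
with no decay; with rare sex (10 % of offspring sexual), 17 of 24 females
carry independent genotypes, r² is eroded — more between than within
chromosomes, because chromosome segregation outpaces crossover
recombination — and every chromosome shows significant LD decay.

The other `examples/` scripts each exercise one capability: simulation and
truth tables (01), clonal structure and NJ trees (02), LD and decay (03),
heterozygosity outliers, cross expectations and the ploidy screen (04).

A thin CLI wraps the same functions:

```bash
crypticsex simulate --preset rare-sex --seed 42 --out pop.vcf --truth truth.tsv
crypticsex classify pop.vcf --out-dir report/
```

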