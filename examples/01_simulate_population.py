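"""Simulate a parthenogenetic population and write it as a VCF.

Runs the forward simulator under the "rare-sex" scenario (automictic
parthenogenesis with occasional X-loss males and rare sexual crosses) and
prints the sample's provenance.  The truth table records, per sampled
female, whether she was produced sexually or parthenogenetically — the
ground truth against which the detection pipeline can be judged.
"""

from crypticsex import preset_config, run_simulation, write_vcf

cfg = preset_config("rare-sex", seed=42)
res = run_simulation(cfg)

write_vcf(res.genotypes, "rare_sex_population.vcf")
res.truth.to_csv("rare_sex_truth.tsv", sep="\t", index=False)

print(f"simulated {cfg.pop_size} individuals for {cfg.generations} generations "
      f"(sex rate {cfg.sex_rate}, male rate {cfg.male_rate})")
print(f"sampled {res.genotypes.n_samples} females x {res.genotypes.n_sites} SNPs "
      "-> rare_sex_population.vcf")
print(res.truth["production_mode"].value_counts().to_string())
print("\nA 'sexual' row means that female's egg was fertilized by a rare male;")
print("her genome is a fresh recombinant and will show elevated heterozygosity.")
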