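"""Find sexually produced individuals by their heterozygosity.

Parthenogenesis by gamete duplication makes offspring fully homozygous, so
any individual with substantial heterozygosity must have been produced by a
sexual cross in the previous generation.  The Mendelian cross-expectation
model checks whether an outlier's heterozygosity is compatible with a cross
between two low-heterozygosity members of the same population, and the
allele-balance screen rules out triploidy as an alternative explanation.
"""

import numpy as np

from crypticsex import (
    allele_balance_screen,
    cross_het_distribution,
    detect_het_outliers,
    polymorphic_sites,
    preset_config,
    relative_het,
    run_simulation,
)

res = run_simulation(preset_config("rare-sex", seed=42))
poly = polymorphic_sites(res.genotypes)
profile = relative_het(poly)
flags = detect_het_outliers(profile)

print(profile.table[["sample", "relative_het", "median_chrom_het",
                     "outlier"]].to_string(index=False))

truly_sexual = set(res.truth.loc[res.truth["production_mode"] == "sexual", "id"])
flagged = set(profile.table.loc[profile.table["outlier"], "sample"])
print(f"\nflagged {len(flagged)} outliers; truly sexually produced: "
      f"{len(truly_sexual)}; overlap: {len(flagged & truly_sexual)}")

dist = cross_het_distribution(poly, low_het_threshold=0.05)
lo, hi = np.nanpercentile(dist["expected_het"], [2.5, 97.5])
print(f"expected offspring heterozygosity for within-population crosses "
      f"between low-het parents: 2.5-97.5% band [{lo:.3f}, {hi:.3f}]")
print("outliers inside this band are compatible with sex within the population.")

ploidy = allele_balance_screen(poly)
print("\nallele-balance verdicts:",
      ploidy["verdict"].value_counts().to_dict(),
      "(diploid-consistent = heterozygosity is not a ploidy artifact)")
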