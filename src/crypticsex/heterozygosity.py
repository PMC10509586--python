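"""Per-individual heterozygosity, outlier detection, expected heterozygosity
of within-population crosses, and the allele-balance ploidy screen.

Automictic parthenogens with genome-wide loss of heterozygosity should be
(nearly) fully homozygous; a sexually produced individual instead carries
heterozygous genotypes at the sites where its parents' genomes differ.
Relative heterozygosity — heterozygous calls divided by called polymorphic
positions — therefore flags sexually produced individuals directly, and a
simple Mendelian model predicts how heterozygous the offspring of any
candidate parent pair should be.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import binom

from .genotype_io import MISSING, GenotypeMatrix
from .linkage import ld_decay, ld_scan, maf_filter, summarize_ld


@dataclass
class HetProfile:
    """Per-sample relative heterozygosity (genome-wide and per chromosome)."""

    table: pd.DataFrame          # sample, n_het, n_called, relative_het,
                                 # median_chrom_het [, outlier]
    per_chromosome: pd.DataFrame  # samples × chromosomes

    @property
    def samples(self) -> list:
        return list(self.table["sample"])

    @property
    def values(self) -> pd.Series:
        return self.table.set_index("sample")["relative_het"]


def relative_het(gm: GenotypeMatrix) -> HetProfile:
    """Relative heterozygosity: heterozygous calls / called polymorphic
    positions, per individual.

    ``gm`` should already be restricted to polymorphic sites (see
    :func:`crypticsex.genotype_io.polymorphic_sites`); missing calls are
    excluded from numerator and denominator.  Per-chromosome values and
    their median are also reported; samples with zero called sites in a
    scope get NaN there.
    """
    called = gm.dosage != MISSING
    het = gm.dosage == 1
    n_called = called.sum(axis=1)
    n_het = het.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)

    chroms = gm.chromosomes()
    chrom_arr = gm.sites["chrom"].to_numpy()
    per = {}
    for c in chroms:
        m = chrom_arr == c
        nc = called[:, m].sum(axis=1)
        nh = het[:, m].sum(axis=1)
        per[c] = np.where(nc > 0, nh / np.maximum(nc, 1), np.nan)
    per_chrom = pd.DataFrame(per, index=gm.samples)
    median = per_chrom.median(axis=1, skipna=True).to_numpy()

    table = pd.DataFrame({
        "sample": gm.samples,
        "n_het": n_het, "n_called": n_called,
        "relative_het": rel,
        "median_chrom_het": median,
    })
    if gm.sex_labels:
        table["sex"] = [gm.sex_labels.get(s, "") for s in gm.samples]
    return HetProfile(table=table, per_chromosome=per_chrom)


def detect_het_outliers(profile: HetProfile, rule: str = "tukey",
                        k: float = 3.0, floor: float = 0.05,
                        threshold: float | None = None) -> pd.Series:
    """Flag heterozygosity outliers (putatively sexually produced
    individuals).

    Default rule: value > max(Q3 + k·IQR, ``floor``).  The absolute floor
    reflects the ceiling observed for parthenogenetically produced
    individuals (relative heterozygosity between 0 and 0.05), preventing
    within-noise flags in all-homozygous populations where the IQR is ~0.
    ``rule="fixed"`` uses the given ``threshold`` alone.  Also annotates
    the profile's table with an ``outlier`` column.
    """
    vals = profile.values
    if vals.size < 5:
        raise ValueError("outlier detection requires at least 5 samples")
    arr = vals.to_numpy(dtype=float)
    if rule == "tukey":
        if np.isnan(arr).all():
            profile.table["outlier"] = False
            return pd.Series(False, index=vals.index)
        q1, q3 = np.nanpercentile(arr, [25, 75])
        cut = max(q3 + k * (q3 - q1), floor)
    elif rule == "fixed":
        if threshold is None:
            raise ValueError("rule='fixed' requires a threshold")
        cut = threshold
    else:
        raise ValueError(f"unknown rule {rule!r}")
    flags = vals > cut
    profile.table["outlier"] = flags.to_numpy()
    return flags


# ---------------------------------------------------------------------------
# expected heterozygosity of crosses
# ---------------------------------------------------------------------------

def expected_cross_het(gm: GenotypeMatrix, parent_a, parent_b) -> float:
    """Mendelian expectation of offspring relative heterozygosity for a
    cross between two sampled individuals.

    Per shared called site: parents homozygous for different alleles → 1;
    homozygous for the same allele → 0; one or both heterozygous → 1/2.
    Averaged over sites called in both parents.  ``gm`` should be
    restricted to polymorphic sites so the denominator matches the
    observed relative-heterozygosity scale.
    """
    ia = gm.samples.index(parent_a)
    ib = gm.samples.index(parent_b)
    a, b = gm.dosage[ia], gm.dosage[ib]
    ok = (a != MISSING) & (b != MISSING)
    if not ok.any():
        raise ValueError(f"no shared called sites for {parent_a!r}, {parent_b!r}")
    a, b = a[ok], b[ok]
    any_het = (a == 1) | (b == 1)
    p = np.where(any_het, 0.5, (a != b).astype(float))
    return float(p.mean())


def cross_het_distribution(gm: GenotypeMatrix, samples=None,
                           low_het_threshold: float | None = None) -> pd.DataFrame:
    """Expected offspring heterozygosity for every candidate parent pair.

    ``samples`` restricts the candidate parents; alternatively
    ``low_het_threshold`` keeps only individuals whose own relative
    heterozygosity is at or below the threshold (the "crosses between
    individuals with low heterozygosity" scenario).  Returns one row per
    unordered pair.
    """
    cand = list(samples) if samples is not None else list(gm.samples)
    if low_het_threshold is not None:
        prof = relative_het(gm)
        vals = prof.values
        cand = [s for s in cand if vals[s] <= low_het_threshold]
    rows = []
    for a, b in combinations(cand, 2):
        try:
            e = expected_cross_het(gm, a, b)
        except ValueError:
            e = float("nan")
        rows.append((a, b, e))
    return pd.DataFrame(rows, columns=["parent_a", "parent_b", "expected_het"])


# ---------------------------------------------------------------------------
# allele-balance ploidy screen
# ---------------------------------------------------------------------------

def allele_balance_screen(gm: GenotypeMatrix,
                          min_het_calls: int = 50) -> pd.DataFrame:
    """Screen samples for triploidy from the allele balance at heterozygous
    calls.

    A diploid heterozygote's alternate-read fraction is centred at 1/2; a
    triploid's (AAB or ABB) at 1/3 or 2/3.  Per sample the summed binomial
    log-likelihood of the 1/2 model is compared with an equal mixture of
    the 1/3 and 2/3 models; the verdict is ``diploid-consistent``,
    ``triploid-consistent`` or ``insufficient-data`` (< ``min_het_calls``
    heterozygous calls with allele depths).
    """
    if gm.ad_ref is None or gm.ad_alt is None:
        return pd.DataFrame({
            "sample": gm.samples,
            "n_het_calls": 0, "mean_alt_fraction": np.nan,
            "ll_diploid": np.nan, "ll_triploid": np.nan,
            "verdict": "insufficient-data"})
    rows = []
    for i, s in enumerate(gm.samples):
        het = gm.dosage[i] == 1
        ref_d = gm.ad_ref[i]
        alt_d = gm.ad_alt[i]
        ok = het & (ref_d >= 0) & (alt_d >= 0) & ((ref_d + alt_d) > 0)
        n = int(ok.sum())
        if n < min_het_calls:
            rows.append((s, n, np.nan, np.nan, np.nan, "insufficient-data"))
            continue
        dp = (ref_d[ok] + alt_d[ok]).astype(np.int64)
        alt = alt_d[ok].astype(np.int64)
        mean_frac = float((alt / dp).mean())
        ll_dip = float(binom.logpmf(alt, dp, 0.5).sum())
        ll_tri = float(np.logaddexp(
            np.log(0.5) + binom.logpmf(alt, dp, 1.0 / 3.0),
            np.log(0.5) + binom.logpmf(alt, dp, 2.0 / 3.0)).sum())
        verdict = "diploid-consistent" if ll_dip >= ll_tri else "triploid-consistent"
        rows.append((s, n, mean_frac, ll_dip, ll_tri, verdict))
    return pd.DataFrame(rows, columns=["sample", "n_het_calls",
                                       "mean_alt_fraction", "ll_diploid",
                                       "ll_triploid", "verdict"])


# ---------------------------------------------------------------------------
# LD robustness without outliers
# ---------------------------------------------------------------------------

def ld_without_outliers(gm: GenotypeMatrix, flags, min_maf: float = 0.2,
                        **scan_kwargs) -> dict:
    """Re-run the LD pipeline with heterozygosity-outlier samples removed.

    ``gm`` is the filtered (pre-MAF) matrix; ``flags`` a boolean
    sample-aligned series/array marking outliers.  Returns the full and
    outlier-free summaries, decay curves, and a side-by-side comparison of
    mean r² per stratum.
    """
    flags = np.asarray(pd.Series(flags).reindex(gm.samples).to_numpy()
                       if isinstance(flags, pd.Series) else flags, dtype=bool)
    if flags.shape[0] != gm.n_samples:
        raise ValueError("flags must align with gm.samples")
    keep = np.flatnonzero(~flags)
    if keep.size < 4:
        raise ValueError("fewer than 4 samples remain after outlier removal")

    def _run(sub):
        mf = maf_filter(sub, min_maf=min_maf)
        pairs = ld_scan(mf, **scan_kwargs)
        return summarize_ld(pairs), ld_decay(pairs)

    full_summary, full_decay = _run(gm)
    sub_summary, sub_decay = _run(gm.take_samples(keep))
    comparison = full_summary[["stratum", "mean_r2", "n_pairs"]].merge(
        sub_summary[["stratum", "mean_r2", "n_pairs"]],
        on="stratum", how="outer", suffixes=("_all", "_no_outliers"))
    comparison["delta_mean_r2"] = (comparison["mean_r2_no_outliers"]
                                   - comparison["mean_r2_all"])
    return {
        "summary_all": full_summary, "summary_no_outliers": sub_summary,
        "decay_all": full_decay, "decay_no_outliers": sub_decay,
        "comparison": comparison,
        "n_removed": int(flags.sum()),
    }
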