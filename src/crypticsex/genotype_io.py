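"""Genotype data model, VCF input/output and site/genotype filtering.

The pipeline's universal currency is the :class:`GenotypeMatrix`: an
individuals × sites matrix of alternate-allele dosages (0/1/2, −1 for a
missing call) together with per-site metadata (linkage group, basepair
position, alleles, total depth) and optional per-call quality and
allele-depth annotations.  All downstream statistics (distances, LD,
heterozygosity) are computed on the dosage matrix.

Filtering follows the conventions of RADseq SNP pipelines: low-quality
genotype calls are masked first, then whole sites are removed by total
depth, by allele count (biallelic SNPs only) and by per-site missingness.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: site-table columns guaranteed to be present
SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "site_depth", "n_alt"]


def _natural_key(chrom: str):
    """Sort key placing chr2 before chr10 and autosomes in numeric order."""
    parts = re.split(r"(\d+)", str(chrom))
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass
class GenotypeMatrix:
    """Samples × sites dosage matrix with site metadata.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers.
    sites : pandas.DataFrame
        One row per site with at least ``chrom`` (linkage-group label),
        ``pos`` (1-based bp), ``ref``, ``alt`` (comma-joined alternate
        alleles), ``site_depth`` (total read depth, NaN when absent) and
        ``n_alt`` (number of alternate alleles; >1 flags multiallelic).
    dosage : ndarray of int8, shape (n_samples, n_sites)
        Count of alternate alleles per call; ``MISSING`` (−1) excludes the
        call from every statistic.
    gq : ndarray or None
        Per-call phred genotype quality (NaN when absent).
    ad_ref, ad_alt : ndarray or None
        Per-call reference / alternate read depths (−1 when absent).
    site_qual : ndarray or None
        Per-site record QUAL, used as a fallback when GQ is absent.
    sex_labels : dict or None
        Optional per-sample sex annotation (``"female"``/``"male"``).
    """

    samples: list
    sites: pd.DataFrame
    dosage: np.ndarray
    gq: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None
    site_qual: np.ndarray | None = None
    sex_labels: dict | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        self._sort_sites()

    # -- invariant maintenance -------------------------------------------
    def _sort_sites(self):
        if not len(self.sites):
            return
        chrom = self.sites["chrom"].to_numpy()
        uniq = sorted(set(chrom.tolist()), key=_natural_key)
        code = pd.Categorical(chrom, categories=uniq).codes
        pos = self.sites["pos"].to_numpy()
        order = np.lexsort((pos, code))
        if not np.array_equal(order, np.arange(len(order))):
            self._reindex_sites(order)
        chrom = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        dup = (pos[1:] == pos[:-1]) & (chrom[1:] == chrom[:-1])
        if dup.any():
            raise ValueError("duplicate (chromosome, position) pairs in site table")

    def _reindex_sites(self, order: np.ndarray):
        self.sites = self.sites.iloc[order].reset_index(drop=True)
        self.dosage = self.dosage[:, order]
        for attr in ("gq", "ad_ref", "ad_alt"):
            arr = getattr(self, attr)
            if arr is not None:
                setattr(self, attr, arr[:, order])
        if self.site_qual is not None:
            self.site_qual = self.site_qual[order]

    # -- basic properties --------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage != MISSING

    def chromosomes(self) -> list:
        seen = dict.fromkeys(self.sites["chrom"])
        return list(seen)

    # -- subsetting --------------------------------------------------------
    def take_sites(self, mask) -> "GenotypeMatrix":
        """Return a new matrix restricted to sites where ``mask`` is true."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx].copy(),
            gq=None if self.gq is None else self.gq[:, idx].copy(),
            ad_ref=None if self.ad_ref is None else self.ad_ref[:, idx].copy(),
            ad_alt=None if self.ad_alt is None else self.ad_alt[:, idx].copy(),
            site_qual=None if self.site_qual is None else self.site_qual[idx].copy(),
            sex_labels=None if self.sex_labels is None else dict(self.sex_labels),
        )

    def take_samples(self, which) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given samples (names or indices)."""
        if len(which) and isinstance(next(iter(which)), str):
            idx = [self.samples.index(s) for s in which]
        else:
            idx = list(which)
        idx = np.asarray(idx, dtype=int)
        names = [self.samples[i] for i in idx]
        sex = None
        if self.sex_labels is not None:
            sex = {s: self.sex_labels[s] for s in names if s in self.sex_labels}
        return GenotypeMatrix(
            samples=names,
            sites=self.sites.copy(),
            dosage=self.dosage[idx].copy(),
            gq=None if self.gq is None else self.gq[idx].copy(),
            ad_ref=None if self.ad_ref is None else self.ad_ref[idx].copy(),
            ad_alt=None if self.ad_alt is None else self.ad_alt[idx].copy(),
            site_qual=None if self.site_qual is None else self.site_qual.copy(),
            sex_labels=sex,
        )


@dataclass
class FilterReport:
    """Per-rule removal counts, in application order."""

    sites_in: int = 0
    sites_out: int = 0
    calls_masked_low_quality: int = 0
    sites_removed_depth: int = 0
    sites_removed_not_biallelic: int = 0
    sites_removed_missingness: int = 0
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("sites_in", self.sites_in),
            ("calls_masked_low_quality", self.calls_masked_low_quality),
            ("sites_removed_depth", self.sites_removed_depth),
            ("sites_removed_not_biallelic", self.sites_removed_not_biallelic),
            ("sites_removed_missingness", self.sites_removed_missingness),
            ("sites_out", self.sites_out),
        ]
        return pd.DataFrame(rows, columns=["rule", "count"])

    def __str__(self):
        return (
            f"FilterReport: {self.sites_in} sites in, {self.sites_out} out "
            f"(depth −{self.sites_removed_depth}, "
            f"non-biallelic −{self.sites_removed_not_biallelic}, "
            f"missingness −{self.sites_removed_missingness}); "
            f"{self.calls_masked_low_quality} calls masked for quality"
        )


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_chrom_map(path) -> dict:
    """Read a two-column TSV mapping contig name → linkage-group label."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return dict(zip(df[0], df[1]))


def read_vcf(path, chrom_map: dict | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    ``chrom_map`` optionally remaps contig names to linkage-group labels;
    contigs absent from a provided map are labelled ``"unplaced"``.
    Multiallelic records are retained with ``n_alt > 1`` (downstream filters
    drop them when ``biallelic_only`` is set).  Records without a usable GT
    field yield all-missing calls and a logged warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    n = len(samples)

    chroms, poss, refs, alts, depths, nalts, quals = [], [], [], [], [], [], []
    dosage_rows, gq_rows, adr_rows, ada_rows = [], [], [], []
    any_gq = any_ad = False

    for var in vcf:
        chrom = var.CHROM
        if chrom_map is not None:
            chrom = chrom_map.get(chrom, "unplaced")
        chroms.append(chrom)
        poss.append(var.POS)
        refs.append(var.REF)
        alt_list = [a for a in (var.ALT or []) if a not in (None, "")]
        alts.append(",".join(alt_list) if alt_list else ".")
        nalts.append(len(alt_list))
        dp = var.INFO.get("DP")
        depths.append(float(dp) if dp is not None else np.nan)
        quals.append(var.QUAL if var.QUAL is not None else np.nan)

        try:
            gt = np.asarray(var.gt_types)
            dos = gt.astype(np.int8)
            dos[gt == 3] = MISSING
        except Exception:
            logger.warning("record %s:%s lacks a usable GT field; calls set missing",
                           var.CHROM, var.POS)
            dos = np.full(n, MISSING, dtype=np.int8)
        dosage_rows.append(dos)

        try:
            gq = var.format("GQ")
        except KeyError:
            gq = None
        if gq is not None:
            any_gq = True
            gq = np.asarray(gq, dtype=float).reshape(n, -1)[:, 0]
            gq[gq < 0] = np.nan
        gq_rows.append(gq)

        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            any_ad = True
            ad = np.asarray(ad, dtype=np.int32).reshape(n, -1)
            ref_d = ad[:, 0]
            alt_d = ad[:, 1] if ad.shape[1] > 1 else np.full(n, -1, np.int32)
        else:
            ref_d = alt_d = None
        adr_rows.append(ref_d)
        ada_rows.append(alt_d)

    n_sites = len(chroms)
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64),
         "ref": refs, "alt": alts,
         "site_depth": np.asarray(depths, dtype=float),
         "n_alt": np.asarray(nalts, dtype=np.int32)}
    )
    dosage = (np.vstack(dosage_rows).T if n_sites
              else np.zeros((n, 0), dtype=np.int8))

    def _stack(rows, fill, dtype):
        if not any(r is not None for r in rows):
            return None
        full = [r if r is not None else np.full(n, fill, dtype) for r in rows]
        return np.vstack(full).T.astype(dtype)

    gq_arr = _stack(gq_rows, np.nan, float) if any_gq else None
    adr = _stack(adr_rows, -1, np.int32) if any_ad else None
    ada = _stack(ada_rows, -1, np.int32) if any_ad else None

    return GenotypeMatrix(
        samples=samples, sites=sites, dosage=dosage,
        gq=gq_arr, ad_ref=adr, ad_alt=ada,
        site_qual=np.asarray(quals, dtype=float) if n_sites else None,
    )


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 text file.

    Emits GT always, plus GQ/DP/AD FORMAT fields when the corresponding
    arrays are present; INFO DP from ``site_depth``.  Round-trips through
    :func:`read_vcf` bit-exactly for dosages, coordinates and the missing
    pattern.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    have_gq = gm.gq is not None
    have_ad = gm.ad_ref is not None and gm.ad_alt is not None
    fmt_keys = ["GT"] + (["GQ"] if have_gq else []) + (["AD"] if have_ad else [])
    fmt = ":".join(fmt_keys)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if have_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        if have_ad:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        for chrom in gm.chromosomes():
            length = int(gm.sites.loc[gm.sites["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in gm.samples) + "\n")
        for j in range(gm.n_sites):
            row = gm.sites.iloc[j]
            qual = "."
            if gm.site_qual is not None and np.isfinite(gm.site_qual[j]):
                qual = f"{gm.site_qual[j]:g}"
            info = "."
            if np.isfinite(row["site_depth"]):
                info = f"DP={int(row['site_depth'])}"
            cells = []
            for i in range(gm.n_samples):
                parts = [gt_str[int(gm.dosage[i, j])]]
                if have_gq:
                    q = gm.gq[i, j]
                    parts.append(f"{int(q)}" if np.isfinite(q) else ".")
                if have_ad:
                    r, a = gm.ad_ref[i, j], gm.ad_alt[i, j]
                    parts.append(f"{r},{a}" if r >= 0 and a >= 0 else ".")
                cells.append(":".join(parts))
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t"
                     f"{row['alt']}\t{qual}\tPASS\t{info}\t{fmt}\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_filters(
    gm: GenotypeMatrix,
    dp_min: float = 8,
    dp_max: float = 200,
    qual_min: float = 30,
    max_missing_frac: float = 0.25,
    biallelic_only: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply standard RADseq site/genotype filters.

    Order is fixed: (1) genotype calls with quality ≤ ``qual_min`` are set
    missing (per-call GQ, falling back to the record QUAL where GQ is
    absent); (2) sites with total depth ≤ ``dp_min`` or ≥ ``dp_max`` are
    removed (strict inequalities keep DP in the open interval); (3) with
    ``biallelic_only``, only single-nucleotide sites with exactly one
    alternate allele are kept; (4) sites where more than
    ``max_missing_frac`` of calls are missing are removed.  Quality masking
    precedes the missingness rule because masking changes missingness.
    """
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    report = FilterReport(sites_in=gm.n_sites, params=dict(
        dp_min=dp_min, dp_max=dp_max, qual_min=qual_min,
        max_missing_frac=max_missing_frac, biallelic_only=biallelic_only))

    dosage = gm.dosage.copy()

    # 1. genotype-quality masking
    qual = None
    if gm.gq is not None:
        qual = gm.gq.copy()
        if gm.site_qual is not None:
            fallback = np.broadcast_to(gm.site_qual, qual.shape)
            qual = np.where(np.isnan(qual), fallback, qual)
    elif gm.site_qual is not None:
        qual = np.broadcast_to(gm.site_qual, dosage.shape).copy()
    if qual is not None:
        low = (qual <= qual_min) & (dosage != MISSING) & ~np.isnan(qual)
        report.calls_masked_low_quality = int(low.sum())
        dosage[low] = MISSING

    masked = replace(gm)
    masked.dosage = dosage

    keep = np.ones(gm.n_sites, dtype=bool)

    # 2. site depth
    dp = gm.sites["site_depth"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad_dp = np.isfinite(dp) & ((dp <= dp_min) | (dp >= dp_max))
    report.sites_removed_depth = int(bad_dp.sum())
    keep &= ~bad_dp

    # 3. biallelic SNPs only
    if biallelic_only:
        n_alt = gm.sites["n_alt"].to_numpy()
        snp = (gm.sites["ref"].str.len() == 1) & (
            gm.sites["alt"].str.len() == 1)
        bad_allelic = keep & ~((n_alt == 1) & snp.to_numpy())
        report.sites_removed_not_biallelic = int(bad_allelic.sum())
        keep &= ~bad_allelic

    # 4. missingness
    miss_frac = (dosage == MISSING).mean(axis=0)
    bad_miss = keep & (miss_frac > max_missing_frac)
    report.sites_removed_missingness = int(bad_miss.sum())
    keep &= ~bad_miss

    out = masked.take_sites(keep)
    report.sites_out = out.n_sites
    if out.n_sites == 0:
        logger.warning("all sites removed by filtering")
    return out, report


def polymorphic_sites(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Restrict to sites with ≥2 observed dosage states among called genotypes."""
    d = gm.dosage
    called = d != MISSING
    # a site is polymorphic iff min and max called dosage differ
    with np.errstate(invalid="ignore"):
        dmax = np.where(called, d, -10).max(axis=0)
        dmin = np.where(called, d, 10).min(axis=0)
    keep = (called.sum(axis=0) > 0) & (dmax > dmin)
    return gm.take_sites(keep)
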