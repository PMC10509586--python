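"""Linkage disequilibrium: EM-based r², within/between-chromosome scans,
per-chromosome summaries and LD-decay curves.

Under strict clonal reproduction alleles travel in a single block, so r²
between polymorphic sites is high regardless of where they sit in the
genome and shows no relationship with distance.  Sex and recombination
erode r², fastest between chromosomes and between distant sites, leaving
the diagnostic signature of LD decay with physical distance.

r² is computed from unphased diploid genotypes the way plink does: two-locus
haplotype frequencies are estimated by expectation–maximization over the
double-heterozygote phase ambiguity (Hill's multinomial likelihood under
random union of gametes), then ``r² = D² / (p_A p_a p_B p_b)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genotype_io import MISSING, GenotypeMatrix

EXCLUDED_CHROMS = ("chrX", "X", "unplaced")


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def maf_filter(gm: GenotypeMatrix, min_maf: float = 0.2) -> GenotypeMatrix:
    """Keep sites whose minor-allele frequency (on called genotypes) exceeds
    ``min_maf`` — the informative-marker condition for r² estimation."""
    called = gm.dosage != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, gm.dosage, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    keep = (n_called > 0) & (maf > min_maf)
    return gm.take_sites(keep)


# ---------------------------------------------------------------------------
# EM r²
# ---------------------------------------------------------------------------

def _pair_counts(dosage: np.ndarray, ia: np.ndarray, ib: np.ndarray):
    """3×3 genotype-table counts for each site pair; returns dict of (i,j)
    count arrays over complete (both-called) individuals."""
    A = dosage[:, ia]
    B = dosage[:, ib]
    ok = (A != MISSING) & (B != MISSING)
    counts = {}
    for i in (0, 1, 2):
        Ai = (A == i) & ok
        for j in (0, 1, 2):
            counts[(i, j)] = (Ai & (B == j)).sum(axis=0).astype(np.float64)
    return counts


def r2_em_batch(dosage: np.ndarray, ia, ib, tol: float = 1e-10,
                max_iter: int = 1000) -> np.ndarray:
    """Vectorized EM r² for many site pairs at once.

    ``dosage`` is samples × sites; ``ia``/``ib`` index the paired sites.
    Pairs with fewer than two complete individuals, or monomorphic at
    either site within the complete subset, get NaN.
    """
    ia = np.asarray(ia, dtype=np.intp)
    ib = np.asarray(ib, dtype=np.intp)
    c = _pair_counts(dosage, ia, ib)
    n = sum(c.values())
    # phase-unambiguous haplotype contributions
    kAB = 2 * c[(2, 2)] + c[(2, 1)] + c[(1, 2)]
    kAb = 2 * c[(2, 0)] + c[(2, 1)] + c[(1, 0)]
    kaB = 2 * c[(0, 2)] + c[(1, 2)] + c[(0, 1)]
    kab = 2 * c[(0, 0)] + c[(1, 0)] + c[(0, 1)]
    ndh = c[(1, 1)]
    two_n = 2.0 * n

    with np.errstate(divide="ignore", invalid="ignore"):
        pA = (kAB + kAb + ndh) / two_n
        pB = (kAB + kaB + ndh) / two_n
    valid = (n >= 2) & (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)

    p11 = np.where(valid, pA * pB, 0.25)
    p10 = np.where(valid, pA * (1 - pB), 0.25)
    p01 = np.where(valid, (1 - pA) * pB, 0.25)
    p00 = np.where(valid, (1 - pA) * (1 - pB), 0.25)
    tn = np.where(two_n > 0, two_n, 1.0)

    active = valid.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        coup = p11 * p00
        rep = p10 * p01
        denom = coup + rep
        w = np.where(denom > 0, np.divide(coup, np.where(denom > 0, denom, 1.0)), 0.5)
        q11 = (kAB + w * ndh) / tn
        q00 = (kab + w * ndh) / tn
        q10 = (kAb + (1 - w) * ndh) / tn
        q01 = (kaB + (1 - w) * ndh) / tn
        delta = (np.abs(q11 - p11) + np.abs(q00 - p00)
                 + np.abs(q10 - p10) + np.abs(q01 - p01))
        upd = active
        p11 = np.where(upd, q11, p11)
        p00 = np.where(upd, q00, p00)
        p10 = np.where(upd, q10, p10)
        p01 = np.where(upd, q01, p01)
        active = active & (delta >= tol)

    pA_hat = p11 + p10
    pB_hat = p11 + p01
    D = p11 - pA_hat * pB_hat
    denom = (pA_hat - pA_hat * pA_hat) * (pB_hat - pB_hat * pB_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (D * D) / denom
    r2 = np.where(valid & (denom > 0), r2, np.nan)
    return np.clip(r2, 0.0, 1.0, out=r2)


def r2_em(dosages_a, dosages_b, method: str = "em") -> float:
    """r² for one pair of dosage vectors.

    ``method="em"`` is the plink-style EM estimator; ``method="corr"`` is
    the genotypic-correlation shortcut (squared Pearson correlation of the
    dosage vectors) provided for comparison.
    """
    a = np.asarray(dosages_a, dtype=np.int8)
    b = np.asarray(dosages_b, dtype=np.int8)
    if method == "corr":
        ok = (a != MISSING) & (b != MISSING)
        if ok.sum() < 2:
            return float("nan")
        x, y = a[ok].astype(float), b[ok].astype(float)
        if x.std() == 0 or y.std() == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1] ** 2)
    if method != "em":
        raise ValueError(f"unknown method {method!r}")
    dosage = np.stack([a, b], axis=1)
    return float(r2_em_batch(dosage, [0], [1])[0])


# ---------------------------------------------------------------------------
# pair enumeration
# ---------------------------------------------------------------------------

def ld_scan(gm: GenotypeMatrix, mode: str = "both", max_bp: int = 8_000_000,
            max_between_pairs: int = 2_000_000, seed: int = 0,
            include_x: bool = False) -> pd.DataFrame:
    """Enumerate site pairs and compute r² for each.

    Within-chromosome pairs are enumerated exhaustively up to ``max_bp``
    separation.  Between-chromosome pairs are exhaustive unless their count
    exceeds ``max_between_pairs``, in which case a seeded uniform subsample
    is taken (identical expectation, bounded runtime).  Sites on the X or
    on unplaced contigs are excluded; ``include_x`` re-admits them to the
    between-chromosome pool only.

    Returns a DataFrame with columns ``chrom_a, pos_a, chrom_b, pos_b,
    same_chromosome, bp_distance, r2`` (``bp_distance`` is NaN for
    between-chromosome pairs; ``r2`` is NaN where undefined).
    """
    if mode not in ("within", "between", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    chrom = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    placed = ~np.isin(chrom, EXCLUDED_CHROMS)
    rng = np.random.default_rng(seed)

    ia_list, ib_list, same_list = [], [], []

    if mode in ("within", "both"):
        for c in pd.unique(chrom[placed]):
            idx = np.flatnonzero(placed & (chrom == c))
            if idx.size < 2:
                continue
            i, j = np.triu_indices(idx.size, k=1)
            keep = (pos[idx[j]] - pos[idx[i]]) <= max_bp
            ia_list.append(idx[i[keep]])
            ib_list.append(idx[j[keep]])
            same_list.append(np.ones(int(keep.sum()), dtype=bool))

    if mode in ("between", "both"):
        pool = np.flatnonzero(placed) if not include_x else np.arange(gm.n_sites)
        cpool = chrom[pool]
        sizes = pd.Series(cpool).value_counts()
        total = int((sizes.sum() ** 2 - (sizes ** 2).sum()) // 2)
        if total > 0:
            if total <= max_between_pairs:
                order = np.argsort(cpool, kind="stable")
                p_sorted = pool[order]
                c_sorted = cpool[order]
                i, j = np.triu_indices(p_sorted.size, k=1)
                keep = c_sorted[i] != c_sorted[j]
                ia_list.append(p_sorted[i[keep]])
                ib_list.append(p_sorted[j[keep]])
                same_list.append(np.zeros(int(keep.sum()), dtype=bool))
            else:
                got_a, got_b = [], []
                need = max_between_pairs
                while need > 0:
                    m = int(need * 1.5) + 16
                    a = pool[rng.integers(0, pool.size, size=m)]
                    b = pool[rng.integers(0, pool.size, size=m)]
                    ok = chrom[a] != chrom[b]
                    a, b = a[ok][:need], b[ok][:need]
                    got_a.append(a)
                    got_b.append(b)
                    need -= a.size
                ia_list.append(np.concatenate(got_a))
                ib_list.append(np.concatenate(got_b))
                same_list.append(np.zeros(max_between_pairs, dtype=bool))

    if not ia_list:
        return pd.DataFrame({
            "chrom_a": pd.Series(dtype=object),
            "pos_a": pd.Series(dtype=np.int64),
            "chrom_b": pd.Series(dtype=object),
            "pos_b": pd.Series(dtype=np.int64),
            "same_chromosome": pd.Series(dtype=bool),
            "bp_distance": pd.Series(dtype=float),
            "r2": pd.Series(dtype=float),
        })
    ia = np.concatenate(ia_list)
    ib = np.concatenate(ib_list)
    same = np.concatenate(same_list)

    r2 = np.empty(ia.size)
    chunk = 200_000
    for s in range(0, ia.size, chunk):
        e = min(s + chunk, ia.size)
        r2[s:e] = r2_em_batch(gm.dosage, ia[s:e], ib[s:e])

    dist = np.where(same, np.abs(pos[ib] - pos[ia]).astype(float), np.nan)
    return pd.DataFrame({
        "chrom_a": chrom[ia], "pos_a": pos[ia],
        "chrom_b": chrom[ib], "pos_b": pos[ib],
        "same_chromosome": same, "bp_distance": dist, "r2": r2,
    })


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_ld(pairs: pd.DataFrame) -> pd.DataFrame:
    """Mean r² with ±2·SE interval per within-chromosome stratum, pooled
    within, and pooled between-chromosome.

    SE = sd/√n; the interval approximates a 95% confidence interval.
    Strata with a single pair report the mean with undefined SE.
    """
    rows = []

    def _one(name, vals):
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return
        mean = float(vals.mean())
        if vals.size > 1:
            se = float(vals.std(ddof=1) / np.sqrt(vals.size))
            lo, hi = mean - 2 * se, mean + 2 * se
        else:
            se = lo = hi = float("nan")
        rows.append(dict(stratum=name, mean_r2=mean, se=se,
                         ci_low=lo, ci_high=hi, n_pairs=int(vals.size)))

    within = pairs[pairs["same_chromosome"]]
    for c, grp in within.groupby("chrom_a", sort=False):
        _one(str(c), grp["r2"].to_numpy())
    _one("within_all", within["r2"].to_numpy())
    _one("between", pairs.loc[~pairs["same_chromosome"], "r2"].to_numpy())
    return pd.DataFrame(rows, columns=["stratum", "mean_r2", "se",
                                       "ci_low", "ci_high", "n_pairs"])


# ---------------------------------------------------------------------------
# decay
# ---------------------------------------------------------------------------

@dataclass
class LDDecayCurve:
    """Per-chromosome r²-versus-distance points, optional smoothed fit, and
    a monotone-trend statistic (Spearman ρ with a one-sided permutation p
    for negative trend)."""

    chromosome: str
    bp_distance: np.ndarray
    r2: np.ndarray
    fit_distance: np.ndarray | None
    fit_r2: np.ndarray | None
    smoother_used: str | None
    spearman_rho: float
    spearman_p_negative: float

    @property
    def n_points(self) -> int:
        return int(self.r2.size)


def _permutation_spearman(x, y, n_permutations, rng):
    rx = rankdata(x)
    ry = rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    zx = (rx - rx.mean()) / sx
    zy = (ry - ry.mean()) / sy
    n = x.size
    rho = float(zx @ zy / n)
    if n_permutations <= 0:
        return rho, float("nan")
    perm = rng.permuted(np.tile(zy, (n_permutations, 1)), axis=1)
    rhos = perm @ zx / n
    p_neg = (1.0 + np.sum(rhos <= rho)) / (n_permutations + 1.0)
    return rho, float(p_neg)


def ld_decay(pairs: pd.DataFrame, min_points: int = 100,
             gam_threshold: int = 1000, loess_frac: float = 0.75,
             grid_points: int = 200, n_permutations: int = 1000,
             seed: int = 0) -> dict:
    """Per-chromosome LD-decay curves from within-chromosome pairs.

    Chromosomes with ≤ ``min_points`` observation points get points only,
    no fitted curve; between ``min_points`` and ``gam_threshold`` points a
    LOESS fit is used; above that a penalized cubic smoothing spline
    (GAM-equivalent, smoothing chosen by generalized cross-validation).
    Fits are evaluated on a ``grid_points``-point distance grid.
    """
    import statsmodels.api as sm
    from scipy.interpolate import make_smoothing_spline

    rng = np.random.default_rng(seed)
    out = {}
    if not len(pairs):
        return out
    within = pairs[pairs["same_chromosome"]
                   & np.isfinite(pairs["r2"].to_numpy(dtype=float))]
    for c, grp in within.groupby("chrom_a", sort=False):
        d = grp["bp_distance"].to_numpy(dtype=float)
        r = grp["r2"].to_numpy(dtype=float)
        rho, p_neg = _permutation_spearman(d, r, n_permutations, rng)
        fit_d = fit_r = None
        smoother = None
        if r.size > min_points:
            fit_d = np.linspace(d.min(), d.max(), grid_points)
            if r.size < gam_threshold:
                smoother = "loess"
                sm_fit = sm.nonparametric.lowess(r, d, frac=loess_frac,
                                                 return_sorted=True)
                fit_r = np.interp(fit_d, sm_fit[:, 0], sm_fit[:, 1])
            else:
                smoother = "spline"
                order = np.argsort(d)
                ds, rs = d[order], r[order]
                # aggregate duplicate distances (spline needs increasing x)
                uniq, inv = np.unique(ds, return_inverse=True)
                means = np.bincount(inv, weights=rs) / np.bincount(inv)
                if uniq.size >= 4:
                    spl = make_smoothing_spline(uniq, means)
                    fit_r = spl(fit_d)
                else:
                    smoother = "loess"
                    sm_fit = sm.nonparametric.lowess(r, d, frac=loess_frac,
                                                     return_sorted=True)
                    fit_r = np.interp(fit_d, sm_fit[:, 0], sm_fit[:, 1])
        out[str(c)] = LDDecayCurve(
            chromosome=str(c), bp_distance=d, r2=r,
            fit_distance=fit_d, fit_r2=fit_r, smoother_used=smoother,
            spearman_rho=rho, spearman_p_negative=p_neg)
    return out
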