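"""Clonal structure: pairwise genotype distances, neighbour joining, and
clonal-lineage assignment.

In a strictly parthenogenetic population the sampled individuals collapse
into one or a few clonal lineages — near-identical multilocus genotypes
separated from other lineages by a wide gulf of divergence.  Rare sex
breaks genotypes apart, so the number of distinct lineages relative to the
sample size is the first line of evidence for cryptic sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric pairwise genotype distances with per-pair shared-site counts."""

    samples: list
    d: np.ndarray
    n_shared_sites: np.ndarray

    @property
    def n(self) -> int:
        return len(self.samples)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.samples, columns=self.samples)

    def undefined_pairs(self) -> list:
        i, j = np.where(np.triu(np.isnan(self.d), k=1))
        return [(self.samples[a], self.samples[b]) for a, b in zip(i, j)]


@dataclass
class ClonalAssignment:
    """Partition of samples into clonal lineages.

    ``n_lineages`` counts all clusters (including singletons); ``n_clones``
    only multi-member lineages; ``n_genotypes`` counts exactly distinct
    multilocus genotypes (identical dosage vectors, missing treated as a
    distinct state).
    """

    samples: list
    clone_id: list
    n_lineages: int
    n_clones: int
    n_genotypes: int
    threshold_used: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.samples, "clone_id": self.clone_id})

    def members(self) -> dict:
        out: dict = {}
        for s, c in zip(self.samples, self.clone_id):
            out.setdefault(c, []).append(s)
        return out


def pairwise_distance(gm: GenotypeMatrix, method: str = "euclidean") -> DistanceMatrix:
    """Euclidean distance between dosage vectors with missing-data rescaling.

    ``d[i,j] = sqrt( Σ_shared (x_i − x_j)² · S / s_ij )`` where the sum runs
    over sites called in both samples, ``s_ij`` is their count and ``S`` the
    total number of sites — so distances are comparable between pairs with
    different missingness.  Pairs sharing no called site get NaN (flagged
    via :meth:`DistanceMatrix.undefined_pairs`).
    """
    if method != "euclidean":
        raise ValueError(f"unknown distance method {method!r}")
    if gm.n_samples < 2:
        raise ValueError("need at least two samples for pairwise distances")
    D = gm.dosage.astype(np.float64)
    M = (gm.dosage != MISSING).astype(np.float64)
    X = D * M
    X2 = X * X
    shared = M @ M.T
    # Σ over shared sites of (xi - xj)^2, zeros outside the joint mask
    ss = X2 @ M.T + M @ X2.T - 2.0 * (X @ X.T)
    S = float(gm.n_sites)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(np.maximum(ss, 0.0) * (S / shared))
    d[shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(samples=list(gm.samples), d=d,
                          n_shared_sites=shared.astype(np.int64))


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def neighbour_joining(dm: DistanceMatrix) -> str:
    """Saitou–Nei neighbour joining; returns an unrooted tree in newick form.

    On an additive distance matrix the generating tree (topology and branch
    lengths) is recovered exactly.  Negative branch lengths are clamped to
    zero with the excess transferred to the sister branch, so path lengths
    through the joined node are preserved.
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbour joining requires at least three samples")
    bad = dm.undefined_pairs()
    if bad:
        raise ValueError(f"undefined distances for pairs: {bad[:5]}")

    d = dm.d.astype(np.float64).copy()
    labels = [_escape(s) for s in dm.samples]

    while len(labels) > 3:
        m = len(labels)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new_label = f"({labels[i]}:{li:.17g},{labels[j]}:{lj:.17g})"
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        labels = [labels[x] for x in keep] + [new_label]

    # final trifurcation by the three-point formulas
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return (f"({labels[0]}:{la:.17g},{labels[1]}:{lb:.17g},"
            f"{labels[2]}:{lc:.17g});")


def _escape(name) -> str:
    s = str(name)
    if any(c in s for c in "(),:;'\" \t"):
        return "'" + s.replace("'", "''") + "'"
    return s


# ---------------------------------------------------------------------------
# clone assignment
# ---------------------------------------------------------------------------

def auto_threshold(distances: np.ndarray) -> float:
    """Distance cutoff at the largest gap in the sorted pairwise distances,
    with zero prepended as a virtual lower bound.

    A clonal population has a bimodal distance distribution — tiny
    mutation-scale differences within lineages, divergence-scale distances
    between them — and the widest gap separates the two modes wherever the
    lineage sizes fall.  In a fully sexual population all distances sit in
    a tight clump far from zero, so the widest gap is the one between
    "identical" and the closest pair, and every genotype stays separate.
    Returns the midpoint of the winning gap.
    """
    ds = np.sort(np.asarray(distances, dtype=float))
    ds = ds[np.isfinite(ds)]
    if ds.size == 0:
        return 0.0
    padded = np.concatenate([[0.0], ds])
    gaps = np.diff(padded)
    k = int(np.argmax(gaps))
    return 0.5 * (padded[k] + padded[k + 1])


def assign_clones(dm: DistanceMatrix, threshold="auto",
                  dosage: np.ndarray | None = None) -> ClonalAssignment:
    """Group samples into clonal lineages by single-linkage clustering.

    Two samples share a lineage iff they are connected by a chain of
    pairwise distances each ≤ ``threshold``.  ``threshold="auto"`` uses
    :func:`auto_threshold`.  ``dosage`` (optional, samples × sites) enables
    the exact distinct-genotype count; otherwise distinct genotypes are
    counted as samples at distance zero from each other.
    """
    cond = dm.condensed()
    if np.isnan(cond).any():
        raise ValueError("undefined distances present; cannot assign clones")
    if threshold == "auto":
        t = auto_threshold(cond)
    else:
        t = float(threshold)

    if dm.n == 1:
        labels = np.array([1])
    else:
        Z = linkage(cond, method="single")
        labels = fcluster(Z, t=t, criterion="distance")

    # canonical labels by first occurrence (sample-order independent given
    # the same sample set)
    remap, clone_ids = {}, []
    for lab in labels:
        if lab not in remap:
            remap[lab] = f"clone_{len(remap) + 1}"
        clone_ids.append(remap[lab])

    counts = pd.Series(clone_ids).value_counts()
    if dosage is not None:
        n_genotypes = len({tuple(row) for row in np.asarray(dosage)})
    else:
        if dm.n == 1:
            n_genotypes = 1
        else:
            Z0 = linkage(cond, method="single")
            n_genotypes = int(fcluster(Z0, t=0.0, criterion="distance").max())
    return ClonalAssignment(
        samples=list(dm.samples), clone_id=clone_ids,
        n_lineages=int(counts.size), n_clones=int((counts >= 2).sum()),
        n_genotypes=n_genotypes, threshold_used=t)
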