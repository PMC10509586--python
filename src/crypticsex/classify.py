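"""Population-level synthesis: combine clonal structure, LD, LD decay and
heterozygosity evidence into a verdict on cryptic sex, plus report output.

The decision logic mirrors the contrast between a strictly parthenogenetic
population (few clonal lineages, r² uniformly high within and between
chromosomes, no decay with distance) and one undergoing cryptic sex (many
distinct genotypes, lower LD, clear decay of r² with distance, often with
within-chromosome r² exceeding between-chromosome r²).  The thresholds are
package defaults calibrated on the simulator's scenario presets — the
verbal criteria they operationalize ("low diversity", "high LD", "evident
decay") have no canonical numeric values — and the raw evidence is always
reported alongside the label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clonal import ClonalAssignment, assign_clones, neighbour_joining, pairwise_distance
from .genotype_io import GenotypeMatrix, polymorphic_sites
from .heterozygosity import HetProfile, detect_het_outliers, relative_het
from .linkage import ld_decay, ld_scan, maf_filter, summarize_ld

LABELS = ("no-evidence-of-sex", "cryptic-sex", "sexual-like", "indeterminate")


@dataclass
class ClassificationThresholds:
    """Tunable decision thresholds (defaults calibrated on simulations)."""

    genotype_frac: float = 0.25   # lineages/sample ratio separating clonal from diverse
    r2_floor: float = 0.8         # "high LD" floor for mean within-chromosome r²
    decay_p: float = 0.01         # permutation p for a significant negative decay
    decay_majority: float = 0.5   # fraction of fitted chromosomes that must decay
    sexual_gap: float = 0.05      # |within − between| mean r² for sexual-like
    sexual_level: float = 0.15    # "near-zero" mean within-chromosome r²


@dataclass
class PopulationClassification:
    label: str
    evidence: dict
    caveats: list = field(default_factory=list)

    def to_json(self) -> str:
        def _clean(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v
        payload = {"label": self.label,
                   "evidence": {k: _clean(v) for k, v in self.evidence.items()},
                   "caveats": list(self.caveats)}
        return json.dumps(payload, indent=2, sort_keys=True)


def classify_population(clones: ClonalAssignment, ld_summary: pd.DataFrame,
                        decay_curves: dict, het: HetProfile,
                        thresholds: ClassificationThresholds | None = None,
                        ) -> PopulationClassification:
    """Label a population from its evidence table.

    Pure function of the inputs: re-running on the same stage outputs
    reproduces the label.  The genotype-diversity criterion is applied to
    the number of clonal lineages (single-linkage clusters), which is
    robust to the minor within-lineage differences that mutation creates;
    the exact distinct-genotype count is reported as evidence.
    """
    t = thresholds or ClassificationThresholds()
    for name, val in (("clonal assignment", clones), ("LD summary", ld_summary),
                      ("decay curves", decay_curves), ("heterozygosity", het)):
        if val is None:
            raise ValueError(f"missing input: {name}")

    n_samples = len(clones.samples)
    summary = ld_summary.set_index("stratum")
    mean_within = (float(summary.loc["within_all", "mean_r2"])
                   if "within_all" in summary.index else float("nan"))
    mean_between = (float(summary.loc["between", "mean_r2"])
                    if "between" in summary.index else float("nan"))

    fitted = [c for c in decay_curves.values() if c.smoother_used is not None]
    sig_decay = [c for c in fitted
                 if np.isfinite(c.spearman_rho) and c.spearman_rho < 0
                 and np.isfinite(c.spearman_p_negative)
                 and c.spearman_p_negative < t.decay_p]

    n_outliers = int(het.table["outlier"].sum()) if "outlier" in het.table else None

    evidence = {
        "n_samples": n_samples,
        "n_genotypes": clones.n_genotypes,
        "n_lineages": clones.n_lineages,
        "n_clones": clones.n_clones,
        "genotype_diversity": clones.n_lineages / n_samples,
        "mean_within_r2": mean_within,
        "mean_between_r2": mean_between,
        "n_fitted_chromosomes": len(fitted),
        "n_significant_decay": len(sig_decay),
        "n_het_outliers": n_outliers,
        "clone_threshold": clones.threshold_used,
    }
    caveats = []

    if clones.n_lineages < 2 or clones.n_genotypes < 2:
        caveats.append("single clone — LD uninformative (insufficient polymorphism)")
        return PopulationClassification("indeterminate", evidence, caveats)

    low_diversity = clones.n_lineages <= t.genotype_frac * n_samples
    high_ld = np.isfinite(mean_within) and mean_within >= t.r2_floor
    no_decay = len(sig_decay) == 0
    decay_majority = (len(fitted) > 0
                      and len(sig_decay) >= t.decay_majority * len(fitted))

    # With clear clonal structure and no decay signal, the absence of any
    # MAF-passing within-chromosome marker pair (LD uninformative) does not
    # override the clonal verdict — low polymorphism is itself the expected
    # footprint of strict parthenogenesis.
    ld_uninformative = not np.isfinite(mean_within)

    if low_diversity and no_decay and (high_ld or ld_uninformative):
        label = "no-evidence-of-sex"
        if ld_uninformative:
            caveats.append("no MAF-passing within-chromosome pairs; "
                           "verdict rests on clonal structure alone")
    elif not low_diversity and decay_majority:
        gap_small = (np.isfinite(mean_within) and np.isfinite(mean_between)
                     and abs(mean_within - mean_between) < t.sexual_gap)
        near_zero = np.isfinite(mean_within) and mean_within < t.sexual_level
        label = "sexual-like" if (gap_small and near_zero) else "cryptic-sex"
    else:
        label = "indeterminate"
        caveats.append("evidence mixed; inspect the evidence table")
    if not np.isfinite(mean_within):
        caveats.append("no within-chromosome LD pairs available")
    return PopulationClassification(label, evidence, caveats)


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def analyze_population(gm: GenotypeMatrix, min_maf: float = 0.2,
                       max_bp: int = 8_000_000,
                       max_between_pairs: int = 200_000,
                       clone_threshold="auto", seed: int = 0,
                       n_permutations: int = 1000,
                       thresholds: ClassificationThresholds | None = None) -> dict:
    """Run every analysis stage on an already-filtered genotype matrix.

    Returns a dict with the distance matrix, newick tree, clonal
    assignment, LD pairs/summary/decay, heterozygosity profile (with
    outlier flags when ≥5 samples) and the final classification.
    """
    poly = polymorphic_sites(gm)
    het = relative_het(poly)
    if len(het.table) >= 5:
        detect_het_outliers(het)

    dm = pairwise_distance(gm)
    tree = neighbour_joining(dm) if gm.n_samples >= 3 else None
    clones = assign_clones(dm, threshold=clone_threshold, dosage=gm.dosage)

    mf = maf_filter(gm, min_maf=min_maf)
    pairs = ld_scan(mf, mode="both", max_bp=max_bp,
                    max_between_pairs=max_between_pairs, seed=seed)
    summary = summarize_ld(pairs)
    decay = ld_decay(pairs, n_permutations=n_permutations, seed=seed)

    classification = classify_population(clones, summary, decay, het,
                                         thresholds=thresholds)
    return {
        "polymorphic": poly, "het": het, "distance": dm, "tree": tree,
        "clones": clones, "ld_pairs": pairs, "ld_summary": summary,
        "ld_decay": decay, "classification": classification,
    }


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

def make_report(results: dict, out_dir) -> list:
    """Write the report bundle: LD violin plot, decay panels, heterozygosity
    strip plot, NJ tree, classification JSON and a Markdown summary.
    Deterministic given the inputs; returns the list of files written."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _save(fig, name):
        p = out / name
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    pairs = results.get("ld_pairs")
    notes = []
    if pairs is not None and len(pairs):
        within = pairs.loc[pairs["same_chromosome"], "r2"].dropna().to_numpy()
        between = pairs.loc[~pairs["same_chromosome"], "r2"].dropna().to_numpy()
        groups = [(g, lab, col) for g, lab, col in
                  [(within, "within", "#7b52a8"), (between, "between", "#c0392b")]
                  if g.size > 0]
        if groups:
            fig, ax = plt.subplots(figsize=(4.5, 4))
            data = [g for g, _, _ in groups]
            parts = ax.violinplot(data, showextrema=False)
            for body, (_, _, col) in zip(parts["bodies"], groups):
                body.set_facecolor(col)
                body.set_alpha(0.6)
            for x, (g, _, _) in enumerate(groups, start=1):
                m = g.mean()
                se = g.std(ddof=1) / np.sqrt(g.size) if g.size > 1 else 0.0
                ax.errorbar([x], [m], yerr=[[2 * se], [2 * se]], fmt="o",
                            color="black", capsize=4)
            ax.set_xticks(range(1, len(groups) + 1))
            ax.set_xticklabels([lab for _, lab, _ in groups])
            ax.set_ylabel("r$^2$")
            ax.set_ylim(-0.02, 1.02)
            ax.set_title("LD within vs between chromosomes")
            fig.tight_layout()
            _save(fig, "ld_violin.png")
        else:
            notes.append("LD violin plot omitted: no defined r² values")
    else:
        notes.append("LD violin plot omitted: no LD pairs")

    decay = results.get("ld_decay") or {}
    panels = [c for c in decay.values() if c.n_points > 0]
    if panels:
        ncol = min(4, len(panels))
        nrow = int(np.ceil(len(panels) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.4 * nrow),
                                 squeeze=False)
        for ax in axes.flat[len(panels):]:
            ax.axis("off")
        for ax, curve in zip(axes.flat, panels):
            ax.plot(curve.bp_distance / 1e6, curve.r2, ".", ms=2, alpha=0.4)
            if curve.fit_r2 is not None:
                ax.plot(curve.fit_distance / 1e6, curve.fit_r2, "-", color="tab:blue")
            ax.set_title(f"{curve.chromosome} (n={curve.n_points})", fontsize=8)
            ax.set_ylim(-0.02, 1.02)
        fig.supxlabel("distance (Mb)")
        fig.supylabel("r$^2$")
        fig.tight_layout()
        _save(fig, "ld_decay.png")
    else:
        notes.append("decay panels omitted: no within-chromosome pairs")

    het = results.get("het")
    if het is not None and len(het.table):
        fig, ax = plt.subplots(figsize=(4, 4))
        vals = het.table["relative_het"].to_numpy(dtype=float)
        rng = np.random.default_rng(0)
        x = rng.uniform(-0.08, 0.08, size=vals.size)
        flagged = het.table.get("outlier", pd.Series(False, index=het.table.index))
        ax.scatter(x[~flagged], vals[~flagged], s=18, color="gray")
        if flagged.any():
            ax.scatter(x[flagged.to_numpy()], vals[flagged.to_numpy()],
                       s=24, color="crimson", label="outlier")
            ax.legend()
        ax.set_xlim(-0.5, 0.5)
        ax.set_xticks([])
        ax.set_ylabel("relative heterozygosity")
        fig.tight_layout()
        _save(fig, "heterozygosity.png")

    tree = results.get("tree")
    if tree:
        p = out / "nj_tree.nwk"
        p.write_text(tree + "\n")
        written.append(p)

    cls = results.get("classification")
    if cls is not None:
        p = out / "classification.json"
        p.write_text(cls.to_json() + "\n")
        written.append(p)

    summary = results.get("ld_summary")
    if summary is not None:
        p = out / "ld_summary.tsv"
        summary.to_csv(p, sep="\t", index=False)
        written.append(p)
    if het is not None:
        p = out / "heterozygosity.tsv"
        het.table.to_csv(p, sep="\t", index=False)
        written.append(p)
    clones = results.get("clones")
    if clones is not None:
        p = out / "clones.tsv"
        clones.to_frame().to_csv(p, sep="\t", index=False)
        written.append(p)

    md = ["# Population report", ""]
    if cls is not None:
        md += [f"**Classification:** `{cls.label}`", ""]
        md += ["| evidence | value |", "|---|---|"]
        for k, v in cls.evidence.items():
            if isinstance(v, float):
                v = f"{v:.4g}"
            md.append(f"| {k} | {v} |")
        md.append("")
        for c in cls.caveats:
            md.append(f"- caveat: {c}")
    for nmsg in notes:
        md.append(f"- note: {nmsg}")
    p = out / "report.md"
    p.write_text("\n".join(md) + "\n")
    written.append(p)
    return written
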