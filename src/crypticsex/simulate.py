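"""Forward simulator of parthenogenetic populations with optional rare sex.

The model mirrors the biology of homozygous automictic parthenogens such as
*Timema* stick insects.  Reproduction is by gamete duplication: a single
meiotic product is doubled, so offspring are fully homozygous and any
heterozygosity of the mother is lost in one generation (genome-wide loss of
heterozygosity, LOH).  Sex determination is X0: females carry two X
chromosomes, males one.  Rare males arise by accidental loss of an X during
parthenogenesis (rate ``male_rate`` per offspring) and can sire sexual
offspring (probability ``sex_rate`` per offspring, conditional on at least
one male being alive).  A male transmits his single X to half his offspring;
the other half are X0 males.

Genomes live on a finite predefined site grid (matching the fixed-locus
character of RADseq data): ``n_sites`` biallelic positions spread over
``n_chromosomes`` autosomes of ``chromosome_length_bp`` each, plus
``n_x_sites`` X-linked positions.  Mutation flips one allele of one
homologue at a site with probability ``mutation_rate`` per site per
generation.  Crossovers are Poisson along each chromosome (``crossover_rate``
expected per meiosis) at uniform basepair positions.

The population is founded by ``n_founder_clones`` fully homozygous females;
with two founders, each pair differs at exactly ``founder_divergence`` of
the sites (exact by construction).  Generations are non-overlapping with
constant size ``pop_size``; after ``generations`` generations,
``sample_size`` females (plus optionally ``sample_males`` males) are
genotyped.  The emitted :class:`~crypticsex.genotype_io.GenotypeMatrix`
carries synthesized depth (Poisson, mean 30), genotype quality and allele
depths so the VCF filters and the allele-balance ploidy screen are
exercisable; a truth table records each sampled individual's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MISSING

FEMALE, MALE = "female", "male"
PARTHENOGENETIC, SEXUAL = "parthenogenetic", "sexual"


@dataclass
class SimConfig:
    """Simulation parameters; defaults reflect the study design they emulate
    (24 sampled females from populations of ~10³–10⁴ RADseq SNPs on 12
    autosomal linkage groups, descended from few homozygous founder clones).
    """

    n_chromosomes: int = 12
    chromosome_length_bp: int = 50_000_000
    n_sites: int = 5000            # autosomal SNP positions, split evenly
    n_x_sites: int = 100           # X-linked positions (sex determination only)
    n_founder_clones: int = 2
    founder_divergence: float = 0.2
    pop_size: int = 500
    sample_size: int = 24
    sample_males: int = 0
    generations: int = 50
    sex_rate: float = 0.0          # P(offspring produced sexually | male alive)
    male_rate: float = 0.0         # P(X loss per parthenogenetic offspring)
    mutation_rate: float = 1e-6    # per site per haplotype per generation
    crossover_rate: float = 1.0    # expected crossovers per chromosome per meiosis
    mean_depth: float = 30.0       # synthesized sequencing depth
    seed: int = 0

    def __post_init__(self):
        for name in ("sex_rate", "male_rate", "mutation_rate", "founder_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sample_size > self.pop_size:
            raise ValueError("sample_size exceeds pop_size")
        if self.n_founder_clones < 1:
            raise ValueError("need at least one founder clone")


PRESETS = {
    "strict": dict(sex_rate=0.0, male_rate=0.0),
    "rare-sex": dict(sex_rate=0.1, male_rate=0.05),
    "sexual": dict(sex_rate=1.0, male_rate=0.05),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Build a :class:`SimConfig` from a named reproductive scenario.

    ``strict`` = pure automictic parthenogenesis, no males; ``rare-sex`` =
    occasional X-loss males and rare sexual crosses; ``sexual`` = sexual
    reproduction whenever males are available (males seeded by X loss).
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def _sample_unique_positions(rng: np.random.Generator, lo: int, hi: int,
                             k: int) -> np.ndarray:
    """k distinct sorted integers uniform on [lo, hi); cheap even when the
    range is enormous (rejection on duplicates, never materializes it)."""
    if k > hi - lo:
        raise ValueError("more sites requested than available positions")
    got = np.array([], dtype=np.int64)
    while got.size < k:
        draw = rng.integers(lo, hi, size=2 * (k - got.size) + 8, dtype=np.int64)
        got = np.unique(np.concatenate([got, draw]))
    # deterministic thinning to exactly k
    if got.size > k:
        keep = rng.choice(got.size, size=k, replace=False)
        got = got[np.sort(keep)]
    return got

class GenomeLayout:
    """Site coordinates: chromosome labels, bp positions and index slices."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
        per = np.full(cfg.n_chromosomes, cfg.n_sites // cfg.n_chromosomes)
        per[: cfg.n_sites % cfg.n_chromosomes] += 1
        counts = list(per)
        if cfg.n_x_sites > 0:
            chrom_names.append("chrX")
            counts.append(cfg.n_x_sites)
        chroms, positions, slices = [], [], {}
        start = 0
        for name, k in zip(chrom_names, counts):
            pos = _sample_unique_positions(
                rng, 1, cfg.chromosome_length_bp, k)
            chroms.extend([name] * k)
            positions.append(pos)
            slices[name] = slice(start, start + k)
            start += k
        self.chrom = np.asarray(chroms)
        self.pos = np.concatenate(positions) if positions else np.array([], np.int64)
        self.slices = slices
        self.n_sites = start
        self.x_slice = slices.get("chrX")
        # fixed ref/alt nucleotides per site
        bases = np.array(list("ACGT"))
        ref_i = rng.integers(0, 4, size=self.n_sites)
        alt_i = (ref_i + rng.integers(1, 4, size=self.n_sites)) % 4
        self.ref = bases[ref_i]
        self.alt = bases[alt_i]


# ---------------------------------------------------------------------------
# reproduction mechanics
# ---------------------------------------------------------------------------

def make_founders(cfg: SimConfig, layout: GenomeLayout,
                  rng: np.random.Generator) -> np.ndarray:
    """Return k fully homozygous founder genomes, shape (k, 2, L).

    With one founder the population is monomorphic; with two, founders
    differ at exactly ``round(d·L)`` sites (a seeded draw of the
    founder-distinguishing set); with more, founder alleles are drawn
    Bernoulli(1/2) at a ``2d`` fraction of sites so the expected pairwise
    divergence is ``d``.
    """
    k, L, d = cfg.n_founder_clones, layout.n_sites, cfg.founder_divergence
    hap = np.zeros((k, L), dtype=np.uint8)
    if k == 2:
        n_diff = int(round(d * L))
        diff = rng.choice(L, size=n_diff, replace=False)
        hap[1, diff] = 1
    elif k > 2:
        p_var = min(1.0, 2.0 * d)
        var = rng.random(L) < p_var
        hap[:, var] = rng.integers(0, 2, size=(k, int(var.sum())), dtype=np.uint8)
    return np.stack([hap, hap.copy()], axis=1)  # homozygous: both copies equal


def meiosis_gamete(parent: np.ndarray, cfg: SimConfig, layout: GenomeLayout,
                   rng: np.random.Generator) -> np.ndarray:
    """One recombinant haploid product of meiosis, shape (L,).

    Per chromosome, ``Poisson(crossover_rate)`` crossovers at uniform bp
    positions; the returned strand alternates between the two parental
    homologues at the crossover points, starting from a random homologue.
    """
    gamete = np.empty(layout.n_sites, dtype=np.uint8)
    for name, sl in layout.slices.items():
        h0, h1 = parent[0, sl], parent[1, sl]
        start = rng.integers(0, 2)
        n_xo = rng.poisson(cfg.crossover_rate)
        if n_xo == 0 or np.array_equal(h0, h1):
            gamete[sl] = h1 if start else h0
            continue
        xo = np.sort(rng.uniform(0, cfg.chromosome_length_bp, size=n_xo))
        src = (start + np.searchsorted(xo, layout.pos[sl])) % 2
        gamete[sl] = np.where(src == 0, h0, h1)
    return gamete


def _mutate(child: np.ndarray, sex: str, cfg: SimConfig,
            layout: GenomeLayout, rng: np.random.Generator) -> int:
    """Flip alleles in place at rate μ per site per homologue; returns the
    number of mutations applied."""
    mu = cfg.mutation_rate
    if mu <= 0:
        return 0
    n_mut = rng.binomial(2 * layout.n_sites, mu)
    if n_mut == 0:
        return 0
    flat = rng.choice(2 * layout.n_sites, size=n_mut, replace=False)
    hom, site = flat // layout.n_sites, flat % layout.n_sites
    child[hom, site] ^= 1
    if sex == MALE and layout.x_slice is not None:
        # X0 male: single X carried mirrored on both homologues
        child[1, layout.x_slice] = child[0, layout.x_slice]
    return int(n_mut)


def reproduce_parthenogenetic(mother: np.ndarray, cfg: SimConfig,
                              layout: GenomeLayout,
                              rng: np.random.Generator) -> tuple[np.ndarray, str]:
    """Automictic (gamete-duplication) offspring: homozygous at every site.

    With probability ``male_rate`` one X is lost and the offspring is an X0
    male.  Mutation is applied after duplication, so μ=0 offspring have
    relative heterozygosity exactly 0.
    """
    g = meiosis_gamete(mother, cfg, layout, rng)
    child = np.stack([g, g.copy()], axis=0)
    sex = MALE if (cfg.male_rate > 0 and rng.random() < cfg.male_rate) else FEMALE
    _mutate(child, sex, cfg, layout, rng)
    return child, sex


def reproduce_sexual(mother: np.ndarray, father: np.ndarray, cfg: SimConfig,
                     layout: GenomeLayout,
                     rng: np.random.Generator) -> tuple[np.ndarray, str]:
    """Sexual offspring of a female and an X0 male.

    The father transmits his single X to half his offspring (daughters);
    the nullo-X gamete yields X0 sons carrying only the maternal X.
    """
    gm = meiosis_gamete(mother, cfg, layout, rng)
    gf = meiosis_gamete(father, cfg, layout, rng)
    child = np.stack([gm, gf], axis=0)
    sex = FEMALE
    if layout.x_slice is not None:
        if rng.random() < 0.5:  # father's nullo-X gamete
            sex = MALE
            child[1, layout.x_slice] = child[0, layout.x_slice]
    elif rng.random() < 0.5:
        sex = MALE
    _mutate(child, sex, cfg, layout, rng)
    return child, sex


# ---------------------------------------------------------------------------
# population loop
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    truth: pd.DataFrame
    config: SimConfig
    haplotypes: np.ndarray = field(repr=False, default=None)
    layout: GenomeLayout = field(repr=False, default=None)


def run_simulation(cfg: SimConfig) -> SimResult:
    """Run the forward simulation and genotype a sample of the final
    generation.  Deterministic given ``cfg`` (including its seed)."""
    rng = np.random.default_rng(cfg.seed)
    layout = GenomeLayout(cfg, rng)
    founders = make_founders(cfg, layout, rng)
    k, N = cfg.n_founder_clones, cfg.pop_size

    # generation 0: N females cloned from the founders, round-robin
    lineage = np.arange(N) % k
    pop = founders[lineage].copy()
    sexes = np.array([FEMALE] * N, dtype=object)
    mothers = np.full(N, "", dtype=object)
    fathers = np.full(N, "", dtype=object)
    modes = np.full(N, PARTHENOGENETIC, dtype=object)
    ids = np.array([f"g0_i{j}" for j in range(N)], dtype=object)
    # fully homozygous individuals admit a meiosis shortcut (any meiotic
    # product equals either homologue)
    hom = np.all(pop[:, 0, :] == pop[:, 1, :], axis=1)

    for gen in range(1, cfg.generations + 1):
        females = np.flatnonzero(sexes == FEMALE)
        males = np.flatnonzero(sexes == MALE)
        if females.size == 0:
            raise RuntimeError(f"population extinct (no females) at generation {gen}")
        new_pop = np.empty_like(pop)
        new_hom = np.empty(N, dtype=bool)
        new_sexes = np.empty(N, dtype=object)
        new_mothers = np.empty(N, dtype=object)
        new_fathers = np.empty(N, dtype=object)
        new_modes = np.empty(N, dtype=object)
        new_lineage = np.empty(N, dtype=np.int64)
        new_ids = np.array([f"g{gen}_i{j}" for j in range(N)], dtype=object)

        m_idx = females[rng.integers(0, females.size, size=N)]
        if cfg.sex_rate > 0 and males.size > 0:
            sexual_mask = rng.random(N) < cfg.sex_rate
            f_idx = males[rng.integers(0, males.size, size=N)]
        else:
            sexual_mask = np.zeros(N, dtype=bool)
            f_idx = np.zeros(N, dtype=np.intp)

        for j in range(N):
            mi = m_idx[j]
            if sexual_mask[j]:
                fi = f_idx[j]
                child, sex = reproduce_sexual(pop[mi], pop[fi], cfg, layout, rng)
                new_pop[j] = child
                new_hom[j] = bool(np.array_equal(child[0], child[1]))
                new_fathers[j] = ids[fi]
                new_modes[j] = SEXUAL
                new_lineage[j] = -1  # recombinant: no single clonal lineage
            else:
                if hom[mi]:
                    # gamete of a fully homozygous parent is the parent's
                    # haplotype whatever the crossovers; skip the meiosis draws
                    new_pop[j, 0] = pop[mi, 0]
                    new_pop[j, 1] = pop[mi, 0]
                    sex = (MALE if (cfg.male_rate > 0
                                    and rng.random() < cfg.male_rate)
                           else FEMALE)
                    n_mut = _mutate(new_pop[j], sex, cfg, layout, rng)
                    new_hom[j] = n_mut == 0
                else:
                    child, sex = reproduce_parthenogenetic(pop[mi], cfg,
                                                           layout, rng)
                    new_pop[j] = child
                    new_hom[j] = bool(np.array_equal(child[0], child[1]))
                new_fathers[j] = ""
                new_modes[j] = PARTHENOGENETIC
                new_lineage[j] = lineage[mi]
            new_sexes[j] = sex
            new_mothers[j] = ids[mi]
        pop, sexes, mothers, fathers = new_pop, new_sexes, new_mothers, new_fathers
        modes, lineage, ids, hom = new_modes, new_lineage, new_ids, new_hom

    # sample final generation
    females = np.flatnonzero(sexes == FEMALE)
    males = np.flatnonzero(sexes == MALE)
    if females.size < cfg.sample_size:
        raise RuntimeError(
            f"only {females.size} females available, need {cfg.sample_size}")
    take = rng.choice(females, size=cfg.sample_size, replace=False)
    if cfg.sample_males > 0:
        n_m = min(cfg.sample_males, males.size)
        take = np.concatenate([take, rng.choice(males, size=n_m, replace=False)])
    take = np.sort(take)

    truth = pd.DataFrame({
        "id": ids[take],
        "generation": cfg.generations,
        "mother": mothers[take],
        "father": fathers[take],
        "production_mode": modes[take],
        "sex": sexes[take],
        "lineage": lineage[take],
        "ploidy": 2,
    })
    gm = genotype_sample(pop[take], [str(s) for s in ids[take]],
                         dict(zip(ids[take], sexes[take])), cfg, layout, rng)
    return SimResult(genotypes=gm, truth=truth, config=cfg,
                     haplotypes=pop[take], layout=layout)


def genotype_sample(haps: np.ndarray, names: list, sex_labels: dict,
                    cfg: SimConfig, layout: GenomeLayout,
                    rng: np.random.Generator) -> GenotypeMatrix:
    """Turn sampled haplotypes into a GenotypeMatrix with synthesized
    sequencing annotations (INFO DP ~ Poisson(mean_depth); per-call DP
    Poisson; AD binomial with allele balance 1/2 at heterozygous calls;
    GQ fixed high so default filters are pass-through on clean data)."""
    n, _, L = haps.shape
    dosage = haps.sum(axis=1).astype(np.int8)
    site_depth = rng.poisson(cfg.mean_depth, size=L).astype(float)
    call_dp = rng.poisson(cfg.mean_depth, size=(n, L)).astype(np.int32)
    call_dp = np.maximum(call_dp, 1)
    alt = np.where(dosage == 2, call_dp, 0).astype(np.int32)
    het = dosage == 1
    alt[het] = rng.binomial(call_dp[het], 0.5)
    ad_ref = (call_dp - alt).astype(np.int32)
    gq = np.full((n, L), 99.0)
    sites = pd.DataFrame({
        "chrom": layout.chrom, "pos": layout.pos,
        "ref": layout.ref, "alt": layout.alt,
        "site_depth": site_depth,
        "n_alt": np.ones(L, dtype=np.int32),
    })
    return GenotypeMatrix(samples=list(names), sites=sites, dosage=dosage,
                          gq=gq, ad_ref=ad_ref, ad_alt=alt,
                          site_qual=np.full(L, 1000.0),
                          sex_labels=dict(sex_labels))


def config_to_json(cfg: SimConfig) -> dict:
    return asdict(cfg)
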