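"""Relative heterozygosity, outlier flags, cross expectations, allele
balance and LD robustness to outlier removal."""

import numpy as np
import pytest

from crypticsex import (
    MISSING,
    allele_balance_screen,
    cross_het_distribution,
    detect_het_outliers,
    expected_cross_het,
    ld_without_outliers,
    maf_filter,
    polymorphic_sites,
    relative_het,
)
from crypticsex.simulate import (
    GenomeLayout,
    SimConfig,
    reproduce_sexual,
)
from conftest import make_matrix


class TestRelativeHet:
    def test_simple_ratio(self):
        dosage = np.zeros((2, 100), dtype=np.int8)
        dosage[0, :5] = 1
        dosage[1, :100] = 2  # keeps every site polymorphic
        prof = relative_het(make_matrix(dosage))
        assert prof.values["s0"] == pytest.approx(0.05)

    def test_fully_homozygous_zero(self):
        dosage = np.array([[0, 2, 0, 2], [2, 0, 2, 0]], dtype=np.int8)
        prof = relative_het(make_matrix(dosage))
        assert (prof.values == 0).all()

    def test_missing_excluded_both_sides(self):
        dosage = np.array([[1, MISSING, 0, 1], [0, 2, 2, 0]], dtype=np.int8)
        prof = relative_het(make_matrix(dosage))
        assert prof.values["s0"] == pytest.approx(2 / 3)

    def test_no_called_sites_is_nan(self):
        dosage = np.array([[MISSING, MISSING], [0, 2]], dtype=np.int8)
        assert np.isnan(relative_het(make_matrix(dosage)).values["s0"])

    def test_median_across_chromosomes(self):
        dosage = np.zeros((2, 6), dtype=np.int8)
        dosage[0] = [1, 1, 0, 0, 0, 0]  # chrA het=1.0, chrB 0, chrC 0
        dosage[1] = [0, 0, 2, 2, 2, 2]
        gm = make_matrix(dosage, chrom=["cA", "cA", "cB", "cB", "cC", "cC"],
                         pos=[1, 2, 1, 2, 1, 2])
        prof = relative_het(gm)
        assert prof.table.set_index("sample").loc["s0", "median_chrom_het"] == 0.0
        assert prof.per_chromosome.loc["s0", "cA"] == 1.0

    def test_cross_offspring_het_near_parental_divergence(self):
        # one generation after a cross between homozygous clones differing
        # at 20% of sites, offspring het ~ d at the divergent sites
        rng = np.random.default_rng(8)
        cfg = SimConfig(n_chromosomes=2, n_sites=1000, n_x_sites=0,
                        mutation_rate=0.0, seed=8)
        layout = GenomeLayout(cfg, rng)
        diff = rng.random(1000) < 0.2
        mother = np.zeros((2, 1000), dtype=np.uint8)
        father = np.zeros((2, 1000), dtype=np.uint8)
        father[:, diff] = 1
        child, _ = reproduce_sexual(mother, father, cfg, layout, rng)
        het = (child[0] != child[1]).mean()
        assert het == pytest.approx(diff.mean())


class TestOutliers:
    def test_single_extreme_value_flagged(self):
        vals = np.array([0.01] * 20 + [0.30])
        dosage = np.zeros((21, 200), dtype=np.int8)
        for i, v in enumerate(vals):
            dosage[i, : int(v * 200)] = 1
        dosage[0, 195:] = 2
        prof = relative_het(make_matrix(dosage))
        flags = detect_het_outliers(prof)
        assert flags.sum() == 1
        assert flags["s20"]

    def test_all_equal_no_outliers(self):
        dosage = np.zeros((6, 100), dtype=np.int8)
        dosage[:, :2] = 1  # identical small het everywhere
        dosage[0, 99] = 2
        prof = relative_het(make_matrix(dosage))
        assert detect_het_outliers(prof).sum() == 0

    def test_fs_like_population_flags_exactly_the_sexual_four(self):
        # 17 parthenogenetic (homozygous) + 4 offspring of a cross between
        # clones diverged at 20% of sites
        rng = np.random.default_rng(1)
        n_sites = 1000
        diff = rng.random(n_sites) < 0.2
        dosage = np.zeros((21, n_sites), dtype=np.int8)
        dosage[8:17, diff] = 2           # second clone
        dosage[17:21, diff] = 1
        gm = polymorphic_sites(make_matrix(dosage))
        prof = relative_het(gm)
        flags = detect_het_outliers(prof)
        assert set(np.flatnonzero(flags.to_numpy())) == {17, 18, 19, 20}

    def test_requires_five_samples(self):
        prof = relative_het(make_matrix(np.zeros((3, 10), dtype=np.int8)))
        with pytest.raises(ValueError):
            detect_het_outliers(prof)


class TestExpectedCrossHet:
    def test_fully_divergent_parents(self):
        gm = make_matrix(np.array([[0] * 10, [2] * 10], dtype=np.int8))
        assert expected_cross_het(gm, "s0", "s1") == 1.0

    def test_identical_homozygous_parents(self):
        gm = make_matrix(np.array([[0, 2, 0], [0, 2, 0]], dtype=np.int8))
        assert expected_cross_het(gm, "s0", "s1") == 0.0

    def test_hand_arithmetic_mixture(self):
        # 30 hom-diff, 60 hom-same, 10 one-het of 100 sites -> 0.35
        a = np.array([0] * 30 + [0] * 30 + [2] * 30 + [1] * 10, dtype=np.int8)
        b = np.array([2] * 30 + [0] * 30 + [2] * 30 + [0] * 10, dtype=np.int8)
        gm = make_matrix(np.stack([a, b]))
        assert expected_cross_het(gm, "s0", "s1") == pytest.approx(0.35)

    def test_self_cross_identity(self):
        # expected het of a "self cross" = parent's own het / 2
        rng = np.random.default_rng(4)
        dosage = rng.choice([0, 1, 2], size=(2, 300), p=[0.45, 0.1, 0.45])
        gm = make_matrix(dosage.astype(np.int8))
        prof = relative_het(gm)
        for s in gm.samples:
            dup = make_matrix(np.stack([dosage[gm.samples.index(s)]] * 2)
                              .astype(np.int8))
            assert expected_cross_het(dup, "s0", "s1") == pytest.approx(
                prof.values[s] / 2)

    def test_distribution_rows_are_pairs(self):
        gm = make_matrix(np.array([[0, 2], [2, 0], [0, 0]], dtype=np.int8))
        dist = cross_het_distribution(gm)
        assert len(dist) == 3
        assert set(dist.columns) == {"parent_a", "parent_b", "expected_het"}


class TestAlleleBalance:
    def _gm(self, alt_p, n_calls=120, depth=30, seed=0):
        rng = np.random.default_rng(seed)
        dosage = np.ones((1, n_calls), dtype=np.int8)
        alt = rng.binomial(depth, alt_p, size=(1, n_calls)).astype(np.int32)
        ref = np.full((1, n_calls), depth, dtype=np.int32) - alt
        return make_matrix(dosage, ad_ref=ref, ad_alt=alt)

    def test_diploid_consistent(self):
        rep = allele_balance_screen(self._gm(0.5))
        assert rep.loc[0, "verdict"] == "diploid-consistent"

    def test_triploid_consistent(self):
        rep = allele_balance_screen(self._gm(1 / 3))
        assert rep.loc[0, "verdict"] == "triploid-consistent"

    def test_insufficient_data(self):
        rep = allele_balance_screen(self._gm(0.5, n_calls=10))
        assert rep.loc[0, "verdict"] == "insufficient-data"

    def test_no_ad_fields(self):
        rep = allele_balance_screen(make_matrix(np.ones((2, 60), np.int8)))
        assert (rep["verdict"] == "insufficient-data").all()


class TestLdWithoutOutliers:
    def test_noop_removal_identical_summaries(self, strict_sim):
        gm = strict_sim.genotypes
        flags = np.zeros(gm.n_samples, dtype=bool)
        res = ld_without_outliers(gm, flags, seed=0)
        import pandas as pd
        pd.testing.assert_frame_equal(res["summary_all"],
                                      res["summary_no_outliers"])

    def test_injected_outlier_removed_restores_r2_one(self, strict_sim):
        gm = strict_sim.genotypes.take_samples(range(strict_sim.genotypes.n_samples))
        # replace sample 0 by an artificial recombinant between the two
        # clone genotypes (random parental choice per site breaks the LD)
        rng = np.random.default_rng(7)
        other = gm.dosage[1:]
        lo, hi = other.min(axis=0), other.max(axis=0)
        pick = rng.random(gm.n_sites) < 0.5
        gm.dosage[0, :] = np.where(pick, lo, hi)
        flags = np.zeros(gm.n_samples, dtype=bool)
        flags[0] = True
        res = ld_without_outliers(gm, flags, seed=0)
        sub = res["summary_no_outliers"].set_index("stratum")
        assert sub.loc["within_all", "mean_r2"] == pytest.approx(1.0, abs=1e-12)
        full = res["summary_all"].set_index("stratum")
        assert full.loc["within_all", "mean_r2"] < 1.0

    def test_rare_sex_removal_changes_little(self, rare_sex_sim):
        gm = rare_sex_sim.genotypes
        prof = relative_het(polymorphic_sites(gm))
        flags = detect_het_outliers(prof)
        if flags.sum() == 0 or gm.n_samples - flags.sum() < 4:
            pytest.skip("no outliers in this replicate")
        res = ld_without_outliers(gm, flags.to_numpy(), seed=0)
        a = res["summary_all"].set_index("stratum")
        b = res["summary_no_outliers"].set_index("stratum")
        if "within_all" in a.index and "within_all" in b.index:
            assert abs(a.loc["within_all", "mean_r2"]
                       - b.loc["within_all", "mean_r2"]) < 0.1

    def test_too_few_remaining_rejected(self):
        gm = make_matrix(np.zeros((5, 10), dtype=np.int8))
        with pytest.raises(ValueError):
            ld_without_outliers(gm, np.array([True, True, False, False, False]))
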