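"""Distributional checks on the synthetic-population generator."""

import numpy as np
import pytest

from seeddisp.kernels import DispersalKernel, DispersalParams
from seeddisp.population import MISSING, Population, StudyWindow, as_population
from seeddisp.simulate import (IMMIGRANT, SELF, ThomasClustering,
                               apply_genotyping_error, distance_density_design,
                               draw_founder_genotypes, seed_environment_design,
                               simulate_adults, simulate_allele_frequencies,
                               simulate_offspring_cohort,
                               simulate_seed_fate_experiment)


class TestAdults:
    def test_poisson_count_matches_intensity(self, window):
        counts = [len(simulate_adults(window, 2.5e-5, seed=s)) for s in range(60)]
        # Poisson mean = intensity * area = 100; 3 MC sigma band
        assert abs(np.mean(counts) - 100) < 3 * 10 / np.sqrt(60)

    def test_female_fraction(self, window):
        sexes = [a.sex for s in range(30)
                 for a in simulate_adults(window, 2.5e-5, female_fraction=0.5, seed=s)]
        frac = np.mean([s == "female" for s in sexes])
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(len(sexes))

    def test_all_points_inside_window_minus_holes(self):
        win = StudyWindow.rectangle(1000, 1000,
                                    holes=[[(200, 200), (400, 200), (400, 400),
                                            (200, 400)]])
        adults = simulate_adults(win, 5e-4, seed=4)
        pop = as_population(adults)
        assert win.contains(pop.xy[:, 0], pop.xy[:, 1]).all()
        in_hole = ((pop.xy > 200) & (pop.xy < 400)).all(axis=1)
        assert not in_hole.any()

    def test_adult_dbh_and_cohort(self, window):
        pop = as_population(simulate_adults(window, 2.5e-5, seed=5))
        assert (pop.dbh >= 10).all()
        assert (pop.cohort == "adult").all()

    def test_empty_window_rejected(self, window):
        with pytest.raises(ValueError):
            simulate_adults(window, intensity=0.0)

    def test_determinism(self, window):
        a = as_population(simulate_adults(window, 2.5e-5, seed=7))
        b = as_population(simulate_adults(window, 2.5e-5, seed=7))
        c = as_population(simulate_adults(window, 2.5e-5, seed=8))
        assert np.array_equal(a.xy, b.xy) and a.ids == b.ids
        assert not np.array_equal(a.xy, c.xy)


class TestAlleleFrequencies:
    def test_shape_and_normalization(self):
        t = simulate_allele_frequencies(17, 8, seed=1)
        assert len(t.loci) == 17
        for locus in t.loci:
            p = t.freq_array(locus)
            assert len(p) == 8 and np.isclose(p.sum(), 1.0) and (p > 0).all()

    def test_large_concentration_approaches_uniform(self):
        t = simulate_allele_frequencies(5, 8, concentration=1e6, seed=2)
        for locus in t.loci:
            assert np.allclose(t.freq_array(locus), 1 / 8, atol=0.01)

    def test_expected_heterozygosity_identity(self):
        t = simulate_allele_frequencies(4, 6, seed=3)
        for locus in t.loci:
            p = t.freq_array(locus)
            assert np.isclose(t.expected_heterozygosity(locus), 1 - (p ** 2).sum())

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_allele_frequencies(0, 8)
        with pytest.raises(ValueError):
            simulate_allele_frequencies(5, 8, concentration=-1)


class TestFounderGenotypes:
    def test_heterozygote_fraction_biallelic(self, window):
        from seeddisp.population import AlleleFrequencyTable
        afreq = AlleleFrequencyTable({"L1": {1: 0.5, 2: 0.5}}, {"L1": 0})
        adults = simulate_adults(window, 2e-4, seed=1)
        pop = draw_founder_genotypes(adults, afreq, seed=2)
        het = (pop.genotypes[:, 0, 0] != pop.genotypes[:, 0, 1]).mean()
        assert abs(het - 0.5) < 3 * 0.5 / np.sqrt(len(pop))

    def test_frequency_round_trip(self, window, afreq17):
        from seeddisp.io import estimate_allele_frequencies
        adults = simulate_adults(window, 5e-4, seed=3)   # ~2000 founders
        pop = draw_founder_genotypes(adults, afreq17, seed=4)
        est = estimate_allele_frequencies(pop)
        for locus in afreq17.loci:
            for a, f in afreq17.freqs[locus].items():
                assert abs(est.freqs[locus].get(a, 0.0) - f) < 0.04

    def test_no_missing_by_default(self, adults):
        assert not adults.missing_mask().any()


class TestOffspringCohort:
    def test_all_immigrants_at_boundary(self, adults, window, afreq17):
        params = DispersalParams(m_s=1.0)
        off, truth = simulate_offspring_cohort(adults, params, 50, window,
                                               afreq17, seed=1)
        assert all(t.mother_id == IMMIGRANT and t.father_id == IMMIGRANT
                   for t in truth)

    def test_pure_selfing_is_mendelian_from_mother(self, adults, window, afreq17):
        params = DispersalParams(s_o=1.0, seed=DispersalKernel(100.0, 1.0))
        off, truth = simulate_offspring_cohort(adults, params, 200, window,
                                               afreq17, seed=2)
        assert all(t.father_id == SELF for t in truth)
        ids = {x: i for i, x in enumerate(adults.ids)}
        for o, t in enumerate(truth):
            mg = adults.genotypes[ids[t.mother_id]]
            for l in range(len(afreq17.loci)):
                # each offspring allele must be one of the mother's two alleles
                assert set(off.genotypes[o, l]) <= set(mg[l])

    def test_selfed_homozygosity_rate(self, adults, window, afreq17):
        """Selfing of a heterozygous mother yields homozygous offspring at
        that locus with probability 1/2 (Mendelian transition)."""
        params = DispersalParams(s_o=1.0, seed=DispersalKernel(100.0, 1.0))
        off, truth = simulate_offspring_cohort(adults, params, 400, window,
                                               afreq17, seed=3)
        ids = {x: i for i, x in enumerate(adults.ids)}
        hom, tot = 0, 0
        for o, t in enumerate(truth):
            mg = adults.genotypes[ids[t.mother_id]]
            for l in range(len(afreq17.loci)):
                if mg[l, 0] != mg[l, 1]:
                    tot += 1
                    hom += off.genotypes[o, l, 0] == off.genotypes[o, l, 1]
        assert abs(hom / tot - 0.5) < 3 * 0.5 / np.sqrt(tot)

    def test_gaussian_kernel_mean_distance(self, adults, window, afreq17,
                                           gaussian_params):
        """2-D normal displacements, sd 300 m/axis: radial mean 300*sqrt(pi/2)."""
        big = StudyWindow.rectangle(20000, 20000)   # negligible truncation
        shifted = Population(adults.ids, adults.xy + 9000, adults.cohort,
                             adults.sex, adults.dbh, adults.loci, adults.genotypes)
        _, truth = simulate_offspring_cohort(shifted, gaussian_params, 10000,
                                             big, afreq17, seed=4)
        d = np.array([t.distance for t in truth])
        expected = 300 * np.sqrt(np.pi / 2)         # ~375.99
        assert abs(d.mean() - expected) < 3 * d.std() / np.sqrt(len(d))

    def test_impossible_mixture_rejected(self):
        with pytest.raises(ValueError):
            DispersalParams(s_o=0.7, m_p=0.4)

    def test_positions_inside_window(self, adults, window, afreq17):
        params = DispersalParams(seed=DispersalKernel(800.0, 1.0))
        off, _ = simulate_offspring_cohort(adults, params, 100, window,
                                           afreq17, seed=5)
        assert window.contains(off.xy[:, 0], off.xy[:, 1]).all()


class TestGenotypingError:
    def test_zero_rate_identity(self, adults, afreq17):
        rates = {l: 0.0 for l in afreq17.loci}
        out = apply_genotyping_error(adults, rates, afreq17, seed=1)
        assert np.array_equal(out.genotypes, adults.genotypes)

    def test_full_rate_resamples_to_reference(self, window, afreq17):
        from seeddisp.io import estimate_allele_frequencies
        pop = draw_founder_genotypes(simulate_adults(window, 5e-4, seed=2),
                                     afreq17, seed=3)
        rates = {l: 1.0 for l in afreq17.loci}
        out = apply_genotyping_error(pop, rates, afreq17, seed=4)
        est = estimate_allele_frequencies(out)
        for locus in afreq17.loci[:5]:
            for a, f in afreq17.freqs[locus].items():
                assert abs(est.freqs[locus].get(a, 0.0) - f) < 0.05

    def test_small_rate_changes_expected_fraction(self, adults, afreq17):
        rates = {l: 0.02 for l in afreq17.loci}
        out = apply_genotyping_error(adults, rates, afreq17, seed=5)
        changed = (out.genotypes != adults.genotypes).mean()
        # a replacement draw can coincide with the original allele
        mean_match = np.mean([np.sum(afreq17.freq_array(l) ** 2)
                              for l in afreq17.loci])
        expected = 0.02 * (1 - mean_match)
        n = adults.genotypes.size
        assert abs(changed - expected) < 4 * np.sqrt(expected / n)

    def test_locus_mismatch_rejected(self, adults, afreq17):
        with pytest.raises(ValueError):
            apply_genotyping_error(adults, {"bogus": 0.1}, afreq17)


class TestSeedFateExperiment:
    def test_design_counts(self):
        d = distance_density_design({"low": 14, "high": 25})
        # per tree: (2 + 25) seeds x 3 distances
        assert len(d) == (14 + 25) * 3 * 27
        assert set(d["distance"]) == {2.0, 20.0, 50.0}
        env = seed_environment_design(replicates=60, caged=True, include_gut=True)
        assert len(env) == 60 * 4 * 5

    def test_null_effects_give_half_success(self):
        d = distance_density_design({"low": 30, "high": 30})
        recs = simulate_seed_fate_experiment(d, {"intercept": 0.0}, seed=1)
        rate = np.mean([r.fate == "germinated" for r in recs])
        assert abs(rate - 0.5) < 3 * 0.5 / np.sqrt(len(recs))

    def test_dung_germination_regime(self):
        """The generator reproduces ~95% germination for dung substrate."""
        d = seed_environment_design(replicates=300, caged=True, include_gut=False)
        logit95 = np.log(0.95 / 0.05)
        recs = simulate_seed_fate_experiment(
            d, {"intercept": logit95}, seed=2)
        dung = [r for r in recs if r.treatment == "dung"]
        rate = np.mean([r.fate == "germinated" for r in dung])
        assert abs(rate - 0.95) < 3 * np.sqrt(0.95 * 0.05 / len(dung))

    def test_unknown_term_rejected(self):
        d = distance_density_design()
        with pytest.raises(ValueError):
            simulate_seed_fate_experiment(d, {"intercept": 0, "moonphase": 1})

    def test_thomas_process_is_clustered(self, afreq17):
        from seeddisp.pointpattern import pcf_inhom
        win = StudyWindow.rectangle(2000, 2000)
        ratios = []
        for s in range(10):
            pts = as_population(simulate_adults(
                win, 2e-4, clustering=ThomasClustering(2e-5, 30.0, 10.0),
                seed=s)).xy
            res = pcf_inhom(pts, win, r_grid=np.linspace(5, 100, 20))
            ratios.append(res.g_at(10.0))
        assert np.mean(ratios) > 1.5
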