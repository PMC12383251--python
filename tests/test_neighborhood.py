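"""Dispersal kernels, transition probabilities, likelihood and parentage."""

import itertools
import warnings

import numpy as np
import pytest
from scipy import integrate, stats

from seeddisp.kernels import DispersalKernel, DispersalParams
from seeddisp.neighborhood import (BACKGROUND, NeighborhoodData,
                                   assign_parentage, estimate_error_rates,
                                   fit_neighborhood_model, immigration_summary,
                                   kernel_density, neighborhood_loglik,
                                   transition_probability)
from seeddisp.population import (MISSING, AlleleFrequencyTable,
                                 MappedIndividual, Population, StudyWindow)
from seeddisp.simulate import (apply_genotyping_error, draw_founder_genotypes,
                               simulate_adults, simulate_offspring_cohort)


class TestKernel:
    def test_b2_is_bivariate_gaussian(self):
        """b = 2 reduces to an isotropic 2-D normal: for mean distance
        sigma*sqrt(pi/2) the density equals N(0, sigma^2 I)."""
        sigma = 200.0
        k = DispersalKernel(delta=sigma * np.sqrt(np.pi / 2), b=2.0)
        for d in (0.0, 100.0, 350.0):
            gauss = np.exp(-d ** 2 / (2 * sigma ** 2)) / (2 * np.pi * sigma ** 2)
            assert np.isclose(k.density(d), gauss, rtol=1e-10)

    def test_b1_mean_distance_is_2a(self):
        """b = 1: mean distance 2a (Gamma(3)/Gamma(2) = 2), checked by
        numerically integrating d * f(d) * 2*pi*d."""
        a = 150.0
        k = DispersalKernel(delta=2 * a, b=1.0)
        assert np.isclose(k.scale, a, rtol=1e-12)
        mean, _ = integrate.quad(lambda d: d * k.density(d) * 2 * np.pi * d,
                                 0, 50 * a)
        assert np.isclose(mean, 2 * a, rtol=1e-6)

    @pytest.mark.parametrize("b", [0.6, 1.0, 2.0, 3.0])
    def test_integrates_to_one_and_mean_is_delta(self, b):
        k = DispersalKernel(delta=300.0, b=b)
        total, _ = integrate.quad(lambda d: k.density(d) * 2 * np.pi * d,
                                  0, np.inf, limit=200)
        mean, _ = integrate.quad(lambda d: d * k.density(d) * 2 * np.pi * d,
                                 0, np.inf, limit=200)
        assert np.isclose(total, 1.0, rtol=1e-6)
        assert np.isclose(mean, 300.0, rtol=1e-3)

    def test_isotropic_when_kappa_zero(self):
        k = DispersalKernel(300.0, 1.0, kappa=0.0)
        assert np.isclose(k.density(100.0, 0.3), k.density(100.0, 2.9))

    def test_anisotropic_prefers_axis(self):
        k = DispersalKernel(300.0, 1.0, kappa=2.0, axis=0.0)
        assert k.density(100.0, 0.0) > k.density(100.0, np.pi)
        total, _ = integrate.quad(
            lambda th: float(k.density(100.0, th)), 0, 2 * np.pi)
        iso = DispersalKernel(300.0, 1.0).density(100.0) * 2 * np.pi
        assert np.isclose(total, iso, rtol=1e-8)

    def test_sampled_mean_matches_delta(self):
        rng = np.random.default_rng(1)
        k = DispersalKernel(250.0, 0.8)
        d = np.linalg.norm(k.sample_displacements(20000, rng), axis=1)
        assert abs(d.mean() - 250.0) < 3 * d.std() / np.sqrt(len(d))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            DispersalKernel(-1.0, 1.0)
        with pytest.raises(ValueError):
            DispersalKernel(100.0, 0.0)
        assert kernel_density(100.0, delta=300.0, b=1.0) > 0


class TestTransitionProbability:
    ALLELES = np.array([1, 2, 3, 4])
    FREQS = np.array([0.4, 0.3, 0.2, 0.1])

    def test_homozygous_parents(self):
        t = transition_probability((1, 1), (1, 1), (1, 1), self.ALLELES,
                                   self.FREQS, e=0.0)
        assert t == 1.0

    def test_obligate_heterozygote(self):
        t_ab = transition_probability((1, 2), (1, 1), (2, 2), self.ALLELES,
                                      self.FREQS, e=0.0)
        t_aa = transition_probability((1, 1), (1, 1), (2, 2), self.ALLELES,
                                      self.FREQS, e=0.0)
        assert t_ab == 1.0 and t_aa == 0.0

    def test_background_father_uses_frequencies(self):
        t = transition_probability((1, 2), (1, 1), BACKGROUND, self.ALLELES,
                                   self.FREQS, e=0.0)
        assert np.isclose(t, 0.3)   # mother passes 1, background passes 2

    @pytest.mark.parametrize("mother,father,e", [
        ((1, 2), (3, 4), 0.0), ((1, 1), BACKGROUND, 0.0),
        ((2, 3), (2, 3), 0.05), ((1, 4), BACKGROUND, 0.3)])
    def test_sums_to_one_over_offspring_genotypes(self, mother, father, e):
        total = sum(transition_probability((a, b), mother, father,
                                           self.ALLELES, self.FREQS, e)
                    for a, b in itertools.combinations_with_replacement(
                        self.ALLELES.tolist(), 2))
        assert np.isclose(total, 1.0)

    def test_missing_offspring_integrates_to_one(self):
        assert transition_probability(None, (1, 2), (3, 4), self.ALLELES,
                                      self.FREQS) == 1.0


def _tiny_dataset(afreq, seed=0):
    win = StudyWindow.rectangle(500, 500)
    mother = MappedIndividual("M", 100, 100, sex="female", dbh=20,
                              genotype={"L1": (1, 2), "L2": (1, 1)})
    father = MappedIndividual("F", 300, 300, sex="male", dbh=25,
                              genotype={"L1": (3, 3), "L2": (2, 2)})
    child = MappedIndividual("C", 120, 110, cohort="small_sapling",
                             genotype={"L1": (1, 3), "L2": (1, 2)})
    return win, mother, father, child


@pytest.fixture(scope="module")
def toy_afreq():
    return AlleleFrequencyTable(
        {"L1": {1: 0.4, 2: 0.3, 3: 0.3}, "L2": {1: 0.5, 2: 0.5}},
        {"L1": 1000, "L2": 1000})


class TestLoglik:
    def test_pure_immigration_boundary(self, toy_afreq):
        """m_s = 1: the log-likelihood is the background genotype probability,
        independent of the kernels."""
        win, mother, father, child = _tiny_dataset(toy_afreq)
        data = NeighborhoodData([child], [mother, father], toy_afreq)
        p1 = DispersalParams(m_s=1.0, seed=DispersalKernel(10.0, 1.0))
        p2 = DispersalParams(m_s=1.0, seed=DispersalKernel(5000.0, 2.0))
        # background: P(1,3 at L1) * P(1,2 at L2) = 2*.4*.3 * 2*.5*.5
        expected = np.log(0.24 * 0.5)
        assert np.isclose(neighborhood_loglik(data, p1), expected)
        assert np.isclose(neighborhood_loglik(data, p2), expected)

    def test_single_parent_pair_hand_computed(self, toy_afreq):
        """One candidate mother and father, e = 0: the likelihood is the
        hand-computed Mendelian mixture over selfing/background/outcross."""
        win, mother, father, child = _tiny_dataset(toy_afreq)
        data = NeighborhoodData([child], [mother, father], toy_afreq)
        s_o, m_p = 0.1, 0.2
        params = DispersalParams(s_o=s_o, m_p=m_p, m_s=0.0,
                                 seed=DispersalKernel(100.0, 1.0),
                                 pollen=DispersalKernel(200.0, 1.0))
        # by hand: w_s over the single mother = 1, single father w_p = 1
        # L1: child (1,3); self: mother (1,2)x(1,2) cannot produce 3 -> 0
        #     bg: P(pass 1)*p3 + P(pass 3)*p1 = .5*.3 + 0 = .15
        #     outcross with (3,3): P(1 from mother)*P(3) = .5
        # L2: child (1,2); self: mother (1,1) -> P(2)=0 -> 0
        #     bg: 1*.5 = .5; outcross with (2,2): 1
        L = s_o * 0 + m_p * (0.15 * 0.5) + (1 - s_o - m_p) * (0.5 * 1.0)
        assert np.isclose(neighborhood_loglik(data, params), np.log(L))

    def test_shuffled_parent_genotypes_lower_likelihood(self, adults, window,
                                                        afreq17):
        params = DispersalParams(s_o=0.05, m_p=0.1, m_s=0.1,
                                 seed=DispersalKernel(300.0, 1.0),
                                 pollen=DispersalKernel(300.0, 1.0))
        worse = 0
        for s in range(5):
            off, _ = simulate_offspring_cohort(adults, params, 60, window,
                                               afreq17, seed=s)
            data = NeighborhoodData(off, adults, afreq17)
            ll_true = neighborhood_loglik(data, params)
            rng = np.random.default_rng(s)
            shuffled = Population(adults.ids, adults.xy, adults.cohort,
                                  adults.sex, adults.dbh, adults.loci,
                                  adults.genotypes[rng.permutation(len(adults))])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ll_shuf = neighborhood_loglik(
                    NeighborhoodData(off, shuffled, afreq17), params)
            worse += ll_shuf < ll_true
        assert worse == 5

    def test_offspring_sharing_candidate_id_excluded(self, toy_afreq):
        win, mother, father, child = _tiny_dataset(toy_afreq)
        clone = MappedIndividual("M", 1, 1, genotype={"L1": (1, 2), "L2": (1, 1)})
        with pytest.warns(UserWarning, match="candidates"):
            data = NeighborhoodData([child, clone], [mother, father], toy_afreq)
        assert data.offspring.ids == ["C"]


class TestFitting:
    def test_boundary_selfing_detected(self, adults, window, afreq17):
        true = DispersalParams(s_o=0.0, m_p=0.0, m_s=0.0,
                               seed=DispersalKernel(300.0, 1.0),
                               pollen=DispersalKernel(300.0, 1.0))
        off, _ = simulate_offspring_cohort(adults, true, 150, window, afreq17,
                                           seed=21)
        data = NeighborhoodData(off, adults, afreq17)
        fit = fit_neighborhood_model(data, free=("s_o", "m_p", "m_s",
                                                 "delta_s", "b_s"),
                                     n_starts=3, seed=1)
        assert fit.params.s_o < 0.02

    def test_gaussian_shape_recovered(self, adults, window, afreq17,
                                      gaussian_params):
        off, _ = simulate_offspring_cohort(adults, gaussian_params, 250,
                                           window, afreq17, seed=31)
        data = NeighborhoodData(off, adults, afreq17)
        fit = fit_neighborhood_model(data, free=("delta_s", "b_s", "delta_p",
                                                 "b_p"), n_starts=3, seed=2)
        assert abs(fit.params.seed.b - 2.0) < 0.4

    def test_seed_immigration_recovered(self, adults, window, afreq17):
        true = DispersalParams(s_o=0.05, m_p=0.1, m_s=0.4,
                               seed=DispersalKernel(400.0, 1.0),
                               pollen=DispersalKernel(300.0, 1.0))
        off, _ = simulate_offspring_cohort(adults, true, 300, window, afreq17,
                                           seed=41)
        fit = fit_neighborhood_model(NeighborhoodData(off, adults, afreq17),
                                     n_starts=4, seed=3)
        assert abs(fit.params.m_s - 0.4) < 0.07

    def test_unknown_free_parameter_rejected(self, adults, window, afreq17):
        off, _ = simulate_offspring_cohort(
            adults, DispersalParams(), 30, window, afreq17, seed=51)
        data = NeighborhoodData(off, adults, afreq17)
        with pytest.raises(ValueError, match="unknown"):
            fit_neighborhood_model(data, free=("delta_s", "banana"))


@pytest.fixture(scope="module")
def fitted(adults, window, afreq17):
    true = DispersalParams(s_o=0.02, m_p=0.1, m_s=0.15,
                           seed=DispersalKernel(300.0, 1.0),
                           pollen=DispersalKernel(300.0, 1.0),
                           e_l={l: 0.02 for l in afreq17.loci})
    off, truth = simulate_offspring_cohort(adults, true, 200, window,
                                           afreq17, seed=61)
    observed = apply_genotyping_error(off, true.e_l, afreq17, seed=62)
    data = NeighborhoodData(observed, adults, afreq17)
    fit = fit_neighborhood_model(data, init=true.with_error_rates(true.e_l),
                                 n_starts=3, seed=4)
    return fit, truth


class TestParentage:
    def test_assignment_accuracy(self, fitted):
        """Mother assignment >= 90% correct with 17 loci and 2% mistyping."""
        fit, truth = fitted
        assigns = assign_parentage(fit).set_index("offspring")
        correct = total = 0
        for t in truth:
            got = assigns.loc[t.offspring_id, "mother"]
            if t.mother_id == "IMMIGRANT":
                correct += got is None
            else:
                correct += got == t.mother_id
            total += 1
        assert correct / total >= 0.90

    def test_categories_respect_distance_rule(self, fitted):
        fit, truth = fitted
        assigns = assign_parentage(fit)
        near = assigns["category"] == "not_dispersed"
        assert (assigns.loc[near, "distance"] < 20).all()
        far = assigns["category"] == "dispersed_within_plot"
        assert (assigns.loc[far, "distance"] >= 20).all()

    def test_all_immigrant_when_ms_one(self, adults, window, afreq17):
        true = DispersalParams(m_s=1.0)
        off, _ = simulate_offspring_cohort(adults, true, 40, window, afreq17,
                                           seed=71)
        data = NeighborhoodData(off, adults, afreq17)
        fit = fit_neighborhood_model(data, free=("m_s",), n_starts=2, seed=5)
        assigns = assign_parentage(fit)
        assert (assigns["category"] == "dispersed_from_outside").mean() > 0.95

    def test_immigration_summary_wilson(self, fitted):
        fit, truth = fitted
        assigns = assign_parentage(fit)
        s = immigration_summary(assigns).set_index("type")
        p = s.loc["seed", "proportion"]
        assert s.loc["seed", "ci_low"] <= p <= s.loc["seed", "ci_high"]
        true_ms = np.mean([t.mother_id == "IMMIGRANT" for t in truth])
        assert abs(p - true_ms) < 0.1


class TestErrorRates:
    def test_recovers_zero_when_clean(self, adults, window, afreq17):
        true = DispersalParams(seed=DispersalKernel(300.0, 1.0),
                               pollen=DispersalKernel(300.0, 1.0))
        off, _ = simulate_offspring_cohort(adults, true, 100, window, afreq17,
                                           seed=81)
        data = NeighborhoodData(off, adults, afreq17)
        e_l = estimate_error_rates(data, true, n_cycles=1)
        assert np.mean(list(e_l.values())) < 0.01
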