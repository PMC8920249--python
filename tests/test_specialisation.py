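import itertools

import numpy as np
import pytest
from scipy import stats

from preysel import (
    DietProfile,
    mc_null_w,
    petraitis_w,
    specialist_summary,
    w_from_counts,
)
from preysel.records_io import ValidationError
from preysel.specialisation import SpecialisationResult


def profile(x, subject="P1", species=None):
    species = species or tuple("s%d" % i for i in range(len(x)))
    return DietProfile(subject=subject, species=species, x=tuple(x))


def oracle_loglr(x, q):
    """Independent multinomial likelihood-ratio via scipy.stats.multinomial.

    log L = log P(x | q) − log P(x | p̂): the combinatorial coefficient
    cancels, leaving the same quantity the implementation computes by a
    different route.
    """
    x = np.asarray(x)
    n = x.sum()
    p_hat = x / n
    # scipy requires strictly valid probability vectors; perturbation-free
    # handling of zero components via the 0^0 = 1 convention:
    lp_q = stats.multinomial.logpmf(x, n, q)
    lp_p = stats.multinomial.logpmf(x, n, p_hat)
    return lp_q - lp_p


class TestPetraitisW:
    def test_identical_diet_gives_w_one(self):
        ind = profile((5, 5))
        pop = profile((50, 50), "population")
        r = petraitis_w(ind, pop)
        assert r.W == pytest.approx(1.0)
        assert r.lam == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_monospecific_diet(self):
        r = petraitis_w(profile((10, 0)), profile((50, 50), "population"))
        assert r.W == pytest.approx(0.5)
        assert r.lam == pytest.approx(20 * np.log(2))
        assert r.df == 1
        assert r.p_value == pytest.approx(stats.chi2.sf(20 * np.log(2), 1), rel=1e-9)
        assert r.p_value == pytest.approx(2.0e-4, abs=5e-5)

    def test_moderate_specialisation(self):
        r = petraitis_w(profile((8, 2)), profile((50, 50), "population"))
        assert r.W == pytest.approx(0.8247, abs=1e-4)
        assert r.lam == pytest.approx(3.855, abs=1e-3)
        assert r.p_value == pytest.approx(0.0496, abs=1e-3)

    def test_exhaustive_oracle_small_cases(self):
        """W and λ match the brute-force multinomial likelihood ratio on
        every diet with n_i ≤ 6 and m ≤ 3 species."""
        for m, q in [(2, np.array([0.3, 0.7])), (3, np.array([0.2, 0.3, 0.5]))]:
            for n in range(1, 7):
                for x in itertools.product(range(n + 1), repeat=m):
                    if sum(x) != n:
                        continue
                    W, lam = w_from_counts(x, q)
                    loglr = oracle_loglr(x, q)
                    assert lam == pytest.approx(-2 * loglr, abs=1e-9)
                    assert W == pytest.approx(np.exp(loglr / n), abs=1e-12)
                    assert 0 < W <= 1 + 1e-12
                    # the defining relation between W and λ
                    assert W == pytest.approx(np.exp(-lam / (2 * n)))

    def test_permutation_equivariance(self):
        x = (7, 2, 1)
        q = np.array([0.5, 0.3, 0.2])
        perm = (2, 0, 1)
        W1, lam1 = w_from_counts(x, q)
        W2, lam2 = w_from_counts([x[i] for i in perm], q[list(perm)])
        assert W1 == pytest.approx(W2)
        assert lam1 == pytest.approx(lam2)

    def test_eating_outside_population_diet_impossible(self):
        with pytest.raises(ValidationError):
            petraitis_w(profile((5, 5)), profile((10, 0), "population"))

    def test_empty_diet_undefined(self):
        with pytest.raises(ValidationError):
            petraitis_w(profile((0, 0)), profile((5, 5), "population"))


class TestMonteCarloNull:
    def test_w_one_has_p_one(self):
        pop = profile((50, 50), "population")
        r = petraitis_w(profile((5, 5)), pop, method="monte_carlo", seed=0)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_exact_binomial_tail(self):
        """For x=(10,0) against q=(½,½) the exact null tail is the
        probability of either monospecific outcome, 2·0.5¹⁰ ≈ 0.00195."""
        pop = profile((500, 500), "population")
        null = mc_null_w(10, pop, replicates=100_000, seed=3)
        W, _ = w_from_counts((10, 0), pop.props)
        p = float(np.mean(null <= W + 1e-12))
        exact = 2 * 0.5**10
        # 4 sigma of the binomial MC error at 1e5 replicates
        assert p == pytest.approx(exact, abs=4 * np.sqrt(exact * (1 - exact) / 1e5))

    def test_agrees_with_chi2_at_large_n(self):
        rng = np.random.default_rng(11)
        pop = profile((250, 250, 250, 250), "population")
        q = pop.props
        for x in rng.multinomial(200, q, size=4):
            W, lam = w_from_counts(x, q)
            p_chi = stats.chi2.sf(lam, 3)
            null = mc_null_w(200, pop, replicates=20_000, seed=int(x[0]))
            p_mc = float(np.mean(null <= W + 1e-12))
            assert abs(p_chi - p_mc) < 0.02

    def test_replicates_validated(self):
        with pytest.raises(ValueError):
            mc_null_w(10, profile((5, 5), "population"), replicates=0)


class TestSpecialistSummary:
    def _result(self, p, w=0.5):
        return SpecialisationResult("P", w, 1.0, 1, p, 10, "chi2")

    def test_no_significant(self):
        s = specialist_summary([self._result(1.0)] * 4)
        assert s["frac_significant"] == 0.0

    def test_counting(self):
        s = specialist_summary([self._result(p) for p in (0.01, 0.2, 0.03, 0.6)])
        assert s["frac_significant"] == pytest.approx(0.5)
        assert s["p_hist"].sum() == 4
        assert s["w_hist"].sum() == 4

    def test_simulated_specialised_population_reproducible(self):
        """Under a fixed seed the pipeline summary of a strongly
        specialised simulated population is bit-reproducible."""
        from preysel import (
            SimulationConfig,
            filter_min_feedings,
            individual_diet,
            pooled_diet,
            simulate_experiment,
        )

        def run():
            cfg = SimulationConfig(concentration=0.5, n_predators=30, seed=9)
            recs, _ = simulate_experiment(cfg)
            inc, _, _ = filter_min_feedings(recs)
            pop = pooled_diet(inc, cfg.spec)
            results = [
                petraitis_w(
                    individual_diet(inc, cfg.spec, pid),
                    pop,
                    method="monte_carlo",
                    mc_replicates=1000,
                    seed=13,
                )
                for pid in sorted({r.predator_id for r in inc})
            ]
            return specialist_summary(results)

        a, b = run(), run()
        assert a["frac_significant"] == b["frac_significant"]
        assert a["mean_w"] == b["mean_w"]
        assert 0 < a["mean_w"] < 1


class TestCalibrationProperties:
    def test_type_one_error_near_nominal(self):
        """Individuals feeding exactly like the population (n_i = 100)
        are rejected by the χ² test at ≈ the nominal 5% level."""
        rng = np.random.default_rng(7)
        q = np.full(4, 0.25)
        X = rng.multinomial(100, q, size=2000)
        pooled = X.sum(axis=0)
        pop = profile(tuple(pooled), "population")
        rej = 0
        for x in X:
            r = petraitis_w(profile(tuple(x)), pop)
            rej += r.p_value < 0.05
        # nominal 0.05 within ~4 sigma binomial error plus asymptotic slack
        assert rej / 2000 == pytest.approx(0.05, abs=0.02)

    def test_mean_w_decreases_with_heterogeneity(self):
        """Mean population W falls as the Dirichlet concentration κ falls
        (stronger individual specialisation), averaged over 20 paired seeds."""
        from preysel import (
            SimulationConfig,
            filter_min_feedings,
            individual_diet,
            pooled_diet,
            simulate_experiment,
        )

        def mean_w(kappa, seed):
            cfg = SimulationConfig(concentration=kappa, n_predators=30, seed=seed)
            recs, _ = simulate_experiment(cfg)
            inc, _, _ = filter_min_feedings(recs)
            pop = pooled_diet(inc, cfg.spec)
            ws = [
                petraitis_w(individual_diet(inc, cfg.spec, pid), pop).W
                for pid in sorted({r.predator_id for r in inc})
            ]
            return np.mean(ws)

        kappas = [0.5, 2.0, 8.0]
        means = {
            k: np.mean([mean_w(k, 100 + s) for s in range(20)]) for k in kappas
        }
        assert means[0.5] < means[2.0] < means[8.0]
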