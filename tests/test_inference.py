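"""Likelihood, optimisation, posterior sampling, credible bands."""

import numpy as np
import pytest

from pqinr import (
    FitProblem,
    PqiCModelParams,
    ReflectivityCurve,
    SamplerConfig,
    Solvent,
    credible_band,
    fit,
    neg_log_likelihood,
    sample_posterior,
)
from pqinr.inference import PosteriorSamples
from pqinr.reflectivity import smeared_reflectivity


def tiny_problem(curves_and_solvents, fit_nuisance=False, **kw):
    return FitProblem(
        base_params=PqiCModelParams(),
        free_names=["apm", "pqic_thickness"],
        bounds={"apm": (45.0, 80.0), "pqic_thickness": (20.0, 90.0)},
        datasets=curves_and_solvents,
        fit_nuisance=fit_nuisance,
        **kw,
    )


@pytest.fixture()
def noiseless_dataset():
    p = PqiCModelParams()
    solvent = Solvent(1.0)
    q = np.geomspace(0.01, 0.25, 40)
    from pqinr.models import build_pqic_stack

    r = smeared_reflectivity(build_pqic_stack(p, solvent), q, 0.035)
    curve = ReflectivityCurve(q, r, dr=0.01 * np.maximum(r, 1e-7),
                              dq_over_q=0.035)
    return [(curve, solvent)]


class TestNegLogLikelihood:
    def test_matches_hand_rolled_loop_on_toy_data(self):
        solvent = Solvent(1.0)
        q = np.array([0.02, 0.05, 0.1])
        r_data = np.array([0.5, 0.01, 1e-4])
        dr = np.array([0.05, 0.001, 1e-5])
        curve = ReflectivityCurve(q, r_data, dr, dq_over_q=0.0)
        prob = tiny_problem([(curve, solvent)])
        theta = prob.start_vector()
        from pqinr.models import build_pqic_stack
        from pqinr.reflectivity import reflectivity

        r_model = reflectivity(build_pqic_stack(prob.base_params, solvent), q)
        expected = 0.0
        for i in range(3):
            expected += 0.5 * ((r_model[i] - r_data[i]) / dr[i]) ** 2
        assert neg_log_likelihood(prob, theta) == pytest.approx(expected)

    def test_doubling_dr_quarters_data_term(self, noiseless_dataset):
        curve, solvent = noiseless_dataset[0]
        shifted = ReflectivityCurve(curve.q, curve.r * 1.05, curve.dr,
                                    dq_over_q=curve.dq_over_q)
        wide = ReflectivityCurve(curve.q, curve.r * 1.05, 2 * curve.dr,
                                 dq_over_q=curve.dq_over_q)
        p1 = tiny_problem([(shifted, solvent)])
        p2 = tiny_problem([(wide, solvent)])
        th = p1.start_vector()
        assert neg_log_likelihood(p2, th) == pytest.approx(
            neg_log_likelihood(p1, th) / 4.0)

    def test_minimum_at_truth_among_perturbations(self, noiseless_dataset):
        prob = tiny_problem(noiseless_dataset)
        th0 = prob.start_vector()
        nll0 = neg_log_likelihood(prob, th0)
        rng = np.random.default_rng(7)
        lo, hi = prob.bounds_array().T
        for _ in range(100):
            th = th0 + rng.uniform(-1, 1, th0.shape) * 0.1 * (hi - lo)
            th = np.clip(th, lo, hi)
            if np.allclose(th, th0):
                continue
            assert neg_log_likelihood(prob, th) >= nll0

    def test_out_of_bounds_is_infinite(self, noiseless_dataset):
        prob = tiny_problem(noiseless_dataset)
        th = prob.start_vector()
        th[0] = 200.0
        assert neg_log_likelihood(prob, th) == np.inf

    def test_invariant_under_dataset_ordering(self, noiseless_dataset):
        curve, _ = noiseless_dataset[0]
        s2 = Solvent(0.0)
        from pqinr.models import build_pqic_stack

        r2 = smeared_reflectivity(build_pqic_stack(PqiCModelParams(), s2),
                                  curve.q, 0.035)
        c2 = ReflectivityCurve(curve.q, r2 * 1.02,
                               0.01 * np.maximum(r2, 1e-7), dq_over_q=0.035)
        d1 = [noiseless_dataset[0], (c2, s2)]
        d2 = [(c2, s2), noiseless_dataset[0]]
        th = tiny_problem(d1).start_vector()
        assert neg_log_likelihood(tiny_problem(d1), th) == pytest.approx(
            neg_log_likelihood(tiny_problem(d2), th))

    def test_normal_prior_adds_quadratic_term(self, noiseless_dataset):
        p_flat = tiny_problem(noiseless_dataset)
        p_prior = tiny_problem(noiseless_dataset,
                               priors={"apm": (58.0, 2.0)})
        th = p_flat.start_vector()  # apm = 60
        diff = (neg_log_likelihood(p_prior, th)
                - neg_log_likelihood(p_flat, th))
        assert diff == pytest.approx(0.5 * ((60.0 - 58.0) / 2.0) ** 2)


class TestFit:
    def test_refit_from_optimum_is_fixed_point(self, noiseless_dataset):
        prob = tiny_problem(noiseless_dataset)
        res1 = fit(prob)
        res2 = fit(prob, start=res1.theta)
        assert res2.nll <= res1.nll + 1e-9
        np.testing.assert_allclose(res2.theta, res1.theta, atol=1e-3)

    def test_bare_substrate_drives_coverage_to_zero(self):
        # fitting a bilayer model to bare-substrate data must switch the
        # bilayer off
        from pqinr import builtin_scenarios, simulate_experiment

        sc = builtin_scenarios()["bare_substrate"]
        data = simulate_experiment(sc)
        prob = FitProblem(
            base_params=PqiCModelParams(bilayer_coverage=0.6,
                                        pqic_volume_fraction=0.0),
            free_names=["bilayer_coverage"],
            bounds={"bilayer_coverage": (0.0, 1.0)},
            datasets=data, fit_nuisance=False)
        res = fit(prob)
        assert res.as_dict()["bilayer_coverage"] < 0.05


class TestJointVsIndependentFits:
    def test_joint_contrast_fit_beats_single_contrast_recovery(self):
        # sharing geometry across the four solvent contrasts must reduce
        # the recovery error of the protein slab thickness relative to
        # fitting one contrast alone (fixed seeds, several replicates)
        from dataclasses import replace as dc_replace

        from pqinr import builtin_scenarios, simulate_experiment

        base = builtin_scenarios()["bilayer_pqic"]
        free = ["pqic_thickness"]
        bounds = {"pqic_thickness": (20.0, 90.0)}
        start = dc_replace(base.truth, pqic_thickness=44.0)
        sse_joint, sse_single = 0.0, 0.0
        for rep in range(6):
            sc = dc_replace(base, seed=500 + rep, n_points=50)
            data = simulate_experiment(sc)
            for datasets, acc in ((data, "joint"), (data[:1], "single")):
                prob = FitProblem(base_params=start, free_names=free,
                                  bounds=bounds, datasets=datasets,
                                  fit_nuisance=False)
                err = (fit(prob).as_dict()["pqic_thickness"]
                       - base.truth.pqic_thickness) ** 2
                if acc == "joint":
                    sse_joint += err
                else:
                    sse_single += err
        assert sse_joint < sse_single


class TestSampler:
    def test_identical_seed_identical_draws(self, noiseless_dataset):
        prob = tiny_problem(noiseless_dataset)
        cfg = SamplerConfig(walkers=8, steps=40, burn_in=10, seed=3)
        s1 = sample_posterior(prob, cfg)
        s2 = sample_posterior(prob, cfg)
        np.testing.assert_array_equal(s1.draws, s2.draws)

    def test_draws_respect_bounds(self, noiseless_dataset):
        prob = tiny_problem(noiseless_dataset)
        cfg = SamplerConfig(walkers=8, steps=60, burn_in=20, seed=5)
        s = sample_posterior(prob, cfg)
        lo, hi = prob.bounds_array().T
        assert np.all(s.draws >= lo) and np.all(s.draws <= hi)

    def test_flat_likelihood_recovers_uniform_prior(self):
        # zero-weight data: dr -> huge, so the posterior is the uniform
        # prior within bounds
        q = np.geomspace(0.01, 0.2, 10)
        curve = ReflectivityCurve(q, np.full(10, 0.5), np.full(10, 1e9))
        prob = tiny_problem([(curve, Solvent(1.0))])
        cfg = SamplerConfig(walkers=16, steps=1500, burn_in=500, seed=11,
                            init_ball=0.3)
        s = sample_posterior(prob, cfg)
        lo, hi = prob.bounds_array().T
        for j, (a, b) in enumerate(zip(lo, hi)):
            mean = s.draws[:, j].mean()
            std = s.draws[:, j].std()
            width = b - a
            assert mean == pytest.approx((a + b) / 2, abs=0.1 * width)
            assert std == pytest.approx(width / np.sqrt(12), rel=0.25)

    def test_too_few_walkers_rejected(self, noiseless_dataset):
        prob = tiny_problem(noiseless_dataset)
        with pytest.raises(ValueError):
            sample_posterior(prob, SamplerConfig(walkers=2, steps=10,
                                                 burn_in=2, seed=0))


class TestCredibleBand:
    def _normal_samples(self):
        rng = np.random.default_rng(0)
        draws = rng.normal([10.0, -2.0], [1.0, 0.5], size=(40000, 2))
        return PosteriorSamples(draws=draws, log_probs=np.zeros(40000),
                                names=["a", "b"], metadata={})

    def test_constant_functional_zero_width(self):
        s = self._normal_samples()
        lo, hi = credible_band(s, lambda th: 7.5)
        assert lo == hi == 7.5

    def test_normal_draws_bracket_0935_sigma(self):
        # central 65% mass of a normal lies within +/- 0.935 sigma
        s = self._normal_samples()
        lo, hi = credible_band(s, "a", level=0.65)
        assert lo == pytest.approx(10.0 - 0.9346, abs=0.03)
        assert hi == pytest.approx(10.0 + 0.9346, abs=0.03)

    def test_band_contains_best_fit_curve(self, noiseless_dataset):
        prob = tiny_problem(noiseless_dataset)
        res = fit(prob)
        cfg = SamplerConfig(walkers=8, steps=120, burn_in=40, seed=9)
        s = sample_posterior(prob, cfg, start=res.theta)
        curve, _ = noiseless_dataset[0]
        functional = lambda th: prob.model_curves(th)[0]
        lo, hi = credible_band(s, functional, level=0.99)
        best = prob.model_curves(res.theta)[0]
        frac_inside = np.mean((best >= lo - 1e-12) & (best <= hi + 1e-12))
        assert frac_inside > 0.95

    def test_invalid_level_rejected(self):
        s = self._normal_samples()
        with pytest.raises(ValueError):
            credible_band(s, "a", level=1.5)
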