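"""Mixture densities, priors, EM/MAP steps, K selection, post-fit filter."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

from nucpos import Config
from nucpos.model import (EStep, FitError, ParamSet, PriorSpec, _e_step_arrays,
                          _solve_centers, components_from_params, e_step,
                          fit_region, gmrf_logprior, k_search_range,
                          m_step_centers, m_step_rest, mixture_density,
                          postfit_filter, select_K, t4_density)
from nucpos.preprocess import make_candidate_regions
from nucpos.simulate import sample_reads, sample_truth
from nucpos.types import CandidateRegion, MixtureFit, NucleosomeComponent


def random_params(K, rng, spread=200.0):
    mu = np.sort(rng.uniform(0, spread * K, K))
    mu += np.arange(K)  # guarantee strictly increasing
    w = rng.dirichlet(np.ones(K))
    return ParamSet(w=w, mu=mu,
                    delta=rng.uniform(150, 250, K),
                    var_f=rng.uniform(100, 1600, K),
                    var_r=rng.uniform(100, 1600, K))


class TestT4Density:
    def test_peak_value_is_three_eighths(self):
        assert t4_density(0.0, 0.0, 1.0) == pytest.approx(0.375, abs=1e-12)

    def test_symmetry_and_scale(self):
        for a in (13.7, 1.0, 250.0):
            assert t4_density(50 + a, 50, 7.0) == pytest.approx(
                t4_density(50 - a, 50, 7.0))
        # matches scipy's location-scale t(4)
        xs = np.linspace(-300, 300, 31)
        np.testing.assert_allclose(t4_density(xs, 10.0, 25.0),
                                   t_dist.pdf(xs, df=4, loc=10.0, scale=25.0),
                                   rtol=1e-12)

    def test_integrates_to_one(self):
        total, _ = quad(lambda x: t4_density(x, 0.0, 3.0), -1500, 1500)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            t4_density(0.0, 0.0, 0.0)


class TestMixtureDensity:
    @staticmethod
    def _fit(params):
        return MixtureFit(K=params.K, components=components_from_params(params),
                          loglik=0.0, logpost_pen=0.0, n_iter=0, converged=True)

    def test_single_component_fwd_peaks_at_mu_minus_half_delta(self):
        params = ParamSet(np.array([1.0]), np.array([500.0]),
                          np.array([200.0]), np.array([400.0]), np.array([400.0]))
        fit = self._fit(params)
        xs = np.arange(200, 800)
        dens = mixture_density(xs, "fwd", fit)
        assert xs[np.argmax(dens)] == 400  # mu - delta/2

    def test_mirror_components_give_symmetric_density(self):
        params = ParamSet(np.array([0.5, 0.5]), np.array([400.0, 600.0]),
                          np.array([200.0, 200.0]),
                          np.array([625.0, 625.0]), np.array([625.0, 625.0]))
        fit = self._fit(params)
        for off in (0.0, 30.0, 111.5):
            assert mixture_density(500 - off, "fwd", fit) == pytest.approx(
                mixture_density(500 + off, "rev", fit))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_summation(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(3, rng)
        fit = self._fit(params)
        xs = rng.uniform(-100, 800, 20)
        for strand, sign, var in (("fwd", -1, params.var_f),
                                  ("rev", +1, params.var_r)):
            expected = np.zeros_like(xs)
            for k in range(3):
                expected += params.w[k] * t_dist.pdf(
                    xs, df=4, loc=params.mu[k] + sign * params.delta[k] / 2,
                    scale=np.sqrt(var[k]))
            np.testing.assert_allclose(mixture_density(xs, strand, fit),
                                       expected, rtol=1e-10)


class TestGmrfLogprior:
    def test_single_center_is_zero(self):
        assert gmrf_logprior([123.0], PriorSpec()) == 0.0

    def test_exact_spacing_attains_maximum_zero(self):
        spec = PriorSpec()
        mus = np.arange(5) * spec.delta0
        assert gmrf_logprior(mus, spec) == 0.0
        assert gmrf_logprior(mus + np.array([0, 1, 0, 0, 0]), spec) < 0.0

    def test_hand_evaluated_quadratic(self):
        spec = PriorSpec(delta0=200.0, rho_s=0.0008)
        mus = [0.0, 220.0, 400.0]  # spacings delta0 + 20, delta0 - 20
        assert gmrf_logprior(mus, spec) == pytest.approx(-0.0008 * 800)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            gmrf_logprior([300.0, 100.0], PriorSpec())


class TestEStep:
    def test_equidistant_read_splits_evenly(self):
        # fwd strand centres sit at mu - delta/2 = 300 and 500; a forward
        # read at 400 is equidistant (reverse: centres 500 and 700, read 600)
        params = ParamSet(np.array([0.5, 0.5]), np.array([400.0, 600.0]),
                          np.array([200.0, 200.0]),
                          np.array([400.0, 400.0]), np.array([400.0, 400.0]))
        region = CandidateRegion("c", 0, 1000, [400], [600])
        est = _e_step_arrays(region, params)
        np.testing.assert_allclose(est.z_f[0], [0.5, 0.5])
        np.testing.assert_allclose(est.z_r[0], [0.5, 0.5])

    def test_latent_weight_at_strand_center(self):
        params = ParamSet(np.array([1.0]), np.array([500.0]),
                          np.array([200.0]), np.array([400.0]), np.array([400.0]))
        region = CandidateRegion("c", 0, 1000, [400], [600])  # exactly at centers
        est = _e_step_arrays(region, params)
        assert est.u_f[0, 0] == pytest.approx(1.25)  # (nu+1)/nu
        assert est.u_r[0, 0] == pytest.approx(1.25)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_responsibilities_match_direct_normalization(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(3, rng)
        f = rng.uniform(0, 800, 15).astype(int)
        r = rng.uniform(0, 800, 15).astype(int)
        region = CandidateRegion("c", -1, 801, f, r)
        est = _e_step_arrays(region, params)
        for i, x in enumerate(np.sort(f)):
            dens = np.array([
                params.w[k] * t_dist.pdf(x, df=4,
                                         loc=params.mu[k] - params.delta[k] / 2,
                                         scale=np.sqrt(params.var_f[k]))
                for k in range(3)])
            np.testing.assert_allclose(est.z_f[i], dens / dens.sum(), rtol=1e-9)


def _dense_center_solution(region, est, params, spec):
    """Oracle: build the full quadratic system and solve densely."""
    K = params.K
    f, r = region.fwd.astype(float), region.rev.astype(float)
    Wf, Wr = est.z_f * est.u_f, est.z_r * est.u_r
    M = np.zeros((K, K))
    c = np.zeros(K)
    for k in range(K):
        A = Wf[:, k].sum() / params.var_f[k] + Wr[:, k].sum() / params.var_r[k]
        b = (Wf[:, k] @ (f + params.delta[k] / 2)) / params.var_f[k] \
            + (Wr[:, k] @ (r - params.delta[k] / 2)) / params.var_r[k]
        M[k, k] += A
        c[k] += b
    for k in range(1, K):
        M[k, k] += 2 * spec.rho_s
        M[k - 1, k - 1] += 2 * spec.rho_s
        M[k, k - 1] -= 2 * spec.rho_s
        M[k - 1, k] -= 2 * spec.rho_s
        c[k] += 2 * spec.rho_s * spec.delta0
        c[k - 1] -= 2 * spec.rho_s * spec.delta0
    return np.linalg.solve(M, c)


def _random_center_system(K, rng):
    n_f = n_r = 30
    f = np.sort(rng.integers(0, 200 * K, n_f))
    r = np.sort(rng.integers(0, 200 * K, n_r))
    region = CandidateRegion("c", -1, 200 * K + 1, f, r)
    params = random_params(K, rng, spread=180.0)
    est = _e_step_arrays(region, params)
    return region, est, params


class TestMStepCenters:
    def test_k1_reduces_to_weighted_average(self):
        rng = np.random.default_rng(0)
        region, est, params = _random_center_system(1, rng)
        spec = PriorSpec()
        mu = m_step_centers(region, est, params, spec)
        Wf = est.z_f * est.u_f
        Wr = est.z_r * est.u_r
        num = (Wf[:, 0] @ (region.fwd + params.delta[0] / 2)) / params.var_f[0] \
            + (Wr[:, 0] @ (region.rev - params.delta[0] / 2)) / params.var_r[0]
        den = Wf[:, 0].sum() / params.var_f[0] + Wr[:, 0].sum() / params.var_r[0]
        assert mu[0] == pytest.approx(num / den, rel=1e-12)

    def test_vanishing_coupling_matches_uncoupled_solution(self):
        rng = np.random.default_rng(1)
        region, est, params = _random_center_system(3, rng)
        spec = PriorSpec(rho_s=1e-12)
        mu = _solve_centers(region, est, params, spec)
        Wf = est.z_f * est.u_f
        Wr = est.z_r * est.u_r
        for k in range(3):
            num = (Wf[:, k] @ (region.fwd + params.delta[k] / 2)) / params.var_f[k] \
                + (Wr[:, k] @ (region.rev - params.delta[k] / 2)) / params.var_r[k]
            den = Wf[:, k].sum() / params.var_f[k] + Wr[:, k].sum() / params.var_r[k]
            assert mu[k] == pytest.approx(num / den, abs=1e-5)

    def test_tridiagonal_matches_dense_solver(self):
        rng = np.random.default_rng(2)
        spec = PriorSpec()
        for _ in range(25):
            K = int(rng.integers(1, 7))
            region, est, params = _random_center_system(K, rng)
            got = _solve_centers(region, est, params, spec)
            expected = _dense_center_solution(region, est, params, spec)
            np.testing.assert_allclose(got, expected, atol=1e-8)


class TestMStepRest:
    @staticmethod
    def _system(rng, K=2):
        region, est, params = _random_center_system(K, rng)
        return region, est, params

    def test_kappa_zero_gives_pure_data_offset(self):
        rng = np.random.default_rng(5)
        region, est, params = self._system(rng, K=1)
        spec = PriorSpec(kappa=0.0)
        out = m_step_rest(region, est, params, spec)
        Wf, Wr = est.z_f * est.u_f, est.z_r * est.u_r
        mean_f = (Wf[:, 0] @ region.fwd) / Wf[:, 0].sum()
        mean_r = (Wr[:, 0] @ region.rev) / Wr[:, 0].sum()
        # delta solves the two-strand least squares: weighted blend of
        # 2*(mu - mean_f) and 2*(mean_r - mu)
        pf = Wf[:, 0].sum() / (4 * params.var_f[0])
        pr = Wr[:, 0].sum() / (4 * params.var_r[0])
        expected = (pf * 2 * (params.mu[0] - mean_f)
                    + pr * 2 * (mean_r - params.mu[0])) / (pf + pr)
        assert out.delta[0] == pytest.approx(expected, rel=1e-10)

    def test_kappa_infinity_pins_delta_to_prior_mean(self):
        rng = np.random.default_rng(6)
        region, est, params = self._system(rng)
        spec = PriorSpec(kappa=1e12, xi=200.0)
        out = m_step_rest(region, est, params, spec)
        np.testing.assert_allclose(out.delta, 200.0, atol=1e-4)

    def test_variance_matches_grid_search_of_map_objective(self):
        rng = np.random.default_rng(7)
        region, est, params = self._system(rng, K=2)
        spec = PriorSpec()
        out = m_step_rest(region, est, params, spec)
        Wf = est.z_f * est.u_f
        for k in range(2):
            cf = params.mu[k] - out.delta[k] / 2
            sse = Wf[:, k] @ (region.fwd - cf) ** 2
            n_eff = est.z_f[:, k].sum()

            def neg_q(lam, sse=sse, n_eff=n_eff):
                return -(n_eff / 2 * np.log(lam) - lam * sse / 2
                         + (spec.alpha - 1) * np.log(lam) - spec.beta * lam)

            res = minimize_scalar(neg_q, bounds=(1e-8, 1.0), method="bounded",
                                  options={"xatol": 1e-12})
            assert out.var_f[k] == pytest.approx(1.0 / res.x, rel=1e-4)

    def test_weights_are_normalized_responsibility_masses(self):
        rng = np.random.default_rng(8)
        region, est, params = self._system(rng)
        out = m_step_rest(region, est, params, PriorSpec())
        expected = est.z_f.sum(0) + est.z_r.sum(0)
        np.testing.assert_allclose(out.w, expected / expected.sum(), rtol=1e-10)


class TestFitRegion:
    def test_single_nucleosome_center_recovered(self, sonicated_cfg):
        # t(4) tails make any single draw heavy-tailed; the median error
        # over seeds is the stable summary
        errors = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            truth = sample_truth(1, 1000.0, replace(sonicated_cfg,
                                                    reads_per_nucleosome=200),
                                 rng)
            reads = sample_reads(truth, rng)
            region = make_candidate_regions(reads, sonicated_cfg)[0]
            fit = fit_region(region, 1, sonicated_cfg)
            assert fit.converged
            errors.append(abs(fit.components[0].mu - truth.centers[0]))
        assert np.median(errors) < 5.0

    def test_objective_monotone_nondecreasing(self, three_nuc_region,
                                              sonicated_cfg):
        region, _ = three_nuc_region
        for K in (1, 2, 3, 4):
            fit = fit_region(region, K, sonicated_cfg)
            tr = fit.objective_trace
            assert np.all(np.diff(tr) >= -1e-8 * (np.abs(tr[:-1]) + 1.0))

    def test_read_order_irrelevant(self, three_nuc_region, sonicated_cfg):
        region, _ = three_nuc_region
        rng = np.random.default_rng(0)
        shuffled = CandidateRegion(region.chrom, region.start, region.end,
                                   rng.permutation(region.fwd),
                                   rng.permutation(region.rev))
        a = fit_region(region, 3, sonicated_cfg)
        b = fit_region(shuffled, 3, sonicated_cfg)
        np.testing.assert_allclose(a.mus, b.mus)

    def test_translation_equivariance(self, three_nuc_region, sonicated_cfg):
        region, _ = three_nuc_region
        shift = 50_000
        a = fit_region(region, 3, sonicated_cfg)
        b = fit_region(region.shift(shift), 3, sonicated_cfg)
        np.testing.assert_allclose(b.mus - shift, a.mus, atol=1e-5)
        for ca, cb in zip(a.components, b.components):
            assert cb.delta == pytest.approx(ca.delta, abs=1e-5)
            assert cb.var_f == pytest.approx(ca.var_f, rel=1e-6)

    def test_empty_strand_rejected(self, sonicated_cfg):
        region = CandidateRegion("c", 0, 100, [10, 20], [])
        with pytest.raises(FitError):
            fit_region(region, 1, sonicated_cfg)


class TestKSearchRange:
    @pytest.mark.parametrize("length, delta0, expected", [
        (200, 200.0, range(1, 4)),    # E=1, lower clamp
        (1000, 200.0, range(3, 8)),   # E=5
    ])
    def test_expected_count_bracketing(self, sonicated_cfg, length, delta0,
                                       expected):
        cfg = replace(sonicated_cfg, delta0=delta0)
        fwd = np.linspace(0, length - 1, 20).astype(int)
        region = CandidateRegion("c", 0, length, fwd, fwd)
        assert k_search_range(region, cfg) == expected

    def test_capped_by_reads_per_strand(self, sonicated_cfg):
        region = CandidateRegion("c", 0, 1000, [10, 900], [20, 800])
        assert max(k_search_range(region, sonicated_cfg)) == 2


class TestSelectK:
    @staticmethod
    def _fit(K, loglik, mus=None):
        mus = np.arange(K) * 200.0 if mus is None else np.asarray(mus)
        comps = [NucleosomeComponent(1.0 / K, m, 200.0, 400.0, 400.0)
                 for m in mus]
        return MixtureFit(K=K, components=comps, loglik=loglik,
                          logpost_pen=loglik, n_iter=1, converged=True)

    def test_single_candidate_returned(self):
        fit = self._fit(2, -10.0)
        assert select_K([fit], PriorSpec()) is fit

    def test_tie_prefers_smaller_k(self):
        # equal spacing at delta0 makes the prior zero for both candidates
        a, b = self._fit(2, -5.0), self._fit(3, -5.0)
        assert select_K([b, a], PriorSpec()).K == 2

    def test_recovers_k_on_well_separated_simulations(self, sonicated_cfg):
        from nucpos.model import fit_region_auto
        correct = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            truth = sample_truth(3, 1000.0, sonicated_cfg, rng)
            reads = sample_reads(truth, rng)
            total_k = 0
            for region in make_candidate_regions(reads, sonicated_cfg):
                fit = fit_region_auto(region, sonicated_cfg)
                if fit is not None:
                    total_k += fit.K
            if total_k == 3:
                correct += 1
        assert correct >= 0.9 * n_rep


class TestPostfitFilter:
    @staticmethod
    def _fit(comps):
        return MixtureFit(K=len(comps), components=comps, loglik=-1.0,
                          logpost_pen=-1.0, n_iter=1, converged=True)

    def test_in_bounds_components_unchanged(self, sonicated_cfg):
        comps = [NucleosomeComponent(0.5, 100.0, 200.0, 400.0, 400.0),
                 NucleosomeComponent(0.5, 300.0, 200.0, 400.0, 400.0)]
        out = postfit_filter(self._fit(comps), sonicated_cfg)
        assert out.K == 2
        np.testing.assert_allclose(out.mus, [100.0, 300.0])

    def test_negligible_weight_dropped_and_renormalized(self, sonicated_cfg):
        comps = [NucleosomeComponent(0.799, 100.0, 200.0, 400.0, 400.0),
                 NucleosomeComponent(0.001, 300.0, 200.0, 400.0, 400.0),
                 NucleosomeComponent(0.2, 500.0, 200.0, 400.0, 400.0)]
        out = postfit_filter(self._fit(comps), sonicated_cfg)
        assert out.K == 2
        assert sum(c.w for c in out.components) == pytest.approx(1.0)

    def test_close_pair_merged_keeping_heavier_shape(self, sonicated_cfg):
        comps = [NucleosomeComponent(0.3, 100.0, 180.0, 400.0, 400.0),
                 NucleosomeComponent(0.7, 110.0, 220.0, 900.0, 900.0)]
        out = postfit_filter(self._fit(comps), sonicated_cfg)
        assert out.K == 1
        c = out.components[0]
        assert c.mu == 110.0 and c.delta == 220.0
        assert c.w == pytest.approx(1.0)

    def test_out_of_bounds_delta_dropped(self, sonicated_cfg):
        comps = [NucleosomeComponent(0.5, 100.0, 300.0, 400.0, 400.0),
                 NucleosomeComponent(0.5, 400.0, 200.0, 400.0, 400.0)]
        out = postfit_filter(self._fit(comps), sonicated_cfg)
        assert out.K == 1
        assert out.components[0].mu == 400.0
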