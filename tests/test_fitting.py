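"""Boltzmann-machine learning: update rules, gradients, recovery, sweeps."""

import numpy as np
import pytest
from scipy.special import logsumexp

import repeatscape as rs
from repeatscape.entropy import enumerate_states
from repeatscape.fitting import _coupling_update

from conftest import random_small_model


class TestCouplingUpdateRule:
    """The four-case L1-proximal step, checked entry by entry."""

    def test_zero_coupling_stays_zero_inside_tube(self):
        J = np.zeros((2, 2))
        grad = np.array([[0.0005, -0.0008], [0.0, 0.0009]])
        out = _coupling_update(J, grad, eps_j=0.05, gamma=0.001)
        assert np.all(out == 0.0)

    def test_zero_coupling_released_softthresholded(self):
        J = np.zeros((1, 1))
        grad = np.array([[0.01]])
        out = _coupling_update(J, grad, eps_j=0.05, gamma=0.001)
        assert out[0, 0] == pytest.approx(0.05 * (0.01 - 0.001))

    def test_active_coupling_moves_along_gradient(self):
        J = np.array([[0.3]])
        grad = np.array([[0.02]])
        out = _coupling_update(J, grad, eps_j=0.05, gamma=0.001)
        assert out[0, 0] == pytest.approx(0.3 + 0.05 * (0.02 - 0.001))

    def test_sign_crossing_clamps_to_zero(self):
        J = np.array([[1e-4]])
        grad = np.array([[-0.5]])
        out = _coupling_update(J, grad, eps_j=0.05, gamma=0.001)
        assert out[0, 0] == 0.0


def exact_model_observables(model):
    """Exact f1, f2, P(ID) of a small model by enumeration (oracle)."""
    states = enumerate_states(model.n_sites, model.q)
    E = model.energies(states)
    p = np.exp(-E - logsumexp(-E))
    aln = rs.Alignment(states, [str(i) for i in range(len(states))],
                       model.L, q=model.q, weights=p)
    return rs.compute_observables(aln)


class TestGradientDirection:
    def test_field_update_is_likelihood_gradient(self):
        """eps_m * (f_data - f_model) equals the exact per-sequence
        log-likelihood gradient wrt h_i(s), checked by finite differences."""
        rng = np.random.default_rng(11)
        m = random_small_model(rng, L=2, q=3, density=0.5)
        data = rs.make_planted_alignment(m, 400, seed=1)
        obs = rs.compute_observables(data)
        states = enumerate_states(4, 3)

        def avg_loglik(model):
            E = model.energies(states)
            logZ = logsumexp(-E)
            data_E = model.energies(data.sequences)
            return float((-data_E - logZ).mean())

        eps = 1e-6
        mobs = exact_model_observables(m)
        for (i, s) in [(0, 0), (1, 2), (3, 1)]:
            m2 = rs.PottsModel(m.h.copy(), m.J.copy(), m.lam.copy(), m.mask)
            m2.h[i, s] += eps
            num_grad = (avg_loglik(m2) - avg_loglik(m)) / eps
            assert num_grad == pytest.approx(obs.f1[i, s] - mobs.f1[i, s], abs=1e-5)

    def test_lambda_update_sign(self):
        """lambda enters E with +, so dlogL/dlambda_k = -(P_data - P_model)."""
        rng = np.random.default_rng(12)
        m = random_small_model(rng, L=2, q=3, density=0.5)
        data = rs.make_planted_alignment(m, 400, seed=2)
        obs = rs.compute_observables(data)
        states = enumerate_states(4, 3)

        def avg_loglik(model):
            E = model.energies(states)
            return float((-model.energies(data.sequences) - logsumexp(-E)).mean())

        mobs = exact_model_observables(m)
        eps = 1e-6
        for k in range(3):
            m2 = rs.PottsModel(m.h.copy(), m.J.copy(), m.lam.copy(), m.mask)
            m2.lam[k] += eps
            num_grad = (avg_loglik(m2) - avg_loglik(m)) / eps
            assert num_grad == pytest.approx(-(obs.p_id[k] - mobs.p_id[k]), abs=1e-5)


class TestFitModel:
    def test_near_fixed_point_converges_immediately(self):
        """Starting from the generating model, errors are pure MC noise and the
        criterion is met without parameter drift."""
        rng = np.random.default_rng(13)
        m = random_small_model(rng, L=2, q=3, density=0.4, coupling_scale=0.5)
        aln = rs.make_planted_alignment(m, 40000, seed=3)
        obs = rs.compute_observables(aln)
        cfg = rs.FitConfig(n_samples=40000, thinning=40, max_iters=8, seed=4, eps_id=1.0)
        fitted, rep = rs.fit_model(obs, m, cfg, fit_J=True, fit_lambda=True)
        assert rep.converged
        assert rep.iterations <= 8

    def test_planted_lambda_recovery(self):
        """Fitting only the overlap multipliers on overlap-biased data matches
        the data P(ID) within the criterion's share (0.02 / 5)."""
        L, q = 4, 3
        lam = -0.8 * np.arange(L + 1, dtype=float)
        spec = rs.PlantedSpec(L=L, q=q, coupling_density=0.0, lambda_profile=lam,
                              seed=18)
        m = rs.make_planted_model(spec)
        aln = rs.make_planted_alignment(m, 30000, seed=19)
        obs = rs.compute_observables(aln)
        init = rs.independent_model(obs, pseudocount=1e-6)
        cfg = rs.FitConfig(n_samples=30000, thinning=40, max_iters=150, seed=20,
                           eps_id=1.0)
        fitted, rep = rs.fit_model(obs, init, cfg, fit_J=False, fit_lambda=True)
        assert rep.converged
        ens = rs.metropolis_sample(fitted, 30000, thinning=40, seed=21)
        p_model = rs.ensemble_observables(ens).p_id
        assert np.abs(p_model - obs.p_id).max() < 0.02 / 5 + 0.003  # + MC noise

    def test_nonconvergence_reported_not_raised(self, planted_small):
        aln = rs.make_planted_alignment(planted_small, 500, seed=5)
        obs = rs.compute_observables(aln)
        init = rs.PottsModel.zero(4, 3, rs.make_mask_full(8))
        cfg = rs.FitConfig(n_samples=200, thinning=10, max_iters=2, seed=6)
        _, rep = rs.fit_model(obs, init, cfg)
        assert not rep.converged and rep.iterations == 2

    def test_mismatched_shapes_rejected(self, planted_small):
        aln = rs.make_planted_alignment(planted_small, 50, seed=7)
        obs = rs.compute_observables(aln)
        init = rs.PottsModel.zero(3, 3)
        with pytest.raises(ValueError):
            rs.fit_model(obs, init, rs.FitConfig())


@pytest.fixture(scope="module")
def suite(planted_small):
    aln = rs.make_planted_alignment(planted_small, 8000, seed=8)
    obs = rs.compute_observables(aln)
    cfg = rs.FitConfig(n_samples=8000, thinning=60, max_iters=120, seed=9,
                       eps_id=1.0)
    models, reports = rs.fit_variant_suite(obs, cfg)
    return obs, models, reports


class TestVariantSuite:
    def test_rand_and_independent_are_closed_form(self, suite):
        obs, models, reports = suite
        assert reports["E_rand"] is None and reports["E_1"] is None
        assert np.all(models["E_rand"].h == 0.0)
        f = (obs.f1 + 1e-6) / (1 + obs.q * 1e-6)
        np.testing.assert_allclose(models["E_1"].h, np.log(f))

    def test_tied_variant_is_repeat_swap_invariant(self, suite):
        _, models, _ = suite
        m = models["E_ir"]
        rng = np.random.default_rng(14)
        for _ in range(20):
            s = rng.integers(0, 3, 8).astype(np.int8)
            swapped = np.concatenate([s[4:], s[:4]])
            assert m.energy(s) == pytest.approx(m.energy(swapped), abs=1e-9)

    def test_tied_variant_has_no_interrepeat_couplings(self, suite):
        _, models, _ = suite
        for v in ("E_ir", "E_ir_lambda"):
            assert not models[v].mask.allowed[:4, 4:].any()

    def test_e2_has_zero_lambda(self, suite):
        _, models, _ = suite
        assert np.all(models["E_2"].lam == 0.0)
        assert np.any(models["E_full"].J != 0.0)

    def test_entropy_ordering_with_constraints(self, suite):
        """More constraints can only reduce entropy: S_1 >= S_full (combined error)."""
        _, models, _ = suite
        s1 = rs.entropy_exact_enumeration(models["E_1"])
        sfull = rs.entropy_thermodynamic(models["E_full"], n=4000,
                                         alpha_grid=np.linspace(0, 1, 21),
                                         thinning=60, seed=10)
        assert s1 >= sfull.S_nats - 3 * sfull.mc_error_nats


class TestRangeSweep:
    def test_single_zero_range_is_independent_model(self, planted_small):
        aln = rs.make_planted_alignment(planted_small, 4000, seed=11)
        obs = rs.compute_observables(aln)
        cfg = rs.FitConfig(n_samples=4000, thinning=40, max_iters=60, seed=12,
                           eps_id=1.0)
        models, reports = rs.fit_range_sweep(obs, cfg, [0], fit_lambda=False)
        assert models[0].mask.n_pairs == 0
        assert np.all(models[0].J == 0.0)

    def test_sweep_masks_nest_and_seeds_carry(self, planted_small):
        aln = rs.make_planted_alignment(planted_small, 4000, seed=13)
        obs = rs.compute_observables(aln)
        cfg = rs.FitConfig(n_samples=3000, thinning=40, max_iters=15, seed=14,
                           eps_id=1.0)
        models, _ = rs.fit_range_sweep(obs, cfg, [1, 4, 7], fit_lambda=False)
        assert models[0].mask.n_pairs < models[1].mask.n_pairs < models[2].mask.n_pairs
        # final linear range >= 2L-1 covers every pair: same constraint set as E_full
        assert models[2].mask.n_pairs == 8 * 7 // 2

    def test_sweep_is_reproducible(self, planted_small):
        aln = rs.make_planted_alignment(planted_small, 2000, seed=15)
        obs = rs.compute_observables(aln)
        cfg = rs.FitConfig(n_samples=1000, thinning=20, max_iters=5, seed=16,
                           eps_id=1.0)
        m1, r1 = rs.fit_range_sweep(obs, cfg, [1, 3], fit_lambda=True)
        m2, r2 = rs.fit_range_sweep(obs, cfg, [1, 3], fit_lambda=True)
        for a, b in zip(m1, m2):
            assert a.content_hash() == b.content_hash()
        assert [r.error_trace for r in r1] == [r.error_trace for r in r2]

    def test_unsorted_ranges_rejected(self, planted_small):
        aln = rs.make_planted_alignment(planted_small, 200, seed=17)
        obs = rs.compute_observables(aln)
        with pytest.raises(ValueError):
            rs.fit_range_sweep(obs, rs.FitConfig(), [3, 1])
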