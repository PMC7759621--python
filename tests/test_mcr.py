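"""MCR-ALS: SIMPLISMA selection, constrained ALS, variance diagnostics."""

import dataclasses

import numpy as np
import pytest
import scipy.optimize

from tachem import mcr, synthetic
from tachem.errors import ConfigurationError, InitializationError
from tachem.scenarios import UvVisScenario

from conftest import make_spectral_matrix


def _congruence(a, b):
    return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))


class TestSimplisma:
    def test_pure_rows_selected_from_mixture(self):
        s1 = np.exp(-0.5 * ((np.arange(40) - 10) / 4.0) ** 2)
        s2 = np.exp(-0.5 * ((np.arange(40) - 28) / 4.0) ** 2)
        X = np.vstack([s1, 0.5 * s1 + 0.5 * s2, s2])
        sm = make_spectral_matrix(X, wavelengths=400.0 + 2 * np.arange(40))
        init = mcr.simplisma_init(sm, 2)
        chosen = {tuple(init[:, k]) for k in range(2)}
        assert chosen == {tuple(s1), tuple(s2)}

    def test_identity_matrix_selects_all_rows(self):
        X = np.eye(3) + 0.01
        init = mcr.simplisma_init(X, 3)
        # every selected column is (a scaled copy of) a distinct unit row
        assert np.linalg.matrix_rank(init) == 3

    def test_constant_matrix_raises(self):
        with pytest.raises(InitializationError):
            mcr.simplisma_init(np.ones((4, 10)), 2)

    def test_default_scenario_init_correlates_with_truth(self, uvvis_default):
        init = mcr.simplisma_init(uvvis_default, 2)
        S_true = uvvis_default.truth["S"]
        best = np.zeros(2)
        for k in range(2):
            for j in range(2):
                best[j] = max(best[j], _congruence(init[:, k], S_true[:, j]))
        assert np.all(best > 0.95)


class TestFitMCR:
    def test_noiseless_bilinear_recovery(self, uvvis_noiseless):
        res = mcr.fit_mcr(
            uvvis_noiseless,
            mcr.MCRConfig(2, constraints={"nonneg_c", "nonneg_s"}),
        )
        assert res.r2 >= 0.9999
        S_true = uvvis_noiseless.truth["S"]
        # max-congruence assignment over the permutation ambiguity
        c = np.array(
            [[_congruence(res.S[:, k], S_true[:, j]) for j in range(2)] for k in range(2)]
        )
        assert max(c[0, 0] * c[1, 1], c[0, 1] * c[1, 0]) >= 0.99**2

    def test_closure_run_recovers_band_maxima_and_extinctions(self, scenarios):
        lam1, lam2, eps = [], [], []
        for seed in range(20):
            sc = dataclasses.replace(scenarios["fe_ta_uvvis"], seed=1000 + seed)
            sm = synthetic.generate_uvvis_titration(sc)
            res = mcr.fit_mcr(
                sm,
                mcr.MCRConfig(
                    2,
                    constraints={"nonneg_c", "nonneg_s", "closure"},
                    closure_total=2.00e-5,
                ),
            )
            lam1.append(res.lambda_max[0])
            lam2.append(res.lambda_max[1])
            eps.append(res.eps_max)
        eps = np.array(eps)
        assert abs(np.median(lam1) - 580.0) <= 2.0
        assert abs(np.median(lam2) - 513.0) <= 2.0
        # ground-truth extinction maxima of the packaged scenario
        assert np.median(eps[:, 0]) == pytest.approx(3487.0, rel=0.05)
        assert np.median(eps[:, 1]) == pytest.approx(7576.0, rel=0.05)

    def test_rank1_solution_matches_multistart_oracle(self):
        rng = np.random.default_rng(11)
        X = np.abs(rng.normal(size=(4, 3))) + 0.1
        sm = make_spectral_matrix(X, wavelengths=np.array([500.0, 550.0, 600.0]))
        res = mcr.fit_mcr(sm, mcr.MCRConfig(1, constraints={"nonneg_c", "nonneg_s"}))
        rss = np.sum(res.residuals**2)
        # independent oracle: alternating scipy nnls from 100 random starts
        best = np.inf
        for start in range(100):
            r = np.random.default_rng(start)
            s = np.abs(r.normal(size=3)) + 0.01
            for _ in range(60):
                c = np.array([scipy.optimize.nnls(s[:, None], X[i])[0][0] for i in range(4)])
                s = np.array([scipy.optimize.nnls(c[:, None], X[:, j])[0][0] for j in range(3)])
            best = min(best, np.sum((X - np.outer(c, s)) ** 2))
        assert rss == pytest.approx(best, rel=1e-6, abs=1e-12)

    def test_rss_non_increasing_without_closure(self, uvvis_default):
        res = mcr.fit_mcr(
            uvvis_default, mcr.MCRConfig(2, constraints={"nonneg_c", "nonneg_s"})
        )
        h = np.array(res.rss_history)
        assert np.all(np.diff(h) <= 1e-10 * h[:-1])

    def test_closure_rows_sum_to_total(self, uvvis_default):
        total = 2.00e-5
        res = mcr.fit_mcr(
            uvvis_default,
            mcr.MCRConfig(
                2, constraints={"nonneg_c", "nonneg_s", "closure"}, closure_total=total
            ),
        )
        sums = res.C.sum(axis=1)
        assert np.all(np.abs(sums - total) / total <= 1e-8)

    def test_closure_jump_unflagged_on_consistent_data(self, uvvis_noiseless):
        # rows rescaled to sum exactly to the total: closure is then a
        # no-op at the optimum and must not be flagged
        sm = uvvis_noiseless
        C = sm.truth["C"]
        C = C / C.sum(axis=1, keepdims=True) * 2.00e-5
        consistent = make_spectral_matrix(
            C @ sm.truth["S"].T, wavelengths=sm.wavelengths
        )
        res = mcr.fit_mcr(
            consistent,
            mcr.MCRConfig(
                2, constraints={"nonneg_c", "nonneg_s", "closure"}, closure_total=2e-5
            ),
        )
        assert not res.closure_violation
        assert res.r2 >= 1 - 1e-8

    def test_closure_jump_flagged_on_noisy_data(self, uvvis_default):
        # with measurement noise the free least-squares row sums deviate
        # from the total, so the projection must raise RSS noticeably --
        # the fit reports it instead of failing
        res = mcr.fit_mcr(
            uvvis_default,
            mcr.MCRConfig(
                2, constraints={"nonneg_c", "nonneg_s", "closure"}, closure_total=2e-5
            ),
        )
        assert res.closure_violation

    def test_components_ordered_by_descending_band_maximum(self, uvvis_default):
        res = mcr.fit_mcr(
            uvvis_default, mcr.MCRConfig(2, constraints={"nonneg_c", "nonneg_s"})
        )
        assert res.lambda_max[0] > res.lambda_max[1]

    def test_too_many_components_rejected(self, uvvis_default):
        with pytest.raises(ConfigurationError):
            mcr.fit_mcr(uvvis_default, mcr.MCRConfig(300))

    def test_unknown_constraint_rejected(self):
        with pytest.raises(ConfigurationError) as err:
            mcr.MCRConfig(2, constraints={"sparsity"})
        assert "nonneg_c" in str(err.value)  # message lists the valid set

    def test_nonconvergence_flagged_not_raised(self, uvvis_default):
        res = mcr.fit_mcr(
            uvvis_default,
            mcr.MCRConfig(2, max_iter=2, constraints={"nonneg_c", "nonneg_s"}),
        )
        assert res.converged is False


class TestExplainedVariance:
    def test_perfect_reconstruction_gives_r2_one(self):
        C = np.array([[1.0], [2.0], [3.0]])
        S = np.array([[2.0], [1.0], [4.0], [0.5]])
        sm = make_spectral_matrix(C @ S.T, wavelengths=np.arange(4.0))
        res = mcr.fit_mcr(sm, mcr.MCRConfig(1, constraints={"nonneg_c", "nonneg_s"}))
        per, cum, r2 = mcr.explained_variance(res, sm)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert cum == pytest.approx(100.0, rel=1e-6)

    def test_zero_factors_give_r2_zero(self, uvvis_default):
        res = mcr.fit_mcr(
            uvvis_default, mcr.MCRConfig(2, constraints={"nonneg_c", "nonneg_s"})
        )
        res.C = np.zeros_like(res.C)
        res.S = np.zeros_like(res.S)
        _, cum, r2 = mcr.explained_variance(res, uvvis_default)
        assert r2 == 0.0 and cum == 0.0

    def test_zero_matrix_raises(self):
        rng = np.random.default_rng(0)
        sm = make_spectral_matrix(rng.uniform(0.1, 1.0, (3, 5)))
        res = mcr.fit_mcr(sm, mcr.MCRConfig(1, constraints={"nonneg_c", "nonneg_s"}))
        sm.absorbance = np.zeros_like(sm.absorbance)
        with pytest.raises(ConfigurationError):
            mcr.explained_variance(res, sm)

    def test_r2_matches_noise_floor_expectation(self, scenarios):
        # E[SS(E)] ~ sigma^2 * N for a rank-2 fit of rank-2 data + noise
        r2s, expect = [], []
        for seed in range(20):
            sc = dataclasses.replace(scenarios["fe_ta_uvvis"], seed=4000 + seed)
            sm = synthetic.generate_uvvis_titration(sc)
            res = mcr.fit_mcr(
                sm, mcr.MCRConfig(2, constraints={"nonneg_c", "nonneg_s"})
            )
            r2s.append(res.r2)
            ss_x = np.sum(sm.absorbance**2)
            expect.append(1.0 - sc.noise_sd**2 * sm.absorbance.size / ss_x)
        assert np.mean(r2s) == pytest.approx(np.mean(expect), abs=0.002)


class TestScaleHandling:
    def test_calibrate_epsilon_preserves_reconstruction(self, uvvis_default):
        res = mcr.fit_mcr(
            uvvis_default, mcr.MCRConfig(2, constraints={"nonneg_c", "nonneg_s"})
        )
        cal = mcr.calibrate_epsilon(res, [3487.0, 7576.0])
        assert np.allclose(cal.C @ cal.S.T, res.C @ res.S.T, rtol=1e-12)
        assert cal.eps_max == pytest.approx([3487.0, 7576.0])

    def test_projection_recovers_known_concentrations(self, scenarios):
        sc = dataclasses.replace(scenarios["fe_ta_uvvis"], noise_sd=0.0)
        sm = synthetic.generate_uvvis_titration(sc)
        res = mcr.fit_mcr(
            sm,
            mcr.MCRConfig(
                2, constraints={"nonneg_c", "nonneg_s", "closure"}, closure_total=2e-5
            ),
        )
        proj = mcr.project_concentrations(sm, res)
        assert np.allclose(proj.C, sm.truth["C"], rtol=0.05, atol=1.0e-6)


def test_peak_refinement_beats_argmax_under_noise():
    rng = np.random.default_rng(3)
    wl = 400.0 + 2.0 * np.arange(251)
    band = 3487.0 * np.exp(-4 * np.log(2) * (wl - 580.0) ** 2 / 150.0**2)
    errs_raw, errs_ref = [], []
    for _ in range(50):
        noisy = band + rng.normal(0, 50.0, size=wl.shape)
        errs_raw.append(abs(wl[np.argmax(noisy)] - 580.0))
        lam, _ = mcr.refine_peak(wl, noisy)
        errs_ref.append(abs(lam - 580.0))
    assert np.mean(errs_ref) < 0.5 * np.mean(errs_raw)
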