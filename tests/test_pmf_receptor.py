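"""PMF receptor model: uncertainties, factorization quality, recovery, diagnostics."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from metalrisk.core_tables import Metal, METALS, SampleMatrix, ValidationError
from metalrisk.pmf_receptor import (
    FactorSolution,
    build_uncertainty,
    diagnostics,
    factor_contributions,
    fit_pmf,
)
from metalrisk.synthetic_data import FactorTruth, simulate_factor_data


def matched_cosines(f_true: np.ndarray, f_hat: np.ndarray) -> np.ndarray:
    """Cosine similarity per factor after optimal (Hungarian) matching."""
    ft = f_true / np.linalg.norm(f_true, axis=1, keepdims=True)
    fh = f_hat / np.linalg.norm(f_hat, axis=1, keepdims=True)
    sim = ft @ fh.T
    rows, cols = linear_sum_assignment(-sim)
    return sim[rows, cols], cols


def make_matrix(values, mdl_value=0.01):
    values = np.asarray(values, float)
    metals = METALS[: values.shape[1]]
    return SampleMatrix(
        values=values,
        species=[f"s{i}" for i in range(values.shape[0])],
        metals=metals,
        mdl={m: mdl_value for m in metals},
        raw=values.copy(),
    )


class TestUncertainty:
    def test_below_mdl_branch(self):
        sm = make_matrix([[0.05]], mdl_value=0.1)
        alpha = build_uncertainty(sm)
        assert alpha.alpha[0, 0] == pytest.approx(5.0 / 6.0 * 0.1)

    def test_above_mdl_branch(self):
        sm = make_matrix([[1.0]], mdl_value=0.1)
        alpha = build_uncertainty(sm)
        assert alpha.alpha[0, 0] == pytest.approx(0.05 * 1.0 + 0.1)

    def test_value_exactly_at_mdl_uses_detection_branch(self):
        sm = make_matrix([[0.1]], mdl_value=0.1)
        alpha = build_uncertainty(sm)
        assert alpha.alpha[0, 0] == pytest.approx(5.0 / 6.0 * 0.1)

    def test_branch_condition_uses_presubstitution_value(self):
        values = np.array([[0.05]])
        sm = make_matrix(values, mdl_value=0.1)
        sm.values = np.array([[0.05]])  # working value
        sm.raw = np.array([[0.2]])  # raw above MDL -> additive branch on values
        alpha = build_uncertainty(sm)
        assert alpha.alpha[0, 0] == pytest.approx(0.05 * 0.05 + 0.1)

    def test_nonpositive_mdl_rejected(self):
        sm = make_matrix([[1.0]], mdl_value=0.01)
        sm.mdl = {Metal.AS: 0.0}
        with pytest.raises(ValidationError):
            build_uncertainty(sm)


class TestFit:
    def test_noise_free_data_factorizes_exactly(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(0.5, 2, (60, 3))
        f = rng.uniform(0.1, 5, (3, 6))
        sm = make_matrix(g @ f)
        alpha = build_uncertainty(sm)
        sol = fit_pmf(sm, alpha, n_factors=3, n_runs=5, seed=1)
        assert sol.q_true < 1e-6 * sm.values.size
        diag = diagnostics(sm, alpha, sol)
        assert all(r2 > 0.9999 for r2 in diag["r2_per_metal"].values())

    def test_three_factor_recovery_from_noisy_data(self, factor_truth_3):
        sm = simulate_factor_data(factor_truth_3, seed=11)
        alpha = build_uncertainty(sm)
        sol = fit_pmf(sm, alpha, n_factors=3, n_runs=20, seed=1)
        cosines, _ = matched_cosines(np.asarray(factor_truth_3.f_true), sol.f)
        assert np.all(cosines >= 0.95)
        assert sol.n_converged >= 1

    def test_rank_one_data_recovers_the_profile(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(0.5, 2, (40, 1))
        f = np.array([[1.0, 2.0, 0.5, 3.0, 0.2, 1.5]])
        truth = FactorTruth(g_true=g, f_true=f, noise_cv=0.02, mdl={m: 0.01 for m in METALS})
        sm = simulate_factor_data(truth, seed=4)
        alpha = build_uncertainty(sm)
        sol = fit_pmf(sm, alpha, n_factors=1, n_runs=5, seed=2)
        cosines, _ = matched_cosines(f, sol.f)
        assert cosines[0] >= 0.999
        rel = np.abs(sol.predicted - sm.values) / sm.values
        assert np.quantile(rel, 0.95) < 0.1  # reproduces X within the noise level

    def test_q_robust_never_exceeds_q_true(self, factor_truth_3):
        sm = simulate_factor_data(factor_truth_3, seed=11)
        alpha = build_uncertainty(sm)
        sol = fit_pmf(sm, alpha, n_factors=2, n_runs=5, seed=0)
        assert sol.q_robust <= sol.q_true + 1e-9

    def test_q_monotone_nonincreasing(self, factor_truth_3):
        sm = simulate_factor_data(factor_truth_3, seed=11)
        alpha = build_uncertainty(sm)
        sol = fit_pmf(sm, alpha, n_factors=3, n_runs=1, seed=5, robust=False)
        hist = sol.q_history
        rises = np.diff(hist) / np.maximum(hist[:-1], 1e-12)
        assert rises.max() <= 1e-9

    def test_more_factors_never_fit_worse(self, factor_truth_3):
        sm = simulate_factor_data(factor_truth_3, seed=11)
        alpha = build_uncertainty(sm)
        qs = [
            fit_pmf(sm, alpha, n_factors=k, n_runs=8, seed=1).q_true for k in (2, 3, 4)
        ]
        assert qs[1] <= qs[0] * 1.01
        assert qs[2] <= qs[1] * 1.01

    def test_q_invariant_under_per_factor_rescaling(self, factor_truth_3):
        from metalrisk.pmf_receptor import _q_values

        sm = simulate_factor_data(factor_truth_3, seed=11)
        alpha = build_uncertainty(sm)
        sol = fit_pmf(sm, alpha, n_factors=3, n_runs=3, seed=2)
        c = np.array([2.0, 0.5, 7.0])
        g2, f2 = sol.g * c[None, :], sol.f / c[:, None]
        q_scaled, _ = _q_values(sm.values, g2 @ f2, np.asarray(alpha.alpha))
        assert q_scaled == pytest.approx(sol.q_true, rel=1e-9)

    def test_structure_destroyed_data_fits_worse(self, factor_truth_3):
        sm = simulate_factor_data(factor_truth_3, seed=11)
        alpha = build_uncertainty(sm)
        structured = fit_pmf(sm, alpha, n_factors=3, n_runs=5, seed=1)
        rng = np.random.default_rng(9)
        shuffled = sm.values.copy()
        for j in range(shuffled.shape[1]):
            rng.shuffle(shuffled[:, j])
        sm2 = make_matrix(shuffled)
        sol2 = fit_pmf(sm2, build_uncertainty(sm2), n_factors=3, n_runs=5, seed=1)
        r2_structured = np.mean(list(diagnostics(sm, alpha, structured)["r2_per_metal"].values()))
        r2_shuffled = np.mean(
            list(diagnostics(sm2, build_uncertainty(sm2), sol2)["r2_per_metal"].values())
        )
        assert r2_shuffled < r2_structured - 0.2

    def test_invalid_factor_count_rejected(self, factor_truth_3):
        sm = simulate_factor_data(factor_truth_3, seed=11)
        alpha = build_uncertainty(sm)
        with pytest.raises(ValidationError):
            fit_pmf(sm, alpha, n_factors=0)
        with pytest.raises(ValidationError):
            fit_pmf(sm, alpha, n_factors=7)


class TestContributions:
    def test_single_factor_gets_everything(self):
        sol = FactorSolution(
            g=np.ones((10, 1)), f=np.ones((1, 3)), q_true=0, q_robust=0,
            n_factors=1, metals=METALS[:3], seed_of_best=0, n_converged=1,
        )
        pct = factor_contributions(sol)
        assert np.allclose(pct.to_numpy(), 100.0)

    def test_identical_factors_split_evenly(self):
        sol = FactorSolution(
            g=np.ones((10, 2)), f=np.ones((2, 3)), q_true=0, q_robust=0,
            n_factors=2, metals=METALS[:3], seed_of_best=0, n_converged=1,
        )
        assert np.allclose(factor_contributions(sol).to_numpy(), 50.0)

    def test_columns_sum_to_100(self, factor_truth_3):
        sm = simulate_factor_data(factor_truth_3, seed=11)
        sol = fit_pmf(sm, build_uncertainty(sm), n_factors=3, n_runs=5, seed=1)
        pct = factor_contributions(sol)
        assert np.allclose(pct.sum(axis=0).to_numpy(), 100.0, atol=0.01)

    def test_known_80pct_attribution_recovered(self):
        """A metal generated 80% by one source keeps that share in the fit."""
        rng = np.random.default_rng(12)
        # squared uniforms: many samples dominated by one source, which anchors
        # the factorization; equal column mass makes the true share 80% exactly
        g = rng.uniform(0.0, 1.0, size=(100, 3)) ** 2
        g = g / g.sum(axis=0, keepdims=True)
        f = np.array([
            [0.1, 3.0, 3.0, 0.2, 0.2, 0.2],
            [0.8, 0.2, 0.2, 3.0, 0.2, 0.2],  # first metal: 80% from factor 2
            [0.1, 0.2, 0.2, 0.2, 3.0, 3.0],
        ])
        truth = FactorTruth(g_true=g, f_true=f, noise_cv=0.05, mdl={m: 1e-4 for m in METALS})
        sm = simulate_factor_data(truth, seed=21)
        sol = fit_pmf(sm, build_uncertainty(sm), n_factors=3, n_runs=20, seed=3)
        _, mapping = matched_cosines(f, sol.f)
        pct = factor_contributions(sol).to_numpy()
        recovered = pct[mapping[1], 0]
        assert recovered == pytest.approx(80.0, abs=5.0)

    def test_zero_metal_column_rejected(self):
        f = np.array([[1.0, 0.0], [2.0, 0.0]])
        sol = FactorSolution(
            g=np.ones((5, 2)), f=f, q_true=0, q_robust=0,
            n_factors=2, metals=METALS[:2], seed_of_best=0, n_converged=1,
        )
        with pytest.raises(ValidationError, match="Mn"):
            factor_contributions(sol)


class TestDiagnostics:
    def test_noise_free_fit_has_unit_r2_and_zero_residuals(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(0.5, 2, (50, 2))
        f = rng.uniform(0.1, 5, (2, 5))
        sm = make_matrix(g @ f)
        alpha = build_uncertainty(sm)
        sol = fit_pmf(sm, alpha, n_factors=2, n_runs=5, seed=0)
        diag = diagnostics(sm, alpha, sol)
        assert all(r2 == pytest.approx(1.0, abs=1e-6) for r2 in diag["r2_per_metal"].values())
        assert np.abs(diag["scaled_residuals"]).max() < 1e-3

    def test_noisy_fit_residuals_mostly_within_3(self, factor_truth_3):
        sm = simulate_factor_data(factor_truth_3, seed=11)
        alpha = build_uncertainty(sm)
        sol = fit_pmf(sm, alpha, n_factors=3, n_runs=10, seed=1)
        diag = diagnostics(sm, alpha, sol)
        assert diag["fraction_within_3"] >= 0.95
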