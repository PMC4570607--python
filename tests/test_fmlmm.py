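"""Mixture of linear mixed models: design algebra, E/M-step oracles, the
replicate-independence reduction and BIC bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from splicemix import fmlmm, fmm, synthetic
from splicemix.params import LMMMixtureParams


@pytest.fixture
def two_component_params():
    return LMMMixtureParams(
        pi=[0.6, 0.4],
        alpha=[[0.85, 0.12], [0.68, 0.30]],
        phi=np.stack([[[2e-4, -1e-4], [-1e-4, 2e-4]],
                      [[3e-4, -2e-4], [-2e-4, 3e-4]]]),
        sigma2=[[1e-4, 2e-4], [2e-4, 1e-4]])


def test_build_design_block_structure():
    assert np.array_equal(fmlmm.build_design(1), np.eye(2))
    V3 = fmlmm.build_design(3)
    assert V3.shape == (6, 2)
    assert np.array_equal(V3[:3], np.tile([1.0, 0.0], (3, 1)))
    assert np.array_equal(V3[3:], np.tile([0.0, 1.0], (3, 1)))
    for R in range(1, 6):
        V = fmlmm.build_design(R)
        assert np.array_equal(V.T @ V, R * np.eye(2))


def test_marginal_moments_special_cases():
    p = LMMMixtureParams(pi=[1.0], alpha=[[0.5, 0.3]],
                         phi=np.zeros((1, 2, 2)), sigma2=[[0.7, 0.2]])
    _, sigma = fmlmm.marginal_moments(p, 0, 3)
    assert np.allclose(sigma, np.diag([0.7] * 3 + [0.2] * 3))

    v = 0.05
    p = LMMMixtureParams(pi=[1.0], alpha=[[0.0, 0.0]],
                         phi=(v * np.eye(2))[None], sigma2=[[0.0, 0.0]])
    _, sigma = fmlmm.marginal_moments(p, 0, 2)
    assert sigma[0, 1] == pytest.approx(v)   # within-variant replicate cov
    assert sigma[0, 2] == pytest.approx(0.0)  # cross-variant cov


def test_marginal_moments_match_hand_computation(fmlmm_reference_params):
    g, R = 1, 3
    V = fmlmm.build_design(R)
    expected = V @ fmlmm_reference_params.phi[g] @ V.T \
        + np.diag(V @ fmlmm_reference_params.sigma2[g])
    mu, sigma = fmlmm.marginal_moments(fmlmm_reference_params, g, R)
    assert np.abs(sigma - expected).max() < 1e-12
    assert np.allclose(mu, V @ fmlmm_reference_params.alpha[g])


def test_e_step_trivial_cases(two_component_params):
    x = np.array([0.8, 0.82, 0.81, 0.14, 0.15, 0.13])
    one = LMMMixtureParams(pi=[1.0], alpha=two_component_params.alpha[:1],
                           phi=two_component_params.phi[:1],
                           sigma2=two_component_params.sigma2[:1])
    assert fmlmm.fmlmm_e_step([x], one)[0] == pytest.approx([1.0])

    twin = LMMMixtureParams(
        pi=[0.3, 0.7],
        alpha=np.tile(two_component_params.alpha[:1], (2, 1)),
        phi=np.tile(two_component_params.phi[:1], (2, 1, 1)),
        sigma2=np.tile(two_component_params.sigma2[:1], (2, 1)))
    w = fmlmm.fmlmm_e_step([x], twin)
    assert w[0] == pytest.approx([0.3, 0.7], abs=1e-12)


def test_e_step_matches_direct_mvn_oracle(two_component_params):
    rng = np.random.default_rng(0)
    vectors = [rng.normal(0.5, 0.1, size=6) for _ in range(4)]
    w = fmlmm.fmlmm_e_step(vectors, two_component_params)
    for i, x in enumerate(vectors):
        dens = np.array([
            pi * stats.multivariate_normal.pdf(
                x, *fmlmm.marginal_moments(two_component_params, g, 3))
            for g, pi in enumerate(two_component_params.pi)])
        assert w[i] == pytest.approx(dens / dens.sum(), abs=1e-10)
    assert np.abs(w.sum(axis=1) - 1.0).max() < 1e-12


def test_blup_zero_cases(two_component_params):
    x = fmlmm.build_design(3) @ two_component_params.alpha[0]
    assert fmlmm.blup(x, two_component_params, 0) == pytest.approx([0.0, 0.0],
                                                                   abs=1e-12)
    frozen = LMMMixtureParams(pi=[1.0], alpha=[[0.5, 0.3]],
                              phi=np.zeros((1, 2, 2)), sigma2=[[1e-3, 1e-3]])
    x = np.array([0.6, 0.4, 0.55, 0.2, 0.35, 0.3])
    assert fmlmm.blup(x, frozen, 0) == pytest.approx([0.0, 0.0], abs=1e-12)


def test_blup_small_error_limit_is_replicate_mean_projection():
    """As sigma2 -> 0 with a single component (w = 1), V @ blup approaches
    the least-squares projection of the residual onto the replicate-mean
    space."""
    p = LMMMixtureParams(pi=[1.0], alpha=[[0.5, 0.3]],
                         phi=np.array([[[4e-2, 0.0], [0.0, 4e-2]]]),
                         sigma2=[[1e-10, 1e-10]])
    x = np.array([0.62, 0.58, 0.63, 0.25, 0.33, 0.29])
    V = fmlmm.build_design(3)
    resid = x - V @ p.alpha[0]
    projection = V @ np.linalg.solve(V.T @ V, V.T @ resid)
    assert V @ fmlmm.blup(x, p, 0) == pytest.approx(projection, abs=1e-6)


def test_m_step_degenerate_sigma_update():
    """One component, Phi = 0: the error-variance update is the per-variant
    mean squared residual around the fixed effect."""
    rng = np.random.default_rng(1)
    alpha = np.array([0.8, 0.2])
    vectors = [np.concatenate([alpha[0] + rng.normal(0, 0.05, 3),
                               alpha[1] + rng.normal(0, 0.02, 3)])
               for _ in range(200)]
    p = LMMMixtureParams(pi=[1.0], alpha=[alpha], phi=np.zeros((1, 2, 2)),
                         sigma2=[[1e-3, 1e-3]])
    w = np.ones((200, 1))
    updated = fmlmm.fmlmm_m_step(vectors, w, p)
    X = np.stack(vectors)
    mse1 = ((X[:, :3] - alpha[0]) ** 2).mean()
    mse2 = ((X[:, 3:] - alpha[1]) ** 2).mean()
    assert updated.sigma2[0] == pytest.approx([mse1, mse2], rel=1e-8)


def test_m_step_uniform_weights_give_uniform_pi(two_component_params):
    rng = np.random.default_rng(2)
    vectors = [rng.normal(0.5, 0.1, size=6) for _ in range(10)]
    w = np.full((10, 2), 0.5)
    updated = fmlmm.fmlmm_m_step(vectors, w, two_component_params)
    assert updated.pi == pytest.approx([0.5, 0.5])


@pytest.fixture(scope="module")
def large_reference_vectors(fmlmm_reference_params):
    """A panel large enough that Monte Carlo noise on the second moments of
    the rarest component (pi ~ 0.1) drops below the 2% fixed-point band."""
    panel, _ = synthetic.generate_fmlmm_panel(fmlmm_reference_params, 20000, 3,
                                              seed=3, missing_rate=0.0)
    return panel.tissue_vectors()[1]


@pytest.mark.parametrize("alpha_update", ["printed", "gls"])
def test_m_step_fixed_point_near_mle(fmlmm_reference_params, alpha_update,
                                     large_reference_vectors):
    """Starting AT the generating parameters of a large panel, one M-step
    must barely move them: the truth sits near the MLE."""
    vectors = large_reference_vectors
    w = fmlmm.fmlmm_e_step(vectors, fmlmm_reference_params)
    updated = fmlmm.fmlmm_m_step(vectors, w, fmlmm_reference_params,
                                 alpha_update)
    p0 = fmlmm_reference_params
    for g in range(3):
        assert np.linalg.norm(updated.alpha[g] - p0.alpha[g]) \
            < 0.02 * np.linalg.norm(p0.alpha[g])
        assert np.linalg.norm(updated.phi[g] - p0.phi[g], "fro") \
            < 0.02 * np.linalg.norm(p0.phi[g], "fro")
        assert np.abs(updated.sigma2[g] - p0.sigma2[g]).max() \
            < 0.02 * p0.sigma2[g].max()
    assert np.abs(updated.pi - p0.pi).max() < 0.02


def test_reduction_to_pooled_fmm_at_zero_random_effect():
    """With Phi = 0 and a shared error variance the marginal likelihood
    equals the pooled diagonal-covariance Gaussian mixture with shared
    tissue membership, evaluated directly."""
    s = 4e-4
    p = LMMMixtureParams(pi=[0.55, 0.45],
                         alpha=[[0.85, 0.12], [0.68, 0.30]],
                         phi=np.zeros((2, 2, 2)),
                         sigma2=np.full((2, 2), s))
    rng = np.random.default_rng(4)
    vectors = [rng.normal(0.5, 0.2, size=6) for _ in range(12)]
    got = fmlmm.marginal_loglik(vectors, p)
    # oracle: per tissue, log sum_g pi_g prod_r N(x_ir | alpha_g, s I_2)
    expected = 0.0
    for x in vectors:
        reps = np.stack([x[:3], x[3:]], axis=1)  # (R, 2)
        per_g = []
        for g in range(2):
            logs = stats.multivariate_normal.logpdf(reps, p.alpha[g],
                                                    s * np.eye(2))
            per_g.append(np.log(p.pi[g]) + logs.sum())
        expected += np.logaddexp(*per_g)
    assert got == pytest.approx(expected, abs=1e-6)


def test_fit_recovers_well_separated_components():
    gen = LMMMixtureParams(pi=[0.5, 0.5],
                           alpha=[[0.2, 0.7], [0.8, 0.1]],
                           phi=np.stack([1e-5 * np.eye(2)] * 2),
                           sigma2=np.full((2, 2), 1e-5))
    panel, labels = synthetic.generate_fmlmm_panel(gen, 60, 3, seed=5,
                                                   missing_rate=0.0)
    fit = fmlmm.fmlmm_fit(panel, 2, seed=0, n_starts=3)
    assigned = fit.allocation()["component"].to_numpy() - 1
    agreement = max((assigned == labels).mean(), (assigned != labels).mean())
    assert agreement == 1.0
    assert np.all(np.diff(fit.loglik_trace) > -1e-8)


def test_fit_handles_unequal_replicate_counts(fmlmm_reference_params):
    panel, _ = synthetic.generate_fmlmm_panel(fmlmm_reference_params, 80, 3,
                                              seed=6, missing_rate=0.3)
    fit = fmlmm.fmlmm_fit(panel, 2, seed=0, n_starts=2, max_iter=200)
    assert np.isfinite(fit.loglik)
    assert np.abs(fit.weights.sum(axis=1) - 1.0).max() < 1e-12
    assert len(fit.tissue_ids) == 80


def test_permutation_invariance_of_marginal_loglik(two_component_params):
    rng = np.random.default_rng(7)
    vectors = [rng.normal(0.5, 0.1, size=6) for _ in range(8)]
    p = two_component_params
    swapped = LMMMixtureParams(pi=p.pi[::-1].copy(), alpha=p.alpha[::-1].copy(),
                               phi=p.phi[::-1].copy(), sigma2=p.sigma2[::-1].copy())
    assert fmlmm.marginal_loglik(vectors, swapped) \
        == pytest.approx(fmlmm.marginal_loglik(vectors, p), rel=1e-12)


def test_psd_and_nonnegativity_preserved_over_em(fmlmm_reference_params):
    panel, _ = synthetic.generate_fmlmm_panel(fmlmm_reference_params, 100, 3,
                                              seed=8, missing_rate=0.0)
    _, vectors = panel.tissue_vectors()
    params = fmlmm._base_init(vectors, 3, seed=0)
    for _ in range(25):
        w = fmlmm.fmlmm_e_step(vectors, params)
        params = fmlmm.fmlmm_m_step(vectors, w, params)
        assert np.all(np.linalg.eigvalsh(params.phi) > -1e-12)
        assert np.all(params.sigma2 >= 0)
        assert np.allclose(params.phi, np.transpose(params.phi, (0, 2, 1)))


def test_bic_free_parameter_counts():
    assert fmlmm.fmlmm_n_free_params(3) == 23
    assert fmlmm.fmlmm_n_free_params(1) == 7
    assert fmlmm.fmlmm_bic(-100.0, 1, 50) \
        == pytest.approx(200 + 7 * np.log(50))
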