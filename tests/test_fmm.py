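"""Pooled-replicate Gaussian mixture: EM correctness against brute-force
oracles, covariance-family constraints, BIC bookkeeping and allocation."""

import itertools

import numpy as np
import pytest
from scipy import optimize, stats

from splicemix import fmm, synthetic
from splicemix.params import GaussianMixtureParams


def brute_force_loglik(points, params):
    """Independent oracle: direct per-point density sums via scipy."""
    total = 0.0
    for x in np.atleast_2d(points):
        dens = sum(pi * stats.multivariate_normal.pdf(x, mean=mu, cov=sig)
                   for pi, mu, sig in zip(params.pi, params.mu, params.sigma))
        total += np.log(dens)
    return total


@pytest.fixture
def tiny_mixture():
    return GaussianMixtureParams(
        pi=[0.4, 0.6], mu=[[0.0, 0.0], [2.0, 1.0]],
        sigma=np.stack([[[1.0, 0.3], [0.3, 0.8]], [[0.5, -0.1], [-0.1, 0.7]]]))


def test_loglik_single_point_at_mean():
    params = GaussianMixtureParams(pi=[1.0], mu=[[1.0, 2.0]], sigma=np.eye(2)[None])
    assert fmm.loglik(np.array([[1.0, 2.0]]), params) \
        == pytest.approx(np.log(1 / (2 * np.pi)), abs=1e-10)


def test_loglik_additive_under_duplication(tiny_mixture):
    pts = np.array([[0.1, 0.2], [1.5, 0.9], [-1.0, 0.3]])
    one = fmm.loglik(pts, tiny_mixture)
    two = fmm.loglik(np.vstack([pts, pts]), tiny_mixture)
    assert two == pytest.approx(2 * one, rel=1e-12)


def test_loglik_matches_brute_force_oracle(tiny_mixture):
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(4, 2))
    assert fmm.loglik(pts, tiny_mixture) \
        == pytest.approx(brute_force_loglik(pts, tiny_mixture), abs=1e-10)


def test_e_step_trivial_and_symmetric_cases(tiny_mixture):
    one_comp = GaussianMixtureParams(pi=[1.0], mu=[[0, 0]], sigma=np.eye(2)[None])
    w = fmm.e_step(np.array([[3.0, -1.0]]), one_comp)
    assert w[0] == pytest.approx([1.0])

    sym = GaussianMixtureParams(pi=[0.5, 0.5], mu=[[-1, 0], [1, 0]],
                                sigma=np.stack([np.eye(2)] * 2))
    w = fmm.e_step(np.array([[0.0, 5.0]]), sym)
    assert w[0] == pytest.approx([0.5, 0.5], abs=1e-12)

    rng = np.random.default_rng(1)
    pts = rng.normal(size=(50, 2))
    rows = fmm.e_step(pts, tiny_mixture).sum(axis=1)
    assert np.abs(rows - 1.0).max() < 1e-12


def test_m_step_single_component_is_sample_moments():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(40, 2))
    params = fmm.m_step(pts, np.ones((40, 1)), "VVV")
    assert params.mu[0] == pytest.approx(pts.mean(axis=0))
    dev = pts - pts.mean(axis=0)
    assert params.sigma[0] == pytest.approx(dev.T @ dev / 40, abs=1e-10)


def test_m_step_hard_weights_give_per_blob_moments(separated_blobs):
    pts, labels = separated_blobs
    w = np.zeros((len(pts), 2))
    w[np.arange(len(pts)), labels] = 1.0
    params = fmm.m_step(pts, w, "VVV")
    for g in range(2):
        blob = pts[labels == g]
        assert params.mu[g] == pytest.approx(blob.mean(axis=0))


def test_family_constraints_hold_after_m_step(separated_blobs):
    pts, labels = separated_blobs
    w = np.zeros((len(pts), 2))
    w[np.arange(len(pts)), labels] = 1.0
    eii = fmm.m_step(pts, w, "EII").sigma
    assert np.allclose(eii[0], eii[1]) and np.allclose(eii[0], eii[0][0, 0] * np.eye(2))
    vii = fmm.m_step(pts, w, "VII").sigma
    assert np.allclose(vii[0], vii[0][0, 0] * np.eye(2))
    eee = fmm.m_step(pts, w, "EEE").sigma
    assert np.allclose(eee[0], eee[1])
    eev = fmm.m_step(pts, w, "EEV").sigma
    ev0 = np.sort(np.linalg.eigvalsh(eev[0]))
    ev1 = np.sort(np.linalg.eigvalsh(eev[1]))
    assert ev0 == pytest.approx(ev1, rel=1e-10)  # shared scale and shape


def test_eev_recovery_of_shared_eigenvalues():
    """Refit data generated from an exactly-EEV mixture; the shared
    eigenvalues must come back within 5%."""
    lam = np.array([0.02, 0.002])
    def rot(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, -s], [s, c]])
    sigmas = np.stack([rot(t) @ np.diag(lam) @ rot(t).T
                       for t in (0.3, 1.2, 2.2)])
    gen = GaussianMixtureParams(pi=[0.4, 0.35, 0.25],
                                mu=[[0, 0], [2, 0], [0, 2]], sigma=sigmas,
                                family="EEV")
    pts, _ = synthetic.generate_fmm_points(gen, 5000, seed=4)
    fit = fmm.em_fit(pts, 3, "EEV", seed=0, n_starts=5)
    fitted = np.sort(np.linalg.eigvalsh(fit.params.sigma[0]))
    assert fitted == pytest.approx(np.sort(lam), rel=0.05)


def test_cem_init_deterministic_and_separates_blobs(separated_blobs):
    pts, labels = separated_blobs
    a = fmm.cem_init(pts, 2, seed=5)
    b = fmm.cem_init(pts, 2, seed=5)
    assert np.allclose(a.mu, b.mu) and np.allclose(a.pi, b.pi)
    got = {tuple(np.round(m, 0)) for m in a.mu}
    want = {(-10.0, -10.0), (10.0, 10.0)}
    assert got == want


def test_em_single_component_is_closed_form_mle():
    rng = np.random.default_rng(6)
    pts = rng.normal(size=(30, 2))
    fit = fmm.em_fit(pts, 1, "VVV", seed=0)
    dev = pts - pts.mean(axis=0)
    assert fit.params.mu[0] == pytest.approx(pts.mean(axis=0))
    assert fit.params.sigma[0] == pytest.approx(dev.T @ dev / 30, rel=1e-6)


def test_em_beats_direct_numerical_maximizer():
    """On a tiny G=2 VVV instance EM must reach at least the likelihood a
    generic optimizer finds for the same objective."""
    rng = np.random.default_rng(7)
    pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(4, 1, (3, 2))])

    def unpack(v):
        pi1 = 1 / (1 + np.exp(-v[0]))
        mu = v[1:5].reshape(2, 2)
        sig = []
        for g in range(2):
            a, b, c = v[5 + 3 * g: 8 + 3 * g]
            L = np.array([[np.exp(a), 0.0], [c, np.exp(b)]])
            sig.append(L @ L.T)
        return GaussianMixtureParams(pi=[pi1, 1 - pi1], mu=mu, sigma=np.stack(sig))

    def neg_loglik(v):
        try:
            with np.errstate(over="ignore"):
                return -fmm.loglik(pts, unpack(v))
        except (ValueError, np.linalg.LinAlgError):
            return 1e10

    best = np.inf
    for s in range(5):
        x0 = np.concatenate([[0.0], pts[np.random.default_rng(s).choice(6, 2)].ravel(),
                             np.tile([0.0, 0.0, 0.0], 2)])
        res = optimize.minimize(neg_loglik, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "fatol": 1e-10})
        best = min(best, res.fun)
    fit = fmm.em_fit(pts, 2, "VVV", seed=0, n_starts=10)
    assert fit.loglik >= -best - 1e-4


def test_em_loglik_trace_monotone_all_families(fmm_reference_params):
    pts, _ = synthetic.generate_fmm_points(fmm_reference_params, 300, seed=9)
    for family in ("EII", "VII", "EEE", "VVV", "EEV"):
        fit = fmm.em_fit(pts, 3, family, seed=1, n_starts=5)
        diffs = np.diff(fit.loglik_trace)
        assert diffs.min() > -1e-10, family
        assert np.abs(fit.params.pi.sum() - 1.0) < 1e-12
        assert np.all(np.linalg.eigvalsh(fit.params.sigma) > -1e-12)


def test_matches_sklearn_reference_on_unconstrained_fit():
    """Independent cross-check: converged VVV loglik agrees with
    scikit-learn's GaussianMixture on well-separated data."""
    sklearn = pytest.importorskip("sklearn.mixture")
    rng = np.random.default_rng(10)
    pts = np.vstack([rng.normal(0, 0.5, (80, 2)), rng.normal(5, 0.5, (80, 2))])
    fit = fmm.em_fit(pts, 2, "VVV", seed=0)
    gm = sklearn.GaussianMixture(2, covariance_type="full", reg_covar=1e-10,
                                 n_init=3, random_state=0, tol=1e-8).fit(pts)
    assert fit.loglik / len(pts) == pytest.approx(gm.score(pts), abs=1e-4)


@pytest.mark.parametrize("family,G,expected", [
    ("EEV", 3, 13), ("VVV", 2, 11), ("EII", 1, 3),
    ("EEE", 2, 8), ("VII", 2, 7),
])
def test_n_free_params(family, G, expected):
    assert fmm.n_free_params(family, G) == expected


def test_bic_arithmetic():
    assert fmm.bic(0.0, 1, 1) == pytest.approx(0.0)
    assert fmm.bic(-10.0, 2, 100) == pytest.approx(20 + 2 * np.log(100))


def test_permutation_invariance(tiny_mixture):
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(20, 2))
    swapped = GaussianMixtureParams(pi=tiny_mixture.pi[::-1].copy(),
                                    mu=tiny_mixture.mu[::-1].copy(),
                                    sigma=tiny_mixture.sigma[::-1].copy())
    assert fmm.loglik(pts, swapped) == pytest.approx(
        fmm.loglik(pts, tiny_mixture), rel=1e-12)


def test_map_allocation_and_entropy():
    w = np.array([[1.0, 0.0, 0.0],
                  [1 / 3, 1 / 3, 1 / 3],
                  [0.51, 0.49, 0.0]])
    alloc = fmm.map_allocate(w)
    assert list(alloc["component"]) == [1, 1, 1]
    assert alloc["entropy"][0] == pytest.approx(0.0, abs=1e-12)
    assert alloc["entropy"][1] == pytest.approx(1.0, abs=1e-12)
    # two-component anchors for the published uncertainty discussion
    assert fmm.normalized_entropy(np.array([0.51, 0.49]), 2) \
        == pytest.approx(0.99971, abs=5e-6)
    assert fmm.normalized_entropy(np.array([0.99, 0.01]), 2) \
        == pytest.approx(0.08079, abs=5e-6)


def test_tissue_summary_majority_and_counts():
    import pandas as pd
    alloc = pd.DataFrame({
        "tissue_id": ["a", "a", "a", "b", "b"],
        "replicate_id": [1, 2, 3, 1, 2],
        "component": [1, 1, 2, 2, 2],
        "entropy": [0.1, 0.2, 0.3, 0.0, 0.0],
    })
    summary = fmm.tissue_summary(alloc, G=2)
    a = summary[summary["tissue_id"] == "a"].iloc[0]
    assert (a["n_comp1"], a["n_comp2"], a["component"]) == (2, 1, 1)
    assert a["entropy"] == pytest.approx(0.2)
    assert summary[["n_comp1", "n_comp2"]].to_numpy().sum() == 5
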