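"""Finite mixture of bivariate Gaussians over pooled technical replicates.

Each tissue replicate is treated as an independent unit, so a panel of n
tissues with R replicates yields nR points in the (Ratio1, Ratio2) plane.
The EM algorithm alternates posterior-weight updates with weighted-moment
M-steps; the component covariances can be constrained through the
scale/shape/orientation eigendecomposition Sigma_g = lambda_g D_g A_g D_g'.
Five families are supported:

======  =============================================
EII     spherical, equal volume across components
VII     spherical, varying volume
EEE     one shared full covariance
VVV     unconstrained per-component covariances
EEV     equal volume and shape, varying orientation
======  =============================================

Model choice minimizes BIC = -2 loglik + k log(nR); initialization uses
short classification-EM (CEM) runs from random starts.  Hard MAP labels
come with a normalized Shannon entropy measuring allocation uncertainty.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .params import COVARIANCE_FAMILIES, GaussianMixtureParams

log = logging.getLogger(__name__)

_DIM = 2
_LOG2PI = np.log(2.0 * np.pi)


class ComponentCollapseError(RuntimeError):
    """A mixture component lost essentially all posterior mass."""


def _regularize(sigma: np.ndarray, rel_floor: float = 1e-10) -> np.ndarray:
    """Floor eigenvalues at rel_floor * trace so near-singular components
    (the fitted ones have |rho| ~ 0.99) stay invertible."""
    out = np.array(sigma, dtype=float, copy=True)
    for g in range(out.shape[0]):
        tr = np.trace(out[g])
        floor = rel_floor * max(tr, 1e-300)
        vals, vecs = np.linalg.eigh(out[g])
        if vals.min() < floor:
            vals = np.maximum(vals, floor)
            out[g] = (vecs * vals) @ vecs.T
    return out


def component_logpdf(points: np.ndarray, params: GaussianMixtureParams) -> np.ndarray:
    """(n, G) matrix of per-component Gaussian log densities."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    out = np.empty((n, params.G))
    sigma = _regularize(params.sigma)
    for g in range(params.G):
        chol = np.linalg.cholesky(sigma[g])
        dev = points - params.mu[g]
        z = np.linalg.solve(chol, dev.T)  # (2, n)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        with np.errstate(over="ignore"):  # far-tail points: -inf is fine
            out[:, g] = -0.5 * (_DIM * _LOG2PI + logdet + (z * z).sum(axis=0))
    return out


def loglik(points: np.ndarray, params: GaussianMixtureParams) -> float:
    """Pooled-replicate observed-data log-likelihood
    sum_units log sum_g pi_g N(x | mu_g, Sigma_g), via log-sum-exp."""
    lp = component_logpdf(points, params) + np.log(params.pi)[None, :]
    return float(logsumexp(lp, axis=1).sum())


def e_step(points: np.ndarray, params: GaussianMixtureParams) -> np.ndarray:
    """Posterior membership weights w_irg; rows sum to one."""
    lp = component_logpdf(points, params) + np.log(params.pi)[None, :]
    lw = lp - logsumexp(lp, axis=1, keepdims=True)
    return np.exp(lw)


# ------------------------------------------------------------------ M-step

def _family_covariances(scatter: np.ndarray, masses: np.ndarray,
                        family: str) -> np.ndarray:
    """Project per-component weighted scatter matrices onto a family.

    ``scatter[g]`` is sum_units w_g (x - mu_g)(x - mu_g)'; ``masses[g]`` is
    the component mass n_g.  Closed forms follow the eigenvalue
    decomposition approach for constrained Gaussian mixtures.
    """
    G = scatter.shape[0]
    n = masses.sum()
    if family == "VVV":
        return scatter / masses[:, None, None]
    if family == "EEE":
        pooled = scatter.sum(axis=0) / n
        return np.repeat(pooled[None, :, :], G, axis=0)
    if family == "VII":
        lam = np.trace(scatter, axis1=1, axis2=2) / (_DIM * masses)
        return lam[:, None, None] * np.eye(_DIM)[None, :, :]
    if family == "EII":
        lam = np.trace(scatter, axis1=1, axis2=2).sum() / (_DIM * n)
        return np.repeat((lam * np.eye(_DIM))[None, :, :], G, axis=0)
    if family == "EEV":
        # W_g = D_g Omega_g D_g'; share scale and shape, keep orientations
        omegas = np.empty((G, _DIM))
        rotations = np.empty((G, _DIM, _DIM))
        for g in range(G):
            vals, vecs = np.linalg.eigh(scatter[g])
            order = np.argsort(vals)[::-1]
            omegas[g] = vals[order]
            rotations[g] = vecs[:, order]
        pooled = np.maximum(omegas.sum(axis=0), 1e-300)
        det_pooled = float(np.prod(pooled))
        shape = pooled / det_pooled ** (1.0 / _DIM)  # det(A) = 1
        lam = det_pooled ** (1.0 / _DIM) / n  # shared volume
        out = np.empty_like(scatter)
        for g in range(G):
            out[g] = (rotations[g] * (lam * shape)) @ rotations[g].T
        return out
    raise ValueError(f"unknown covariance family {family!r}")


def m_step(points: np.ndarray, weights: np.ndarray,
           family: str = "VVV") -> GaussianMixtureParams:
    """Weighted-moment updates, then projection onto the covariance family."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    weights = np.asarray(weights, dtype=float)
    n, G = weights.shape
    masses = weights.sum(axis=0)
    if masses.min() < 1e-10:
        raise ComponentCollapseError(
            f"component mass collapsed to {masses.min():.3g}")
    pi = masses / n
    mu = (weights.T @ points) / masses[:, None]
    scatter = np.empty((G, _DIM, _DIM))
    for g in range(G):
        dev = points - mu[g]
        scatter[g] = (weights[:, g, None] * dev).T @ dev
    sigma = _regularize(_family_covariances(scatter, masses, family))
    return GaussianMixtureParams(pi=pi, mu=mu, sigma=sigma, family=family)


# ----------------------------------------------------------- initialization

def cem_init(points: np.ndarray, G: int, family: str = "VVV",
             n_starts: int = 20, n_iter: int = 10,
             seed: int = 0) -> GaussianMixtureParams:
    """Short classification-EM runs from random starts.

    Each start seeds component means at G distinct points, hard-assigns by
    nearest mean, then alternates hard E-steps with family-constrained
    M-steps.  The start with the highest complete-data log-likelihood wins.
    Hard assignment is robust to stray extreme values and gives EM a
    well-separated launch point.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if G == 1:
        w = np.ones((n, 1))
        return m_step(points, w, family)
    rng = np.random.default_rng(seed)
    best, best_cll = None, -np.inf
    for _ in range(n_starts):
        centers = points[rng.choice(n, size=G, replace=False)]
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        try:
            params = None
            for _ in range(n_iter):
                w = np.zeros((n, G))
                w[np.arange(n), labels] = 1.0
                params = m_step(points, w, family)
                labels = (component_logpdf(points, params)
                          + np.log(params.pi)[None, :]).argmax(axis=1)
            # complete-data loglik at the final hard partition
            lp = component_logpdf(points, params) + np.log(params.pi)[None, :]
            cll = float(lp[np.arange(n), labels].sum())
        except (ComponentCollapseError, np.linalg.LinAlgError):
            continue
        if cll > best_cll:
            best, best_cll = params, cll
    if best is None:
        raise ComponentCollapseError("all CEM starts collapsed")
    return best


# --------------------------------------------------------------------- fit

@dataclass
class FmmFit:
    params: GaussianMixtureParams
    weights: np.ndarray
    loglik_trace: list[float]
    n_units: int
    converged: bool

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    @property
    def bic(self) -> float:
        k = n_free_params(self.params.family, self.params.G)
        return bic(self.loglik, k, self.n_units)


def em_fit(points: np.ndarray, G: int, family: str = "VVV",
           tol: float = 1e-8, max_iter: int = 500,
           init: GaussianMixtureParams | None = None,
           n_starts: int = 20, cem_iter: int = 10, seed: int = 0) -> FmmFit:
    """EM until the log-likelihood change drops below ``tol``.

    On component collapse the fit restarts from a fresh CEM initialization
    (different stream), up to 3 times.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    k = n_free_params(family, G)
    if n < k:
        log.warning("only %d points for %d free parameters (%s, G=%d)",
                    n, k, family, G)
    for attempt in range(4):
        try:
            params = init if (init is not None and attempt == 0) else cem_init(
                points, G, family, n_starts=n_starts, n_iter=cem_iter,
                seed=seed + 1000 * attempt)
            trace = [loglik(points, params)]
            converged = False
            for _ in range(max_iter):
                w = e_step(points, params)
                params = m_step(points, w, family)
                trace.append(loglik(points, params))
                if abs(trace[-1] - trace[-2]) < tol:
                    converged = True
                    break
            w = e_step(points, params)
            return FmmFit(params, w, trace, n, converged)
        except (ComponentCollapseError, np.linalg.LinAlgError) as err:
            last = err
            log.warning("EM attempt %d failed (%s); restarting", attempt, err)
    raise ComponentCollapseError(f"EM failed after 3 restarts: {last}")


# ------------------------------------------------------------- BIC and k

def n_free_params(family: str, G: int, dim: int = 2) -> int:
    """Free-parameter count: G*dim means + (G-1) proportions + covariance
    parameters by family (dim = 2 only)."""
    if dim != _DIM:
        raise ValueError("only bivariate mixtures are supported")
    if family not in COVARIANCE_FAMILIES:
        raise ValueError(f"unknown covariance family {family!r}")
    base = G * dim + (G - 1)
    cov = {
        "EII": 1,
        "VII": G,
        "EEE": dim * (dim + 1) // 2,
        "VVV": G * (dim * (dim + 1) // 2),
        "EEV": 1 + (dim - 1) + G * (dim * (dim - 1) // 2),
    }[family]
    return base + cov


def bic(loglik_value: float, k: int, n: int) -> float:
    """BIC = -2 loglik + k log n; smaller is better."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik_value + k * np.log(n)


def select_model(points: np.ndarray, G_range=range(1, 7),
                 families=("EEV",), seed: int = 0,
                 **fit_kwargs) -> tuple[FmmFit, pd.DataFrame]:
    """Fit every (G, family) combination; return the minimum-BIC fit and the
    full score table (non-finite fits are excluded with a warning)."""
    rows, best, best_bic = [], None, np.inf
    for G, family in itertools.product(G_range, families):
        try:
            fit = em_fit(points, G, family, seed=seed, **fit_kwargs)
        except (ComponentCollapseError, np.linalg.LinAlgError) as err:
            log.warning("fit G=%d %s failed: %s", G, family, err)
            continue
        if not np.isfinite(fit.loglik):
            log.warning("fit G=%d %s produced non-finite loglik; excluded", G, family)
            continue
        rows.append({"G": G, "family": family, "loglik": fit.loglik,
                     "k": n_free_params(family, G), "bic": fit.bic})
        if fit.bic < best_bic:
            best, best_bic = fit, fit.bic
    if best is None:
        raise ComponentCollapseError("no (G, family) combination could be fitted")
    return best, pd.DataFrame(rows)


# ------------------------------------------------------ allocation tables

def normalized_entropy(weights_row: np.ndarray, G: int | None = None) -> float:
    """Shannon entropy of a posterior row, normalized by log G into [0, 1]."""
    w = np.asarray(weights_row, dtype=float)
    G = G if G is not None else len(w)
    if G <= 1:
        return 0.0
    w = w[w > 0]  # 0 log 0 = 0
    return float(-(w * np.log(w)).sum() / np.log(G))


def map_allocate(weights: np.ndarray,
                 index: pd.DataFrame | None = None) -> pd.DataFrame:
    """Hard MAP labels and normalized entropy per unit.

    Ties go to the lowest component index (logged).  If ``index`` carries
    (tissue_id, replicate_id) columns they are attached, enabling the
    tissue-level summary.  Labels are 1-based for reporting.
    """
    weights = np.asarray(weights, dtype=float)
    n, G = weights.shape
    labels = weights.argmax(axis=1)
    ties = (weights == weights.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        log.info("MAP ties at %d unit(s); lowest index taken", int(ties.sum()))
    entropy = np.array([normalized_entropy(weights[i], G) for i in range(n)])
    out = pd.DataFrame({"component": labels + 1, "entropy": entropy})
    if index is not None:
        out = pd.concat([index.reset_index(drop=True), out], axis=1)
    return out


def tissue_summary(alloc: pd.DataFrame, G: int) -> pd.DataFrame:
    """Per-tissue replicate counts per component, majority label (ties to
    lowest index, logged) and average entropy."""
    if "tissue_id" not in alloc.columns:
        raise ValueError("allocation table lacks tissue_id")
    rows = []
    for tid, grp in alloc.groupby("tissue_id", sort=True):
        counts = np.bincount(grp["component"] - 1, minlength=G)
        if (counts == counts.max()).sum() > 1:
            log.info("majority tie at tissue %s; lowest index taken", tid)
        rows.append({"tissue_id": tid,
                     **{f"n_comp{g + 1}": int(counts[g]) for g in range(G)},
                     "component": int(counts.argmax()) + 1,
                     "entropy": float(grp["entropy"].mean())})
    return pd.DataFrame(rows)
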