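"""Finite mixture of linear mixed models for replicated tissue measurements.

All R technical replicates of a tissue share one mixture component; the
tissue's stacked 2R-vector x_i (R values of Ratio1 then R of Ratio2) follows,
conditional on component g,

    x_i = V (alpha_g + u_ig) + e_ig,

with V the 2R x 2 block design ([1_R, 0], [0, 1_R]), a tissue-level random
effect u_ig ~ MVN(0, Phi_g) (non-diagonal: the two ratios trade off on the
simplex) and measurement error e_ig ~ MVN(0, Omega_g) with per-variant
variances, Omega_g = diag(V sigma2_g).  Marginally x_i | g ~
MVN(V alpha_g, V Phi_g V' + Omega_g).

The EM treats both component labels and random effects as missing data.
The M-step updates used here are the conditional-expectation closed forms:
the incremental fixed-effect update (algebraically the exact EM update),
the per-variant error-variance update with the trace of cov(e|x) =
Omega - Omega Sigma^-1 Omega restricted to the variant's block, and the
random-effect covariance update E[u u' | x] averaged over tissues.  A
closed-form weighted-GLS alpha update is available as an alternative.
Tissues with unequal replicate counts get per-tissue design matrices.

BIC uses the number of tissues as sample size (the statistical units under
this model) with k = G(2 + 3 + 2) + (G - 1) free parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import fmm as _fmm
from .panel import TissuePanel
from .params import LMMMixtureParams

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


class ComponentCollapseError(RuntimeError):
    pass


def build_design(R: int) -> np.ndarray:
    """The 2R x 2 block design matrix [[1_R, 0_R], [0_R, 1_R]]."""
    if R < 1:
        raise ValueError("R must be >= 1")
    V = np.zeros((2 * R, 2))
    V[:R, 0] = 1.0
    V[R:, 1] = 1.0
    return V


def marginal_moments(params: LMMMixtureParams, g: int, R: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Component-g marginal mean V alpha_g and covariance V Phi_g V' + Omega_g."""
    V = build_design(R)
    mu = V @ params.alpha[g]
    omega = np.diag(V @ params.sigma2[g])
    sigma = V @ params.phi[g] @ V.T + omega
    return mu, 0.5 * (sigma + sigma.T)


def _floored_inverse(sigma: np.ndarray, rel_floor: float = 1e-12
                     ) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant via eigendecomposition with a relative
    eigenvalue floor (the marginal covariances can be near-singular)."""
    vals, vecs = np.linalg.eigh(sigma)
    floor = rel_floor * max(np.trace(sigma), 1e-300)
    vals = np.maximum(vals, floor)
    inv = (vecs / vals) @ vecs.T
    return inv, float(np.log(vals).sum())


def _group_by_R(tissue_vectors) -> dict[int, np.ndarray]:
    """Indices of tissues per replicate count; a precomputed dict of
    {R: (indices, stacked (m, 2R) array)} passes through unchanged."""
    if isinstance(tissue_vectors, dict):
        return tissue_vectors
    groups: dict[int, list[int]] = {}
    for i, x in enumerate(tissue_vectors):
        if len(x) % 2:
            raise ValueError("tissue vectors must have even length 2R")
        groups.setdefault(len(x) // 2, []).append(i)
    return {R: (np.array(idx), np.stack([tissue_vectors[i] for i in idx]))
            for R, idx in groups.items()}


def _n_tissues(groups: dict) -> int:
    return sum(len(idx) for idx, _ in groups.values())


def _log_marginal_density(tissue_vectors, params: LMMMixtureParams) -> np.ndarray:
    """(n, G) log N(x_i; V alpha_g, Sigma_g), grouped by replicate count."""
    groups = _group_by_R(tissue_vectors)
    n, G = _n_tissues(groups), params.G
    out = np.empty((n, G))
    for R, (idx, X) in groups.items():
        for g in range(G):
            mu, sigma = marginal_moments(params, g, R)
            inv, logdet = _floored_inverse(sigma)
            dev = X - mu
            quad = np.einsum("ij,jk,ik->i", dev, inv, dev)
            out[idx, g] = -0.5 * (2 * R * _LOG2PI + logdet + quad)
    return out


def marginal_loglik(tissue_vectors, params: LMMMixtureParams) -> float:
    lp = _log_marginal_density(tissue_vectors, params) + np.log(params.pi)[None, :]
    return float(logsumexp(lp, axis=1).sum())


def fmlmm_e_step(tissue_vectors, params: LMMMixtureParams) -> np.ndarray:
    """Per-tissue posterior membership weights w_ig."""
    lp = _log_marginal_density(tissue_vectors, params) + np.log(params.pi)[None, :]
    return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))


def blup(x_i: np.ndarray, params: LMMMixtureParams, g: int) -> np.ndarray:
    """Posterior-mean random-effect predictor for tissue vector ``x_i``
    under component g, weighted by the tissue's membership probability:
    w_ig Phi_g V' Sigma_g^-1 (x_i - V alpha_g)."""
    x_i = np.asarray(x_i, dtype=float)
    R = len(x_i) // 2
    V = build_design(R)
    w = fmlmm_e_step([x_i], params)[0, g]
    mu, sigma = marginal_moments(params, g, R)
    inv, _ = _floored_inverse(sigma)
    return w * params.phi[g] @ V.T @ inv @ (x_i - mu)


def _symmetrize_psd(mat: np.ndarray, floor: float = 0.0) -> np.ndarray:
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() < floor:
        log.warning("projecting covariance update onto the PSD cone "
                    "(min eigenvalue %.3g)", vals.min())
        vals = np.maximum(vals, floor)
        sym = (vecs * vals) @ vecs.T
    return sym


def fmlmm_m_step(tissue_vectors, weights: np.ndarray,
                 params: LMMMixtureParams,
                 alpha_update: str = "printed") -> LMMMixtureParams:
    """One M-step from posterior weights and current parameters.

    ``alpha_update``:
      * ``printed`` — incremental update alpha + (V'Omega^-1 V)^-1 V' Sigma^-1
        applied to the weighted mean residual (the exact EM conditional-
        expectation form);
      * ``gls`` — closed-form weighted generalized-least-squares solve.
    """
    if alpha_update not in ("printed", "gls"):
        raise ValueError(f"unknown alpha_update {alpha_update!r}")
    weights = np.asarray(weights, dtype=float)
    n, G = weights.shape
    masses = weights.sum(axis=0)
    if masses.min() < 1e-10:
        raise ComponentCollapseError(f"component mass collapsed to {masses.min():.3g}")
    groups = _group_by_R(tissue_vectors)
    new_pi = masses / n
    new_alpha = np.empty((G, 2))
    new_phi = np.empty((G, 2, 2))
    new_sigma2 = np.empty((G, 2))
    for g in range(G):
        alpha_g = params.alpha[g]
        # per-R-group precomputations at the current parameters
        sum_w_resid = np.zeros(2)     # for the alpha update, variant means
        gls_lhs = np.zeros((2, 2))
        gls_rhs = np.zeros(2)
        ee_acc = np.zeros(2)          # per-variant sum of E[e'e | x] pieces
        uu_acc = np.zeros((2, 2))     # sum of w * E[u u' | x]
        r_weight = np.zeros(2)        # sum of w * R per variant
        for R, (idx, X) in groups.items():
            V = build_design(R)
            w = weights[idx, g]
            mu, sigma = marginal_moments(params, g, R)
            inv, _ = _floored_inverse(sigma)
            omega_diag = V @ params.sigma2[g]            # (2R,)
            dev = X - mu                                  # (m, 2R)
            # conditional means given component membership
            u_hat = dev @ (inv @ V @ params.phi[g])       # (m, 2) = Phi V' inv dev
            e_hat = dev @ (inv * omega_diag[None, :])     # (m, 2R) = Omega inv dev
            cov_u = params.phi[g] - params.phi[g] @ V.T @ inv @ V @ params.phi[g]
            # diag(Omega - Omega Sigma^-1 Omega)
            cov_e_diag = omega_diag - omega_diag ** 2 * np.diag(inv)
            # alpha (printed): (V'Omega^-1 V)^-1 V' Sigma^-1 dev = block means
            # of Sigma^-1-projected residuals scaled by sigma2/R
            proj = dev @ inv                              # (m, 2R)
            block = np.stack([proj[:, :R].sum(axis=1),
                              proj[:, R:].sum(axis=1)], axis=1)  # (m, 2)
            sum_w_resid += (w[:, None] * block).sum(axis=0) * params.sigma2[g] / R
            # alpha (gls)
            vsv = V.T @ inv @ V
            gls_lhs += w.sum() * vsv
            gls_rhs += (w[:, None] * (X @ inv @ V)).sum(axis=0)
            # sigma2: per-variant sum of squared conditional error means
            # plus the per-variant trace of cov(e | x)
            e2 = e_hat ** 2
            ee = np.stack([e2[:, :R].sum(axis=1), e2[:, R:].sum(axis=1)], axis=1)
            tr_cov_e = np.array([cov_e_diag[:R].sum(), cov_e_diag[R:].sum()])
            ee_acc += (w[:, None] * (ee + tr_cov_e[None, :])).sum(axis=0)
            r_weight += w.sum() * R
            # Phi: E[u u' | x] = u_hat u_hat' + cov(u | x)
            uu = np.einsum("i,ij,ik->jk", w, u_hat, u_hat)
            uu_acc += uu + w.sum() * cov_u
        if alpha_update == "printed":
            new_alpha[g] = alpha_g + sum_w_resid / masses[g]
        else:
            new_alpha[g] = np.linalg.solve(gls_lhs, gls_rhs)
        new_sigma2[g] = np.maximum(ee_acc / r_weight, 0.0)
        new_phi[g] = _symmetrize_psd(uu_acc / masses[g])
    return LMMMixtureParams(pi=new_pi, alpha=new_alpha, phi=new_phi,
                            sigma2=new_sigma2)


# ------------------------------------------------------------------- fit

@dataclass
class FmlmmFit:
    params: LMMMixtureParams
    weights: np.ndarray
    loglik_trace: list[float]
    tissue_ids: list[str]
    n_tissues: int
    converged: bool

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    @property
    def bic(self) -> float:
        return fmlmm_bic(self.loglik, self.params.G, self.n_tissues)

    def allocation(self) -> pd.DataFrame:
        alloc = _fmm.map_allocate(self.weights)
        alloc.insert(0, "tissue_id", self.tissue_ids)
        return alloc


def _base_init(tissue_vectors: list[np.ndarray], G: int,
               seed: int) -> LMMMixtureParams:
    """Initialize from a pooled-replicate Gaussian mixture fit.

    Replicate points are clustered with the pooled FMM (CEM-initialized EM),
    labels are aggregated to tissues by majority, and component moments seed
    (alpha, Phi, sigma2).
    """
    rng = np.random.default_rng(seed)
    points, owner = [], []
    for i, x in enumerate(tissue_vectors):
        R = len(x) // 2
        for r in range(R):
            points.append([x[r], x[R + r]])
            owner.append(i)
    points = np.asarray(points)
    owner = np.asarray(owner)
    n = len(tissue_vectors)
    try:
        pooled = _fmm.em_fit(points, G, family="VVV", tol=1e-6, max_iter=100,
                             n_starts=5, seed=seed)
        rep_labels = pooled.weights.argmax(axis=1)
    except (_fmm.ComponentCollapseError, np.linalg.LinAlgError):
        rep_labels = rng.integers(0, G, size=len(points))
    labels = np.empty(n, dtype=int)
    for i in range(n):
        labels[i] = np.bincount(rep_labels[owner == i], minlength=G).argmax()
    # ensure every component owns at least one tissue
    for g in range(G):
        if not np.any(labels == g):
            labels[rng.integers(0, n)] = g
    tissue_means = np.stack([
        np.stack([x[: len(x) // 2].mean(), x[len(x) // 2:].mean()])
        for x in tissue_vectors])
    alpha = np.empty((G, 2))
    phi = np.empty((G, 2, 2))
    sigma2 = np.empty((G, 2))
    for g in range(G):
        sel = labels == g
        m = tissue_means[sel]
        alpha[g] = m.mean(axis=0)
        if sel.sum() > 2:
            phi[g] = np.cov(m.T) + 1e-6 * np.eye(2)
        else:
            phi[g] = 1e-4 * np.eye(2)
        within = []
        for i in np.where(sel)[0]:
            x = tissue_vectors[i]
            R = len(x) // 2
            within.append([x[:R].var(), x[R:].var()])
        sigma2[g] = np.maximum(np.mean(within, axis=0), 1e-8)
    pi = np.bincount(labels, minlength=G) / n
    pi = np.maximum(pi, 1e-3)
    pi /= pi.sum()
    return LMMMixtureParams(pi=pi, alpha=alpha, phi=phi, sigma2=sigma2)


def fmlmm_fit(panel: TissuePanel | list[np.ndarray], G: int,
              tol: float = 1e-8, max_iter: int = 500, n_starts: int = 10,
              seed: int = 0, alpha_update: str = "printed",
              tissue_ids: list[str] | None = None) -> FmlmmFit:
    """Best-of-``n_starts`` EM fit of the G-component mixture of LMMs.

    The first start uses the pooled-FMM initialization as-is; further starts
    jitter its fixed effects (sd 0.02, the scale of the between-component
    mean gaps) from a seeded stream.
    """
    if isinstance(panel, TissuePanel):
        tissue_ids, vectors = panel.tissue_vectors()
    else:
        vectors = list(panel)
        tissue_ids = tissue_ids or [f"tissue_{i}" for i in range(len(vectors))]
    n = len(vectors)
    groups = _group_by_R(vectors)
    base = _base_init(vectors, G, seed=seed)
    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            params = base
        else:
            params = LMMMixtureParams(
                pi=base.pi, alpha=base.alpha + rng.normal(0.0, 0.02,
                                                          size=base.alpha.shape),
                phi=base.phi, sigma2=base.sigma2)
        try:
            trace = [marginal_loglik(groups, params)]
            converged = False
            for _ in range(max_iter):
                w = fmlmm_e_step(groups, params)
                params = fmlmm_m_step(groups, w, params, alpha_update)
                trace.append(marginal_loglik(groups, params))
                if abs(trace[-1] - trace[-2]) < tol:
                    converged = True
                    break
            w = fmlmm_e_step(groups, params)
            fit = FmlmmFit(params, w, trace, tissue_ids, n, converged)
        except (ComponentCollapseError, np.linalg.LinAlgError) as err:
            log.warning("FMLMM start %d failed: %s", start, err)
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise ComponentCollapseError("every FMLMM start failed")
    return best


def fmlmm_n_free_params(G: int) -> int:
    """alpha (2) + Phi (3) + sigma2 (2) per component, plus G-1 proportions."""
    return G * 7 + (G - 1)


def fmlmm_bic(loglik_value: float, G: int, n_tissues: int) -> float:
    return -2.0 * loglik_value + fmlmm_n_free_params(G) * np.log(n_tissues)


def fmlmm_select(panel, G_list=(2, 3), seed: int = 0,
                 **fit_kwargs) -> tuple[FmlmmFit, pd.DataFrame]:
    """Fit each G and return the minimum-BIC fit with the score table."""
    if not G_list:
        raise ValueError("G_list must be nonempty")
    rows, best = [], None
    for G in G_list:
        try:
            fit = fmlmm_fit(panel, G, seed=seed, **fit_kwargs)
        except ComponentCollapseError as err:
            log.warning("FMLMM fit G=%d failed: %s", G, err)
            continue
        rows.append({"G": G, "loglik": fit.loglik,
                     "k": fmlmm_n_free_params(G), "bic": fit.bic})
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise ComponentCollapseError("no G could be fitted")
    return best, pd.DataFrame(rows)
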