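"""Parameter containers for the two mixture models.

Both models cluster tissues in the plane of the first two compositional
ratios (Ratio1 = [Ea]/total, Ratio2 = [Eb]/total); the third ratio is
implied by the unit-sum constraint and is never a model dimension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

COVARIANCE_FAMILIES = ("EII", "VII", "EEE", "VVV", "EEV")


def _check_simplex(pi: np.ndarray, tol: float = 1e-8) -> None:
    if np.any(pi < -tol) or abs(pi.sum() - 1.0) > tol:
        raise ValueError(f"mixing proportions must lie on the simplex, got {pi}")


def _check_psd(mat: np.ndarray, name: str, tol: float = 1e-10) -> None:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() < -tol * max(1.0, abs(eigvals).max()):
        raise ValueError(f"{name} is not positive semi-definite (eigenvalues {eigvals})")


@dataclass
class GaussianMixtureParams:
    """Bivariate Gaussian mixture: weights ``pi``, means ``mu`` (G x 2),
    covariances ``sigma`` (G x 2 x 2) and the covariance family constraint."""

    pi: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    family: str = "VVV"

    def __post_init__(self) -> None:
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim == 2:
            self.sigma = self.sigma[None, :, :]
        if self.family not in COVARIANCE_FAMILIES:
            raise ValueError(f"unknown covariance family {self.family!r}")
        G = len(self.pi)
        if self.mu.shape != (G, 2) or self.sigma.shape != (G, 2, 2):
            raise ValueError("inconsistent shapes for pi/mu/sigma")
        _check_simplex(self.pi)
        for g in range(G):
            _check_psd(self.sigma[g], f"sigma[{g}]")

    @property
    def G(self) -> int:
        return len(self.pi)

    def to_dict(self) -> dict:
        return {
            "model": "fmm",
            "family": self.family,
            "pi": self.pi.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianMixtureParams":
        return cls(pi=np.array(d["pi"]), mu=np.array(d["mu"]),
                   sigma=np.array(d["sigma"]), family=d.get("family", "VVV"))


@dataclass
class LMMMixtureParams:
    """Mixture of linear mixed models: per component a fixed-effect mean
    ``alpha`` (2-vector), random-effect covariance ``phi`` (2x2, non-diagonal
    allowed) and per-variant measurement-error variances ``sigma2`` (2-vector)."""

    pi: np.ndarray
    alpha: np.ndarray
    phi: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim == 2:
            self.phi = self.phi[None, :, :]
        self.sigma2 = np.atleast_2d(np.asarray(self.sigma2, dtype=float))
        G = len(self.pi)
        if self.alpha.shape != (G, 2) or self.phi.shape != (G, 2, 2) \
                or self.sigma2.shape != (G, 2):
            raise ValueError("inconsistent shapes for pi/alpha/phi/sigma2")
        _check_simplex(self.pi)
        if np.any(self.sigma2 < 0):
            raise ValueError("measurement-error variances must be nonnegative")
        for g in range(G):
            _check_psd(self.phi[g], f"phi[{g}]")

    @property
    def G(self) -> int:
        return len(self.pi)

    def to_dict(self) -> dict:
        return {
            "model": "fmlmm",
            "pi": self.pi.tolist(),
            "alpha": self.alpha.tolist(),
            "phi": self.phi.tolist(),
            "sigma2": self.sigma2.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LMMMixtureParams":
        return cls(pi=np.array(d["pi"]), alpha=np.array(d["alpha"]),
                   phi=np.array(d["phi"]), sigma2=np.array(d["sigma2"]))


def load_params(path: str | Path):
    """Load mixture parameters from a JSON file written by ``to_dict``."""
    d = json.loads(Path(path).read_text())
    if d.get("model") == "fmlmm":
        return LMMMixtureParams.from_dict(d)
    return GaussianMixtureParams.from_dict(d)


def save_params(params, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2))
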