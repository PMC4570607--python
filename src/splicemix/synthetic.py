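"""Synthetic tissue panels with the statistical structure the models assume.

The study's raw per-tissue measurements were never published, so every
downstream stage is exercised on data generated from the published parameter
estimates themselves: bivariate Gaussian mixture draws for the pooled-
replicate model, and random-intercept panels x_i = V(alpha_g + u_ig) + e_ig
for the replicated model.  A CT-table generator additionally emulates the
instrument export consumed by :mod:`splicemix.preprocess`, constructed so
the comparative-CT pipeline inverts it exactly when no CT noise is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ISOFORMS, PAN, TissuePanel
from .params import GaussianMixtureParams, LMMMixtureParams


@dataclass
class SimulationSpec:
    """Declarative description of a simulation run.

    ``renormalize`` projects generated (Ratio1, Ratio2, 1-R1-R2) triples back
    onto the simplex; it is off by default because the fitted models are
    unconstrained Gaussians and can legitimately place mass outside [0, 1].
    """

    model: str  # "fmm" | "fmlmm"
    n_tissues: int
    n_replicates: int
    params: object
    seed: int = 0
    renormalize: bool = False
    missing_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.model not in ("fmm", "fmlmm"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_tissues <= 0 or self.n_replicates < 1:
            raise ValueError("n_tissues must be positive and n_replicates >= 1")


def _simplex_project(points: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip (Ratio1, Ratio2) so that both and their complement lie in
    (0, 1).  The floor keeps every implied quantity strictly positive — a
    qPCR assay never reports an exact zero, only values at the detection
    limit — so renormalized panels remain expressible as CT values."""
    pts = np.clip(points, floor, 1.0 - floor)
    total = pts.sum(axis=-1)
    over = total > 1.0 - floor
    pts[over] *= ((1.0 - floor) / total[over])[..., None]
    return pts


def sample_covariance_sqrt(sigma: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Symmetric square root via eigendecomposition with an eigenvalue floor.

    The published component covariances are nearly singular (|rho| ~ 0.99);
    flooring keeps the sampler valid without visibly changing the draw.
    """
    vals, vecs = np.linalg.eigh(np.asarray(sigma, dtype=float))
    vals = np.maximum(vals, floor)
    return (vecs * np.sqrt(vals)) @ vecs.T


def generate_fmm_points(params: GaussianMixtureParams, n_points: int,
                        seed: int, renormalize: bool = False
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Draw labeled (Ratio1, Ratio2) points from a Gaussian mixture.

    Returns ``(points, labels)`` with labels in ``0..G-1`` for recovery tests.
    """
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    rng = np.random.default_rng(seed)
    labels = rng.choice(params.G, size=n_points, p=params.pi)
    points = np.empty((n_points, 2))
    for g in range(params.G):
        mask = labels == g
        n_g = int(mask.sum())
        if n_g == 0:
            continue
        root = sample_covariance_sqrt(params.sigma[g])
        z = rng.standard_normal((n_g, 2))
        points[mask] = params.mu[g] + z @ root.T
    if renormalize:
        points = _simplex_project(points)
    return points, labels


def generate_fmlmm_panel(params: LMMMixtureParams, n_tissues: int,
                         n_replicates: int, seed: int,
                         missing_rate: float = 0.1,
                         renormalize: bool = False
                         ) -> tuple[TissuePanel, np.ndarray]:
    """Draw a replicated tissue panel from the mixture of linear mixed models.

    For tissue i with component z_i = g the 2R-vector is
    x_i = V(alpha_g + u_ig) + e_ig with u_ig ~ MVN(0, Phi_g) and
    e_ig ~ MVN(0, diag(V sigma2_g)).  ``missing_rate`` masks the third
    replicate of randomly chosen tissues, emulating the duplicates that occur
    when a technical triplicate fails; set 0 for complete panels.

    Returns the panel (as ratios: Ec is derived from the unit constraint)
    and the true component label (0-based) per tissue.
    """
    if n_tissues <= 0 or n_replicates < 1:
        raise ValueError("n_tissues must be positive and n_replicates >= 1")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    R = n_replicates
    labels = rng.choice(params.G, size=n_tissues, p=params.pi)
    ndigits = len(str(n_tissues))
    records = []
    drop = (rng.random(n_tissues) < missing_rate) if R >= 3 else np.zeros(n_tissues, bool)
    for i in range(n_tissues):
        g = labels[i]
        u = sample_covariance_sqrt(params.phi[g]) @ rng.standard_normal(2)
        mean = params.alpha[g] + u  # per-tissue intercept, shared by replicates
        e = rng.standard_normal((R, 2)) * np.sqrt(params.sigma2[g])
        reps = mean[None, :] + e  # rows: replicates, cols: (Ratio1, Ratio2)
        if renormalize:
            reps = _simplex_project(reps)
        tid = f"tissue_{i:0{ndigits}d}"
        keep = R - 1 if drop[i] else R
        for r in range(keep):
            ea, eb = reps[r]
            records.append((tid, r + 1, "Ea", ea))
            records.append((tid, r + 1, "Eb", eb))
            records.append((tid, r + 1, "Ec", 1.0 - ea - eb))
    df = pd.DataFrame(records, columns=["tissue_id", "replicate_id", "isoform", "value"])
    # ratios can stray outside [0,1] under the unconstrained Gaussian model,
    # so the panel is flagged as quantities unless projected
    return TissuePanel(df, is_ratio=bool(renormalize)), labels


CALIBRATOR_ID = "calibrator"


def generate_ct_table(panel: TissuePanel, reference_ct: float = 20.0,
                      calibrator_tissue: str = CALIBRATOR_ID,
                      pan_level: pd.Series | None = None,
                      ct_noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Emit a raw CT table whose comparative-CT processing recovers ``panel``.

    CT values are constructed by inverting 2^(-ddCT): the target CT for
    quantity q is reference_ct - log2(q).  A dedicated synthetic calibrator
    sample with unit quantity in every assay is appended (a real panel tissue
    cannot serve, because relative quantities against a tissue-specific
    calibrator would distort the compositional ratios).  ``pan_level``
    optionally overrides the PAN quantity per (tissue, replicate); by default
    PAN equals the isoform sum, so the PAN-consistency check passes.
    """
    wide = panel.ratio_wide()
    vals = wide[list(ISOFORMS)].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("panel values must be strictly positive to emit CT values")
    rng = np.random.default_rng(seed)
    records = []
    for row_idx, row in wide.iterrows():
        tid, rid = row["tissue_id"], int(row["replicate_id"])
        quantities = {iso: float(row[iso]) for iso in ISOFORMS}
        if pan_level is not None:
            quantities[PAN] = float(pan_level.loc[(tid, rid)]
                                    if isinstance(pan_level.index, pd.MultiIndex)
                                    else pan_level.loc[tid])
        else:
            quantities[PAN] = sum(quantities[iso] for iso in ISOFORMS)
        for assay, q in quantities.items():
            ct = reference_ct - np.log2(q)
            records.append((tid, rid, assay, ct))
        records.append((tid, rid, "reference", reference_ct))
    # the synthetic calibrator: unit quantity in every assay
    for assay in ISOFORMS + (PAN, "reference"):
        records.append((calibrator_tissue, 1, assay, reference_ct))
        records.append((calibrator_tissue, 2, assay, reference_ct))
    ct = pd.DataFrame(records, columns=["tissue_id", "replicate_id", "assay", "ct"])
    if ct_noise_sd > 0:
        ct["ct"] = ct["ct"] + rng.normal(0.0, ct_noise_sd, size=len(ct))
    return ct


def simulate(spec: SimulationSpec):
    """Run a :class:`SimulationSpec`; returns (panel, labels_per_tissue)."""
    if spec.model == "fmm":
        n_points = spec.n_tissues * spec.n_replicates
        points, point_labels = generate_fmm_points(
            spec.params, n_points, spec.seed, renormalize=spec.renormalize)
        ndigits = len(str(spec.n_tissues))
        recs = []
        for idx in range(n_points):
            tid = f"tissue_{idx // spec.n_replicates:0{ndigits}d}"
            rid = idx % spec.n_replicates + 1
            ea, eb = points[idx]
            recs.append((tid, rid, "Ea", ea))
            recs.append((tid, rid, "Eb", eb))
            recs.append((tid, rid, "Ec", 1.0 - ea - eb))
        df = pd.DataFrame(recs, columns=["tissue_id", "replicate_id", "isoform", "value"])
        return TissuePanel(df, is_ratio=spec.renormalize), point_labels
    return generate_fmlmm_panel(spec.params, spec.n_tissues, spec.n_replicates,
                                spec.seed, missing_rate=spec.missing_rate,
                                renormalize=spec.renormalize)
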