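"""Comparative-CT quantification and compositional equalization.

Raw qPCR cycle-threshold (CT) tables are turned into relative quantities via
2^(-ddCT) against a reference gene and a calibrator sample, then equalized
to compositional ratios Ratio_k = q_k / (q_Ea + q_Eb + q_Ec), which sum to
one per replicate.  A PAN-consistency check verifies that the pan-isoform
assay agrees with the sum of the three variant-specific assays.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ISOFORMS, PAN, TissuePanel


def comparative_ct_quantity(ct_target: float, ct_reference: float,
                            ct_target_calibrator: float,
                            ct_reference_calibrator: float) -> float:
    """Relative quantity 2^(-ddCT) of a target against reference + calibrator."""
    cts = np.asarray([ct_target, ct_reference, ct_target_calibrator,
                      ct_reference_calibrator], dtype=float)
    if not np.all(np.isfinite(cts)):
        raise ValueError("CT values must be finite")
    ddct = (ct_target - ct_reference) - (ct_target_calibrator - ct_reference_calibrator)
    return float(2.0 ** (-ddct))


def compositional_ratios(ea: float, eb: float, ec: float) -> tuple[float, float, float]:
    """Equalize three nonnegative quantities to ratios summing to one."""
    q = np.asarray([ea, eb, ec], dtype=float)
    if (q < 0).any():
        raise ValueError("quantities must be nonnegative")
    total = q.sum()
    if total <= 0:
        raise ValueError("at least one quantity must be positive")
    r = q / total
    return float(r[0]), float(r[1]), float(r[2])


def ct_to_quantities(ct: pd.DataFrame, calibrator: str,
                     reference_assay: str = "reference") -> TissuePanel:
    """Apply the comparative-CT method to a long CT table.

    ``ct`` has columns tissue_id, replicate_id, assay, ct.  The calibrator's
    delta-CT per assay is the mean over its replicates.  Returns a quantity
    panel (the calibrator sample itself is dropped: its quantities are 1 by
    construction and it is not a tissue).
    """
    required = {"tissue_id", "replicate_id", "assay", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"CT table needs columns {sorted(required)}")
    if not np.isfinite(ct["ct"]).all():
        raise ValueError("CT values must be finite")
    wide = ct.pivot_table(index=["tissue_id", "replicate_id"], columns="assay",
                          values="ct", aggfunc="first")
    if reference_assay not in wide.columns:
        raise ValueError(f"reference assay {reference_assay!r} missing from CT table")
    if wide[reference_assay].isna().any():
        raise ValueError("reference assay must be present for every (tissue, replicate)")
    assays = [c for c in wide.columns if c != reference_assay]
    dct = wide[assays].sub(wide[reference_assay], axis=0)
    cal = dct.loc[calibrator]
    if isinstance(cal, pd.DataFrame):
        cal = cal.mean(axis=0)
    ddct = dct.sub(cal, axis=1)
    quantities = 2.0 ** (-ddct)
    quantities = quantities.drop(index=calibrator, level="tissue_id")
    long = (quantities.reset_index()
            .melt(id_vars=["tissue_id", "replicate_id"],
                  var_name="isoform", value_name="value")
            .dropna(subset=["value"]))
    return TissuePanel(long, is_ratio=False)


def equalize(panel: TissuePanel) -> TissuePanel:
    """Per-replicate compositional ratios from a quantity panel.

    Ratios are computed replicate by replicate, never on replicate means:
    the pooled-replicate mixture treats each technical replicate as a unit.
    """
    wide = panel.ratio_wide()
    vals = wide[list(ISOFORMS)].to_numpy(dtype=float)
    totals = vals.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("each replicate needs a positive isoform total")
    wide[list(ISOFORMS)] = vals / totals
    # unconstrained synthetic panels can carry values slightly outside
    # [0, 1]; such rows normalize but cannot be flagged as strict ratios
    in_simplex = bool((vals >= 0).all())
    return TissuePanel.from_wide(wide, is_ratio=in_simplex)


class PanTestResult(NamedTuple):
    statistic: float
    pvalue: float
    reject: bool
    n: int


def pan_consistency_test(panel: TissuePanel, alpha: float = 0.05) -> PanTestResult:
    """Paired t-test of log(PAN) against log(Ea + Eb + Ec) across replicates.

    qPCR error is multiplicative, hence the log scale.  Failing to reject
    supports the unit constraint: the pan-isoform assay measures the same
    pool as the summed variant assays.
    """
    df = panel.df
    if PAN not in set(df["isoform"]):
        raise ValueError("panel has no PAN measurements")
    wide = df.pivot_table(index=["tissue_id", "replicate_id"], columns="isoform",
                          values="value", aggfunc="first").dropna()
    if len(wide) < 2:
        raise ValueError("need at least two complete replicates for the PAN test")
    log_pan = np.log(wide[PAN].to_numpy(dtype=float))
    log_sum = np.log(wide[list(ISOFORMS)].sum(axis=1).to_numpy(dtype=float))
    diff = log_pan - log_sum
    if np.allclose(diff, 0.0, atol=1e-12) or np.std(diff, ddof=1) == 0.0:
        # identical series: no evidence against the constraint
        return PanTestResult(0.0, 1.0, False, len(diff))
    stat, p = stats.ttest_rel(log_pan, log_sum)
    return PanTestResult(float(stat), float(p), bool(p < alpha), len(diff))


def summary_statistics(values) -> dict[str, float]:
    """Six-number summary (min, q1, median, mean, q3, max).

    Quartiles use linear interpolation between order statistics (type-7),
    the convention of the published descriptive tables.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return {"min": float(x.min()), "q1": float(q1), "median": float(med),
            "mean": float(x.mean()), "q3": float(q3), "max": float(x.max())}


def summarize_panel(panel: TissuePanel) -> pd.DataFrame:
    """Six-number summary per isoform ratio across pooled replicates."""
    if not panel.is_ratio:
        panel = equalize(panel)
    wide = panel.ratio_wide()
    rows = {iso: summary_statistics(wide[iso]) for iso in ISOFORMS}
    return pd.DataFrame(rows).T
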