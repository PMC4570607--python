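"""Long-format container for tissue x isoform x replicate qPCR measurements.

A :class:`TissuePanel` wraps a tidy :class:`pandas.DataFrame` with columns
``tissue_id, replicate_id, isoform, value``.  Values are either relative
quantities (comparative-CT output) or compositional ratios; the ``is_ratio``
flag records which.  Tissues may carry 2 or 3 technical replicates —
duplicates happen when a triplicate fails on the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ISOFORMS = ("Ea", "Eb", "Ec")
PAN = "PAN"

_COLUMNS = ["tissue_id", "replicate_id", "isoform", "value"]


@dataclass
class TissuePanel:
    df: pd.DataFrame
    is_ratio: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"panel is missing columns {missing}")
        self.df = self.df[_COLUMNS].copy()
        if self.df["value"].isna().any():
            raise ValueError("panel contains missing values")
        # quantity panels may carry small negative values when they hold
        # unconstrained Gaussian simulations; CT emission re-checks positivity
        counts = (self.df[self.df["isoform"].isin(ISOFORMS)]
                  .groupby(["tissue_id", "isoform"])["replicate_id"].nunique())
        if len(counts) and not counts.isin([2, 3]).all():
            bad = counts[~counts.isin([2, 3])]
            raise ValueError(f"replicate count per (tissue, isoform) must be 2 or 3:\n{bad}")
        if self.is_ratio:
            self._validate_ratios()

    def _validate_ratios(self, tol: float = 1e-9) -> None:
        wide = self.ratio_wide()
        vals = wide[list(ISOFORMS)].to_numpy()
        if (vals < -tol).any() or (vals > 1 + tol).any():
            raise ValueError("ratios must lie in [0, 1]")
        sums = vals.sum(axis=1)
        if np.abs(sums - 1.0).max() > tol:
            raise ValueError("per-replicate ratios must sum to 1")

    # ---------------------------------------------------------------- views

    def ratio_wide(self) -> pd.DataFrame:
        """One row per (tissue, replicate), one column per isoform."""
        sub = self.df[self.df["isoform"].isin(ISOFORMS)]
        wide = sub.pivot_table(index=["tissue_id", "replicate_id"],
                               columns="isoform", values="value",
                               aggfunc="first").reset_index()
        wide.columns.name = None
        if wide[list(ISOFORMS)].isna().any().any():
            raise ValueError("every replicate needs all three isoform values")
        return wide

    def points(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Pooled replicate units as an (n, 2) array of (Ratio1, Ratio2)
        plus the matching (tissue_id, replicate_id) index frame."""
        wide = self.ratio_wide()
        pts = wide[["Ea", "Eb"]].to_numpy(dtype=float)
        return pts, wide[["tissue_id", "replicate_id"]]

    def tissue_vectors(self) -> tuple[list[str], list[np.ndarray]]:
        """Per-tissue stacked vectors (R values of Ratio1 then R of Ratio2).

        Returns tissue ids and the list of 2R_i vectors; R_i may differ
        across tissues (duplicates vs triplicates)."""
        wide = self.ratio_wide().sort_values(["tissue_id", "replicate_id"])
        ids, vectors = [], []
        for tid, grp in wide.groupby("tissue_id", sort=True):
            ids.append(tid)
            vectors.append(np.concatenate([grp["Ea"].to_numpy(dtype=float),
                                           grp["Eb"].to_numpy(dtype=float)]))
        return ids, vectors

    def tissue_ids(self) -> list[str]:
        return sorted(self.df["tissue_id"].unique())

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, is_ratio: bool = False) -> "TissuePanel":
        return cls(pd.read_csv(path), is_ratio=is_ratio)

    @classmethod
    def from_wide(cls, wide: pd.DataFrame, is_ratio: bool = False) -> "TissuePanel":
        """Build from one-row-per-replicate data with isoform columns."""
        long = wide.melt(id_vars=["tissue_id", "replicate_id"],
                         value_vars=[c for c in wide.columns if c in ISOFORMS + (PAN,)],
                         var_name="isoform", value_name="value")
        return cls(long, is_ratio=is_ratio)
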