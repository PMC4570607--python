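#!/usr/bin/env python
"""Kernel density exploration of the per-isoform ratio distributions.

Estimates each ratio's density across the pooled replicate units of the
200-tissue panel under all four bandwidth rules, and counts modes: the
multimodality that motivates the formal mixture clustering.
"""

from pathlib import Path

import pandas as pd

from splicemix import density
from splicemix.panel import ISOFORMS, TissuePanel

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = TissuePanel.from_csv(OUT / "fmlmm_panel.csv")
    wide = panel.ratio_wide()
    rows = []
    for iso in ISOFORMS:
        x = wide[iso].to_numpy()
        for rule in ("scott", "silverman", "ucv", "sheather_jones"):
            grid, dens, h = density.kde(x, density.KdeSpec(bandwidth_rule=rule))
            modes = density.count_modes(dens, min_prominence=0.01 * dens.max())
            rows.append({"isoform": iso, "rule": rule, "h": h, "modes": modes})
            pd.DataFrame({"x": grid, "density": dens}).to_csv(
                OUT / f"density_{iso}_{rule}.csv", index=False)
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "density_bandwidths.csv", index=False)
    print("bandwidths and mode counts (Gaussian kernel):")
    print(table.round(4).to_string(index=False))
    multi = table[table["isoform"].isin(["Ea", "Eb"])]["modes"].min()
    print(f"\nevery Ratio-1/Ratio-2 estimate shows >= {multi} modes: "
          "the panel is not a single homogeneous population")


if __name__ == "__main__":
    main()
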