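#!/usr/bin/env python
"""Comparative-CT quantification, equalization and the PAN check.

Processes the emulated 20-tissue CT export: relative quantities by
2^(-ddCT) against the synthetic calibrator, a paired log-scale t-test of
the pan-isoform assay against the summed variant assays, compositional
ratios, and a six-number summary per isoform.
"""

from pathlib import Path

import pandas as pd

from splicemix import preprocess, synthetic

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ct = pd.read_csv(OUT / "ct_table.csv")
    quantities = preprocess.ct_to_quantities(ct, calibrator=synthetic.CALIBRATOR_ID)

    pan = preprocess.pan_consistency_test(quantities)
    verdict = "reject" if pan.reject else "fail to reject"
    print(f"PAN consistency (n={pan.n} replicates): "
          f"t = {pan.statistic:.3f}, p = {pan.pvalue:.3f} -> {verdict} "
          f"[PAN] = [Ea]+[Eb]+[Ec]")

    ratios = preprocess.equalize(quantities)
    ratios.to_csv(OUT / "small_panel_ratios.csv")

    summary = preprocess.summarize_panel(ratios).round(4)
    summary.to_csv(OUT / "ratio_summary.csv")
    print("six-number summary of the compositional ratios:")
    print(summary.to_string())

    # the same pipeline on a noisy export: ratios survive CT noise well
    noisy = preprocess.equalize(preprocess.ct_to_quantities(
        pd.read_csv(OUT / "ct_table_noisy.csv"),
        calibrator=synthetic.CALIBRATOR_ID))
    merged = ratios.ratio_wide().merge(noisy.ratio_wide(),
                                       on=["tissue_id", "replicate_id"],
                                       suffixes=("", "_noisy"))
    import numpy as np
    r = np.corrcoef(merged["Ea"], merged["Ea_noisy"])[0, 1]
    print(f"\nwith CT noise sd = 0.1 cycles, recovered Ratio-1 correlates "
          f"r = {r:.3f} with the noiseless values")


if __name__ == "__main__":
    main()
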