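#!/usr/bin/env python
"""Generate the study-condition panels.

The original 20-tissue qPCR measurements were never deposited, so the whole
analysis runs on synthetic panels drawn from the published mixture
estimates: a pooled-replicate Gaussian mixture sample, a replicated
mixture-of-LMMs panel, and a small 20-tissue panel with an emulated raw CT
export for the preprocessing stage.
"""

from pathlib import Path

import pandas as pd

from splicemix import reference, synthetic
from splicemix.params import save_params

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20150915  # fixed once for the whole analysis


def main() -> None:
    OUT.mkdir(exist_ok=True)

    # pooled-replicate sample at the Gaussian-mixture study conditions
    pts, labels = synthetic.generate_fmm_points(reference.FMM_ESTIMATE, 1000,
                                                seed=SEED)
    pd.DataFrame({"ratio1": pts[:, 0], "ratio2": pts[:, 1],
                  "true_component": labels + 1}
                 ).to_csv(OUT / "fmm_points.csv", index=False)
    save_params(reference.FMM_ESTIMATE, OUT / "fmm_generating_params.json")

    # replicated panel at the mixture-of-LMMs study conditions
    panel, tissue_labels = synthetic.generate_fmlmm_panel(
        reference.FMLMM_ESTIMATE, 200, 3, seed=SEED, missing_rate=0.0)
    panel.to_csv(OUT / "fmlmm_panel.csv")
    pd.DataFrame({"tissue_id": panel.tissue_ids(),
                  "true_component": tissue_labels + 1}
                 ).to_csv(OUT / "fmlmm_labels.csv", index=False)
    save_params(reference.FMLMM_ESTIMATE, OUT / "fmlmm_generating_params.json")

    # a 20-tissue panel with duplicates plus its emulated instrument export
    small, _ = synthetic.generate_fmlmm_panel(reference.FMLMM_ESTIMATE, 20, 3,
                                              seed=SEED + 1, missing_rate=0.1,
                                              renormalize=True)
    small.to_csv(OUT / "small_panel.csv")
    # noiseless export: exact round trip, PAN consistent by construction
    synthetic.generate_ct_table(small, seed=SEED + 2).to_csv(
        OUT / "ct_table.csv", index=False)
    # noisy export for the recovery-under-noise demonstration
    synthetic.generate_ct_table(small, ct_noise_sd=0.1, seed=SEED + 2).to_csv(
        OUT / "ct_table_noisy.csv", index=False)

    print(f"wrote {len(pts)} mixture points, a 200-tissue replicated panel "
          f"and a 20-tissue CT export to {OUT}")


if __name__ == "__main__":
    main()
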