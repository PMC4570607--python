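"""Cross-method comparison and pipeline orchestration.

Confusion matrices compare the tissue-level clusterings from the two models;
component labels are arbitrary per fit, so an exhaustive mean-matching
alignment is provided.  ``run_pipeline`` wires the stages together from a
configuration mapping.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import density, fmlmm, fmm, preprocess, synthetic
from .panel import ISOFORMS, TissuePanel
from .params import save_params

log = logging.getLogger(__name__)


def confusion_matrix(alloc_a: pd.Series, alloc_b: pd.Series,
                     name_a: str = "A", name_b: str = "B") -> pd.DataFrame:
    """Tissue counts of method-a labels (rows) by method-b labels (columns),
    with margins.  Both allocations are Series indexed by tissue id."""
    alloc_a, alloc_b = pd.Series(alloc_a), pd.Series(alloc_b)
    only_a = set(alloc_a.index) - set(alloc_b.index)
    only_b = set(alloc_b.index) - set(alloc_a.index)
    if only_a or only_b:
        raise ValueError(f"tissue sets differ: only in {name_a}: {sorted(only_a)}; "
                         f"only in {name_b}: {sorted(only_b)}")
    table = pd.crosstab(alloc_a, alloc_b, margins=True, margins_name="Total")
    table.index.name = name_a
    table.columns.name = name_b
    return table


def align_components(means_a: np.ndarray, means_b: np.ndarray) -> tuple[int, ...]:
    """Permutation p minimizing total distance between matched component
    means: component g of a is matched to component p[g] of b.  Exhaustive
    over G! (G <= 5)."""
    means_a = np.atleast_2d(means_a)
    means_b = np.atleast_2d(means_b)
    G = means_a.shape[0]
    if means_b.shape[0] != G:
        raise ValueError("component counts differ")
    if G > 5:
        raise ValueError("exhaustive matching supports G <= 5")
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(G)):
        cost = sum(np.linalg.norm(means_a[g] - means_b[perm[g]]) for g in range(G))
        if cost < best_cost:
            best, best_cost = perm, cost
    return best


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages (simulate, preprocess, kde, fit_fmm,
    fit_fmlmm, compare) and write their artifacts under ``out_dir``.

    Returns a bundle of in-memory results; a JSON run log with seeds and
    per-stage timings is written alongside the artifacts.  Any stage failure
    aborts with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ["simulate", "fit_fmm", "fit_fmlmm", "compare"])
    bundle: dict = {}
    runlog = {"seed": seed, "stages": {}, "numpy": np.__version__}

    def _stage(name):
        if name not in stages:
            return False
        runlog["stages"][name] = {"started": time.time()}
        return True

    try:
        if _stage("simulate"):
            sim = config["simulate"]
            spec = synthetic.SimulationSpec(
                model=sim.get("model", "fmlmm"),
                n_tissues=int(sim["n_tissues"]),
                n_replicates=int(sim.get("n_replicates", 3)),
                params=sim["params"], seed=seed,
                renormalize=bool(sim.get("renormalize", False)),
                missing_rate=float(sim.get("missing_rate", 0.1)))
            panel, labels = synthetic.simulate(spec)
            panel.to_csv(out / "panel.csv")
            pd.DataFrame({"tissue_id": panel.tissue_ids() if spec.model == "fmlmm"
                          else range(len(labels)),
                          "true_component": np.asarray(labels) + 1}
                         ).to_csv(out / "labels.csv", index=False)
            save_params(sim["params"], out / "generating_params.json")
            bundle["panel"], bundle["labels"] = panel, labels
        elif "input" in config:
            bundle["panel"] = TissuePanel.from_csv(
                config["input"], is_ratio=bool(config.get("is_ratio", False)))

        panel = bundle.get("panel")
        if _stage("preprocess") and panel is not None and not panel.is_ratio:
            panel = preprocess.equalize(panel)
            panel.to_csv(out / "ratios.csv")
            bundle["panel"] = panel

        if _stage("kde"):
            ratios = panel if panel.is_ratio else preprocess.equalize(panel)
            wide = ratios.ratio_wide()
            kde_cfg = config.get("kde", {})
            rule = kde_cfg.get("rule", "silverman")
            for iso in ISOFORMS:
                grid, dens, h = density.kde(
                    wide[iso].to_numpy(),
                    density.KdeSpec(kernel=kde_cfg.get("kernel", "gaussian"),
                                    bandwidth_rule=rule))
                pd.DataFrame({"x": grid, "density": dens}).to_csv(
                    out / f"density_{iso}.csv", index=False)

        if _stage("fit_fmm"):
            cfg = config.get("fmm", {})
            pts, idx = panel.points()
            fit, table = fmm.select_model(
                pts, G_range=range(int(cfg.get("gmin", 1)), int(cfg.get("gmax", 6)) + 1),
                families=tuple(cfg.get("families", ["EEV", "VVV", "EEE", "VII", "EII"])),
                seed=seed, tol=float(cfg.get("tol", 1e-8)),
                n_starts=int(cfg.get("starts", 20)))
            alloc = fmm.map_allocate(fit.weights, idx)
            summary = fmm.tissue_summary(alloc, fit.params.G)
            table.to_csv(out / "fmm_bic.csv", index=False)
            alloc.to_csv(out / "fmm_allocation.csv", index=False)
            summary.to_csv(out / "fmm_tissue_summary.csv", index=False)
            save_params(fit.params, out / "fmm_params.json")
            bundle["fmm_fit"], bundle["fmm_summary"] = fit, summary

        if _stage("fit_fmlmm"):
            cfg = config.get("fmlmm", {})
            fit, table = fmlmm.fmlmm_select(
                panel, G_list=tuple(cfg.get("g_list", [2, 3])), seed=seed,
                tol=float(cfg.get("tol", 1e-8)),
                n_starts=int(cfg.get("starts", 10)),
                alpha_update=cfg.get("alpha_update", "printed"))
            alloc = fit.allocation()
            table.to_csv(out / "fmlmm_bic.csv", index=False)
            alloc.to_csv(out / "fmlmm_allocation.csv", index=False)
            save_params(fit.params, out / "fmlmm_params.json")
            blups = pd.DataFrame(
                [[tid, *fmlmm.blup(x, fit.params, int(c) - 1)]
                 for tid, x, c in zip(fit.tissue_ids, panel.tissue_vectors()[1],
                                      alloc["component"])],
                columns=["tissue_id", "blup_ratio1", "blup_ratio2"])
            blups.to_csv(out / "fmlmm_blup.csv", index=False)
            bundle["fmlmm_fit"], bundle["fmlmm_alloc"] = fit, alloc

        if _stage("compare"):
            a = bundle["fmm_summary"].set_index("tissue_id")["component"]
            b = bundle["fmlmm_alloc"].set_index("tissue_id")["component"]
            cm = confusion_matrix(a, b, "FMM", "FMLMM")
            cm.to_csv(out / "confusion_matrix.csv")
            bundle["confusion"] = cm
    except Exception as err:
        stage = next((s for s, v in reversed(runlog["stages"].items())
                      if "elapsed" not in v), "?")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        for name, rec in runlog["stages"].items():
            rec["elapsed"] = time.time() - rec.pop("started")
        (out / "run_log.json").write_text(json.dumps(runlog, indent=2))
    return bundle
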