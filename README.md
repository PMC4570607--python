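# splicemix

Model-based clustering of tissues by the relative abundance of co-expressed
splice-variant mRNAs, with quantitative real-time PCR (qPCR) data in mind.

## The problem

A single gene can be spliced into several mRNA isoforms, and different
tissues favour different isoforms.  The motivating case is human IGF-1,
whose 3'-end splicing yields the variants Ea, Eb and Ec.  Given a panel of
tissues measured by qPCR (with 2–3 technical replicates per tissue and
isoform), the question is whether the tissues fall into subpopulations with
homogeneous isoform balance — and how to answer it with a formal
probability model rather than by eyeballing expression levels.

Because comparative-CT quantities are only relative, the measurements are
first *equalized* to compositional ratios

    Ratio_k = [E_k] / ([Ea] + [Eb] + [Ec]),   k = a, b, c,

which sum to one in every replicate; the models are then fitted to the
pair (Ratio1, Ratio2), the third ratio being implied.

## The models

**FMM — finite mixture of bivariate Gaussians.**  Every tissue replicate is
treated as an independent unit with density

    f(x) = Σ_g π_g N(x | μ_g, Σ_g),

fitted by EM with short classification-EM (CEM) initialization.  The
component covariances can be constrained through the eigendecomposition
Σ_g = λ_g D_g A_g D_g' (scale / shape / orientation); the families
EII, VII, EEE, VVV and EEV are implemented.  The number of components and
family are chosen by minimizing BIC = −2·loglik + k·log(nR).

**FMLMM — finite mixture of linear mixed models.**  Technical replicates of
one tissue are not independent.  Stacking the R replicates of both ratios
into x_i ∈ R^{2R}, each tissue follows, conditional on its component,

    x_i = V(α_g + u_ig) + e_ig,     V = [[1_R, 0], [0, 1_R]],

with a tissue-level random effect u_ig ~ MVN(0, Φ_g) (non-diagonal, since
the two ratios trade off on the simplex) and measurement error
e_ig ~ MVN(0, diag(Vσ²_g)) with per-variant variances.  All replicates of a
tissue share one component; EM treats both the labels and the random
effects as missing data.  BIC uses the number of tissues as sample size.

Both models report maximum-a-posteriori (MAP) allocations with a
normalized Shannon entropy (0 = certain, 1 = maximally uncertain), and a
confusion matrix compares the two clusterings tissue by tissue.

The original tissue measurements were never deposited, so the package
ships a synthetic-data module that draws panels from the published
parameter estimates (`splicemix.reference`), making every stage testable.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on synthetic
panels and write their tables under `results/`:

```sh
python analysis/01_simulate.py      # panels from the reference estimates
python analysis/02_preprocess.py    # ddCT -> ratios, PAN check, summaries
python analysis/03_density.py       # KDE, four bandwidth rules, mode counts
python analysis/04_fit_fmm.py       # Gaussian mixture + BIC selection
python analysis/05_fit_fmlmm.py     # mixture of LMMs + BIC selection
python analysis/06_compare.py       # cross-method confusion matrix
```

`04_fit_fmm.py` prints, for 1000 points drawn from the three-component
reference mixture:

```
within the EEV family, BIC selects G = 3 (BIC = -8853.1)
component recovery (aligned by nearest means):
 generating_mu1  fitted_mu1  generating_pi  fitted_pi
         0.8420      0.8450         0.6832     0.7008
         0.8443      0.8366         0.2262     0.2179
         0.6772      0.6712         0.0906     0.0813
```

i.e. model selection recovers the generating number of clusters, and the
isolated low-Ratio1 component (high relative Eb) comes back at its
generating mean.  `05_fit_fmlmm.py` does the same for the replicated model
(BIC −5702.1 for G = 3 vs −5592.4 for G = 2, smallest intercept fitted at
0.6751 vs 0.6742 generating), and `06_compare.py` tabulates the published
20-tissue allocations into the cross-method confusion matrix with margins
(14, 4, 2) by (6, 12, 2).

The same functionality is exposed as a CLI:

```sh
splicemix simulate --model fmlmm --params params.json \
    --n-tissues 200 --replicates 3 --seed 1 --out sim/
splicemix fit-fmlmm --input sim/panel.csv --g 2,3 --seed 1 --out fit/
```

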