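# Methods

This note records the statistical models, the numerical choices and the
design decisions behind `splicemix`, and what the synthetic-data tests do
and do not demonstrate about real qPCR panels.

## Data model and equalization

The unit of observation is a tissue × isoform × technical-replicate
measurement.  Raw comparative-CT data are converted to relative quantities
by 2^(−ΔΔCT), where ΔΔCT subtracts a reference-gene ΔCT and a calibrator
sample's ΔCT.  The calibrator is a required user input: relative
quantities are meaningless without one, and no default could be right.
Quantities are then equalized per replicate to compositional ratios
Ratio_k = q_k / Σ q_k.  Ratios are computed replicate by replicate, never
on replicate means, because the pooled-replicate mixture treats each
replicate as a unit; the equalization deliberately discards the original
expression magnitudes, which is the price of comparability across tissues.

The PAN-consistency check tests whether the pan-isoform assay measures the
same pool as the summed variant assays.  It is implemented as a paired
two-sided t-test of log(PAN) against log(Ea+Eb+Ec) across replicates
(α = 0.05); the log scale reflects the multiplicative error structure of
qPCR.  The exact test used in the original study was never specified, so
this is a documented stand-in with the same null hypothesis.  One caveat
discovered while exercising it on noisy synthetic exports: calibrator CT
noise induces a *systematic* per-assay offset shared by all tissues, which
a paired test detects with high power at moderate n.  A rejection can
therefore indicate a noisy calibrator rather than a defective assay.

Six-number summaries use type-7 (linear-interpolation) quantiles, the
default convention of the common statistical environments.

## Kernel density estimation

The per-isoform ratio distributions are summarized by the standard
estimator f̂_h(x) = (1/nh) Σ_i K((x−x_i)/h) with Gaussian (default) or
Epanechnikov kernels.  Four bandwidth selectors are provided:

* **silverman** — 0.9 · min(sd, IQR/1.34) · n^(−1/5);
* **scott** — the same robust spread with the 1.06 normal-reference
  constant (the convention of the common `bw.nrd`-style implementations;
  Scott's original writing uses a slightly different constant — the 1.06
  variant is what the motivating analysis used);
* **ucv** — least-squares (unbiased) cross-validation, minimized on log h
  over [10⁻³·range, range] by bounded scalar minimization (≤ 200
  evaluations), with the closed-form Gaussian-kernel criterion and a
  numerical criterion for the Epanechnikov kernel;
* **sheather_jones** — the solve-the-equation plug-in with normal-scale
  pilot bandwidths (0.920·λ·n^(−1/7), 0.912·λ·n^(−1/9)) solved by Brent
  bracketing in [h_silverman/20, 20·h_silverman]; failure to bracket falls
  back to the Silverman rule with a logged warning.

Density grids default to 512 equally spaced points over
[min − 3h, max + 3h].  Replicates are pooled by default (consistent with
the pooled mixture); a per-tissue-mean option exists because the original
analysis does not state which convention its density figures used.  Mode
counting takes strict local maxima exceeding neighbouring minima by a
prominence threshold (default 0, via peak finding on the grid).

## Pooled-replicate Gaussian mixture (FMM)

With replicates pooled as independent units, the observed-data
log-likelihood is Σ_{i,r} log Σ_g π_g N(x_ir | μ_g, Σ_g), evaluated in
log-space with log-sum-exp.  The M-step uses the standard weighted moments
(mean, and covariance with denominator equal to the component mass), then
projects the covariance set onto the requested family:

* VVV — unconstrained; EEE — pooled; EII/VII — spherical with shared or
  per-component volume;
* EEV — per-component scatter matrices are eigendecomposed; orientations
  are kept, eigenvalues are pooled across components into a shared shape
  (det = 1) and volume.  This closed-form constrained update is applied
  once per EM cycle.

Free-parameter counts for BIC (d = 2): G·d means + (G−1) proportions +
{EII: 1, VII: G, EEE: 3, VVV: 3G, EEV: 2 + G}.  BIC = −2·loglik + k·log n
with n the number of pooled replicate units (nR), matching the pooled
likelihood; BIC is *minimized*.  (Some packages maximize the negated
form; the sign convention here follows "lowest BIC wins".)

Initialization runs 20 random starts of a 10-iteration classification-EM
(hard assignment between E and M steps), keeping the start with the best
complete-data log-likelihood; start counts are exposed as options.  On
component collapse (mass < 1e-10) the fit restarts from a fresh CEM stream
up to 3 times.  Covariance eigenvalues are floored at 1e-10 × trace —
necessary because the reference components have |ρ| ≈ 0.99 and are nearly
singular.  MAP ties and majority-vote ties break to the lowest component
index and are logged.  For reporting, components keep their fitted order;
cross-fit comparisons align components by exhaustive nearest-mean matching.

## Mixture of linear mixed models (FMLMM)

Conditional on component g, a tissue's stacked 2R-vector is
x_i = V(α_g + u_ig) + e_ig with u_ig ~ MVN(0, Φ_g),
e_ig ~ MVN(0, Ω_g), Ω_g = diag(Vσ²_g), so marginally
x_i | g ~ MVN(Vα_g, VΦ_gV' + Ω_g).  Φ_g is deliberately non-diagonal
(the two ratios are negatively coupled through the unit constraint) and
σ²_g is per-variant.

The E-step computes tissue-level posterior weights from the marginal
densities.  The M-step uses the conditional-expectation closed forms,
which constitute a coordinate ascent on the EM Q-function and therefore
keep the marginal log-likelihood non-decreasing:

* π_g — weighted average of memberships;
* α_g — incremental update α_g + (V'Ω⁻¹V)⁻¹V'Σ⁻¹·(weighted mean
  residual).  Algebraically this *is* the exact conditional-expectation
  update given E[u|x]; a closed-form weighted-GLS solve
  (V'Σ⁻¹V)⁻¹V'Σ⁻¹x̄_w is available behind `alpha_update="gls"`;
* σ²_gh — Σ_i w_ig(‖ê_igh‖² + tr_h(Ω−ΩΣ⁻¹Ω)) / (R Σ_i w_ig), where
  ê_ig = ΩΣ⁻¹(x_i − Vα_g) is the conditional error mean and the trace is
  restricted to variant h's R diagonal entries.  The identity
  Ω − ΩΣ⁻¹Ω = V·cov(u|x)·V' makes this the exact conditional second
  moment;
* Φ_g — weighted average of E[u_ig u_ig' | x] = û_ig û_ig' + cov(u|x)
  with û_ig = ΦV'Σ⁻¹(x_i − Vα_g), symmetrized and projected onto the PSD
  cone (eigenvalue floor, logged) if needed.

Inside the M-step the conditional moments are taken *given* component
membership; the public `blup` predictor additionally multiplies by the
membership probability w_ig, the form used for reporting random-effect
predictions.  Marginal covariances are inverted by eigendecomposition with
a relative floor of 1e-12 × trace.

Tissues with unequal replicate counts (duplicates where a triplicate
failed) get per-tissue design matrices and error covariances — a strict
generalization of the fixed-R model, since nothing in the equations
requires a common R.

Initialization fits the pooled Gaussian mixture (VVV) on replicate points,
aggregates replicate labels to tissues by majority, and seeds (α, Φ, σ²)
from the per-component tissue moments; subsequent starts (default 10)
jitter the fixed effects with sd 0.02, the scale of the between-component
mean gaps.  BIC = −2·marginal loglik + k·log(n_tissues) with
k = 7G + (G−1) (per component: 2 fixed effects, 3 random-effect
covariance entries, 2 error variances).  The per-tissue entropy uses the
same normalization (÷ log G) as the pooled model.

## Synthetic panels

The generator draws exactly from the models above, by default at the
published reference estimates: three components with means on the unit
simplex, strongly negatively correlated near-singular covariances
(sampled via eigendecomposition with a 1e-12 eigenvalue floor), and small
per-variant error variances.  Ratio3 is derived as 1 − Ratio1 − Ratio2.
Missing replicates are emulated by masking the third replicate of randomly
chosen tissues (default rate 0.1; protocols that state complete
triplicates pass 0).  Because the fitted models are unconstrained
Gaussians, generated values may stray slightly outside [0, 1]; generation
does not clamp by default, and an optional simplex projection (with a
1e-6 detection-limit floor so every implied quantity stays positive) is
available for realism studies.  The CT-table generator inverts the
comparative-CT arithmetic and appends a dedicated synthetic calibrator
sample with unit quantity in every assay — a real panel tissue cannot
serve as calibrator without distorting the recovered ratios — so the
noiseless round trip is exact to 1e-9.

What passing on synthetic panels shows: the estimators recover the
parameters and the component count of data that exactly follow the model.
What it does not show: robustness to non-Gaussian tails, amplification-
efficiency drift, plate effects, or dependence between tissues — none of
which the generator emulates.

## Problem sizes and observed behaviour

The recovery and selection studies use 1000 pooled points (Gaussian
mixture, EEV grid G = 1..6) and 200 tissues × 3 replicates (mixture of
LMMs, G ∈ {2, 3}), with modal BIC selection over 10 seeds — sizes at
which selection is stable while a full study run stays in the minutes
range.  The one-M-step fixed-point oracle runs at 20 000 tissues: at
5 000, Monte-Carlo noise on the second moments of the rarest component
(π ≈ 0.1) alone exceeds the 2 % proximity band, so the larger panel is
needed for the band to bind on the update rather than on sampling noise.

Two findings worth knowing.  First, a full-family BIC search at n = 1000
prefers many small spherical components (VII, G = 6) over the generating
three-component EEV structure: near-singular elongated ellipses are cheap
to approximate by stacked spheres, so family restriction is part of the
protocol, not a convenience.  Second, the two clustering methods agree on
the isolated component but split the two overlapping ones differently —
the same qualitative behaviour the published 20-tissue confusion matrix
shows.

## Known limitations

* Only the five-family subset of the full covariance-family catalogue is
  implemented, and only bivariate (two-variant) mixtures are exercised.
* The FMLMM fixes an intercept-only design; covariates would need a wider
  V.
* Entropy-based uncertainty is a summary of the posterior, not a
  calibrated error rate.
* The tissue-level label for a pooled-replicate fit is a majority vote
  with lowest-index tie-break; with a 2–1 replicate split both conventions
  (majority vs counting the split tissue with the minority) are defensible,
  and the comparison report emits the replicate-level split alongside.
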