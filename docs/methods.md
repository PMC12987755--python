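# Methods

## Model

Dichotomous responses follow the unidimensional 2PL model
P(X_i = 1 | θ) = Ψ(a_i θ − d_i). Two measurement occasions share a common
item set C; the time-1 latent distribution is fixed to N(0, 1) and the
time-2 distribution N(μ₂, σ₂²) carries the trend parameters. Uniform item
parameter drift adds δ_i to the intercept of item i at time 2 only
(d_i2 = d_i + δ_i, discriminations invariant). Drift is *balanced* when the
δ_i sum to zero over C and *unbalanced* otherwise. Identification rests on
a sparsity assumption: most δ_i are zero, so the drift effects are outliers
rather than a systematic scale shift.

## Marginal likelihood and quadrature

All calibrations maximize the marginal likelihood in which θ is integrated
against the occasion's normal density. The integral is evaluated on one
fixed grid of 61 equally spaced nodes on [−6, 6] shared by both groups,
with group-specific weights proportional to φ(θ; μ_t, σ_t), renormalized.
A shared node set lets the concurrent fit pool expected counts across
groups exactly; the truncation mass beyond +6 for N(1.0, 1.3²) is ~6·10⁻⁵,
which is negligible at the precision of any quantity reported here
(doubling the node count moves item estimates by < 10⁻³; a 2,001-node grid
reproduces the marginal log-likelihood to 10⁻⁶).

Missing responses are treated as ignorable and contribute a factor of one.
Items observed in only one response category are excluded from calibration
with a warning, since their intercepts diverge.

## EM calibration

Single-group, concurrent (two-group) and fixed calibrations run a
Bock–Aitkin EM: the E-step computes each person's posterior over the nodes
and the expected per-node counts; the M-step applies damped Newton updates
per item (pooling counts across groups for anchored items, separately for
freed items) and, where the group distribution is free, a Newton update of
(μ₂, log σ₂) maximizing the expected complete-data term under the
renormalized discrete weights. The deviance trace is recorded and is
non-increasing. Convergence: maximum absolute parameter change < 10⁻⁵,
at most 1,000 iterations. Starting values: unit discriminations and
logit-transformed observed proportions.

## Linking

Separate calibrations (each identified at N(0, 1)) are linked onto the
time-1 metric via θ* = σ₂θ + μ₂, under which the time-2 internal estimates
satisfy â_i2 = a_i σ₂ and d̂_i2 = d_i − (â_i2/σ₂)μ₂. Haberman linking
estimates s₂ = log σ₂ first from log-discriminations (immune to intercept
drift by construction), then μ₂ from intercepts (default; lower variance)
or difficulties, each as a joint robust regression with per-item nuisance
parameters. Haebara linking minimizes the density-weighted integral of the
per-item IRF discrepancy jointly over (μ₂, σ₂); weights are uniform or
normal densities (σ = 0.5, 1, 2) centered at 0 on 61 nodes over [−6, 6] —
the weight center is a declared choice, as is the asymmetric direction
(time-1 IRFs transformed onto the time-2 scale, no symmetrization).

Losses: exact |x|^p for p = 2 (closed forms used where available), the
smooth approximation (x² + ε)^{p/2} with ε = 0.001 for 0 < p ≤ 1, and the
smooth L0 loss x²/(x² + ε) with ε = 0.01. For p < 1 the objective is
non-convex and is minimized by a homotopy: the smoothing parameter is
annealed in decade steps from 1.0 down to its target, warm-starting each
L-BFGS solve at the previous solution, beginning from the least-squares
closed form (a per-item-median start is annealed in parallel and the
better final objective wins). Tracking this path follows a stable central
minimum of the final objective; selecting the globally deepest basin of
the ε-target objective directly proved erratic under sampling noise, with
occasional large jumps of μ̂₂ between local minima.

## Detection and partial invariance

The RMSD statistic for item i at occasion t is the square root of
∫ (P_it(θ) − P_i(θ))² f_t(θ) dθ — the root is applied, consistent with the
statistic's name and the 0.03–0.08 cutoff scale. P_i is the
invariance-constrained IRF; P_it is the pseudo-observed IRF, i.e. the
posterior-expected proportion correct at each node from the constrained
fit's final E-step; f_t is the model-implied normal density on the grid.
An item's flagging statistic is the maximum of its two per-occasion RMSDs;
data-driven robust z-scores are computed separately per occasion
(z_i = |RMSD_i − median| / (1.4826·MAD), one-sided above the median, MAD
floored at 10⁻⁸ so exact ties yield z = 0) and an item is flagged if it
exceeds τ at either occasion.

The likelihood-ratio test uses the constrained-baseline (all-other-anchor)
design: G² = 2(logL₁ − logL₀) with the tested item's (a, d) freed at both
occasions, referred to χ²(2); Bonferroni uses α = 0.05/k for k items
tested. One-step detection flags all items beyond the threshold in a
single pass; iterative purification (RMSD only) refits the
partial-invariance model each round, retests only current anchors, never
revisits earlier flags, and stops after at most 7 rounds. At least 3
anchor items are always retained; excess flags are truncated by statistic
size (ties broken by raw statistic, then item position). Re-estimation
under a partition either refits the concurrent model with flagged items
freed or relinks the separate calibrations on the anchor items with the
squared loss.

## Regularized estimation

The drift model carries shared (a, d), per-item δ applied at time 2, and
(μ₂, σ₂). The smooth BIC

SBIC = 2·nll + log(N₁+N₂) · (H + Σ_i δ_i²/(δ_i² + ε)),  H = 2I + 2,

is minimized jointly by L-BFGS-B with analytic gradients (σ₂ on the log
scale; a bounded below at 0.01) from two starts: the full-invariance
concurrent solution with δ = 0, and a robust start whose (μ₂, σ₂) come
from smooth-L0 Haberman linking and whose δ are the implied
separate-calibration intercept residuals. The lower final criterion wins.
Joint quasi-Newton minimization converged faster and more reliably here
than alternating EM/quasi-Newton blocks. ε defaults to 0.001 (0.01 and
0.0001 exposed). Because the smooth counter never returns exact zeros,
|δ̂_i| > 0.01 is the declared reporting convention for a "selected" drift
effect; the threshold plays no role in estimation.

## Synthetic-data generator

The generator emulates the study conditions exactly: a fixed bank of 10
base items (a = 1.06, 0.78, 0.91, 1.14, 1.19, 0.89, 0.82, 1.00, 1.00,
1.00; d = −0.17, −0.77, 0.36, 1.37, 2.08, −1.56, 0.72, −0.46, −0.46,
−0.46) replicated in blocks to 20 or 40 items, all common; θ₁ ~ N(0, 1),
θ₂ ~ N(1.0, 1.3²); Bernoulli responses from the 2PL IRF; drift injected at
time 2 on item 10 of each block (10%) or items 8–10 (30%, all with
a = 1). Unbalanced drift sets every affected δ_i = −|δ|; balanced drift
alternates +|δ|/−|δ| along the affected-item list, so the effects sum to
zero exactly (the assignment order within the ±halves is a declared
convention). The full design crosses N ∈ {500, 1000, 2500}, I ∈ {20, 40},
δ ∈ {0.5, 1.0}, contamination ∈ {10%, 30%} and balance, plus one no-drift
cell per (N, I): 54 conditions. The estimator grid enumerates 126
configurations (CC, FC, 10 Haberman, 20 Haebara, 21 LRT, 70 RMSD, 3 REG).

What the generator does **not** emulate: real response data with model
misfit (guessing, multidimensionality, local dependence), nonuniform drift
on discriminations, unique items, unequal group sizes, or missingness.
Passing tests therefore demonstrate correct behavior under the 2PL with
sparse uniform intercept drift, not robustness to misspecification.

Randomness: one integer master seed; the child stream for replication r of
condition k is `SeedSequence(master, spawn_key=(k, r))`, so every
replication is independently reproducible and results are invariant to
execution order.

## Evaluation

Bias is the mean of (estimate − truth) over replications; RMSE its root
mean square. RMSE is reported relative to the SBIC (ε = 0.001) reference
as 100·RMSE/RMSE_ref. An estimator is satisfactory at |bias| < 0.015 and
relative RMSE ≤ 125. Failed replications are excluded from summaries with
their count reported, keeping seeds aligned across estimators.

## Problem sizes used in the checks

The reproduction script and the acceptance tests rerun the severe-drift
and no-drift conditions at 40–200 replications per quantity (Monte-Carlo
standard errors of the reported biases ~0.004–0.013), rather than the full
1,000-replication design; the simulation engine itself is
R-configurable. Parameter-recovery checks use N = 100,000 with 3-SE
bounds. Grid-search oracles validate every linking optimum at resolutions
of 10⁻⁴ (1-D profiles) and 5·10⁻³ (2-D Haebara).

## Known limitations

* The smooth-L0 Haberman mean step in the noisiest condition (N = 500,
  δ = 0.5, 30% drift) has Monte-Carlo bias ≈ +0.06 under this
  implementation — the redescending loss only partially separates drifted
  from clean items when calibration noise (residual SD ≈ 0.13) is
  comparable to the loss scale √ε = 0.1. Values near +0.05 are typical of
  published results for this estimator; the discrepancy is within ~3 joint
  Monte-Carlo standard errors.
* Concurrent calibration's drift-induced bias at N = 500 is slightly
  attenuated (≈ 0.26–0.27 rather than 0.28) relative to asymptotic
  behavior; at N ≥ 1,000 it matches 0.27–0.28.
* Exact numeric agreement with other 2PL software is not claimed (EM
  tolerances and quadrature schemes differ); statistical agreement is.
* Chain linking across ≥ 3 occasions, 1PL/3PL or polytomous models,
  information-weighted or symmetric Haebara variants, and SCAD/LASSO
  penalties are out of scope.
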