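# driftlink

Trend estimation for longitudinal assessments under item parameter drift.

## The problem

Longitudinal large-scale assessments estimate how a population's latent
ability changes between two measurement occasions by administering
overlapping test forms and linking them through common items. The package
models dichotomous responses with the two-parameter logistic (2PL) model,

    P(X_i = 1 | θ) = Ψ(a_i θ − d_i),    Ψ(x) = 1 / (1 + exp(−x)),

with discrimination a_i and intercept d_i (difficulty b_i = d_i / a_i). The
time-1 ability distribution is fixed to N(0, 1) for identification; the
targets of inference are the time-2 mean μ₂ and standard deviation σ₂.

When some common items drift — their intercepts change between occasions
(uniform item parameter drift, d_i2 = d_i + δ_i) — estimators that assume
full invariance misread the drift as population change. Under *unbalanced*
drift (all δ_i of one sign) this bias does not vanish with sample size.
`driftlink` implements five families of estimators for (μ₂, σ₂) under
sparse uniform drift, plus the Monte-Carlo machinery to compare them:

1. **Concurrent calibration (CC)** — joint two-group 2PL fit, all common
   item parameters constrained equal.
2. **Fixed calibration (FC)** — items calibrated at time 1 and frozen;
   only (μ₂, σ₂) fitted at time 2.
3. **Robust linking** — separate per-occasion calibrations placed on a
   common scale by Haberman linking (σ₂ from log-discriminations, μ₂ from
   intercepts or difficulties) or Haebara linking (joint minimization of
   the weighted IRF discrepancy), with the residual loss |x|^p for
   p ∈ {0.25, 0.5, 1, 2} or the smooth L0 loss x²/(x²+ε) that caps every
   item's influence.
4. **Detection + partial invariance** — drifting items flagged by the RMSD
   effect size (fixed cutoffs 0.03/0.05/0.08 or data-driven robust-z
   cutoffs τ = 1.7/2.7 based on the median absolute deviation) or by a
   likelihood-ratio test (χ², df = 2; α = 0.05/0.01/Bonferroni), one-step
   or iteratively (≤ 7 rounds, ≥ 3 anchor items always retained), then the
   trend re-estimated with flagged items freed.
5. **Regularized estimation (REG)** — a joint model with one drift effect
   δ_i per item, identified by directly minimizing the smooth Bayesian
   information criterion

       SBIC = 2·nll + log(N*) · (H + Σ_i δ_i²/(δ_i² + ε)),

   which shrinks null drift effects to zero and selects the drifting items
   in the same optimization.

## Worked example

```python
import driftlink as dl

# severe unbalanced drift: 30% of 20 items drift by -1.0 at time 2;
# true trend mu2 = 1.0, sigma2 = 1.3, N = 2,500 per occasion
cond = dl.SimulationCondition(2500, 20, 1.0, 30, "unbalanced")
data, drift = dl.simulate_responses(cond, seed=1)

cc = dl.calibrate_concurrent(data)
print(f"CC:  mu2 = {cc.mu2:.3f}  sigma2 = {cc.sigma2:.3f}")

model, selection, reg = dl.fit_regularized(data, eps=0.001)
print(f"REG: mu2 = {reg.mu2:.3f}  sigma2 = {reg.sigma2:.3f}")
print("items with selected drift:",
      [i for i, s in zip(model.item_ids, selection.selected) if s])
```

Output:

```
CC:  mu2 = 1.269  sigma2 = 1.210
REG: mu2 = 0.984  sigma2 = 1.308
items with selected drift: ['I08', 'I09', 'I10', 'I18', 'I19', 'I20']
```

Concurrent calibration absorbs the negative intercept drift as +0.27 of
spurious growth; the regularized estimator identifies exactly the six
drifting items and recovers the true trend (μ₂ = 1.0, σ₂ = 1.3) within
sampling error.

A command-line interface wraps the same machinery:

```bash
driftlink simulate --config run.yaml --seed 1 --reps 100 --out results/
driftlink analyze  --data responses.csv --estimators "CC,FC,REG eps=0.001" --out trends.csv
driftlink report   --results results/raw_estimates.csv --out evaluation.csv
```

`simulate` writes raw per-replication estimates, a bias/RMSE evaluation
table (RMSE reported relative to the REG reference = 100), and a manifest
with the master seed and configuration hash; re-running with the same
manifest reproduces the results bit for bit.

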