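"""Monte-Carlo study of trend estimation under sparse uniform intercept drift.

The generator draws two-time-point 2PL response data from a fixed bank of
10 base items replicated in blocks of 10 (test lengths 20 or 40).  Time-1
abilities are standard normal; time-2 abilities are N(1.0, 1.3^2).  Drift is
injected at time 2 by adding a per-item effect delta_i to designated item
intercepts: item 10 of each block for 10% contamination, items 8-10 for 30%
(all with discrimination 1.0).  Balanced drift splits the affected items
into equal +|delta| / -|delta| halves (effects sum to zero); unbalanced
drift sets every affected effect to -|delta|.

The full design crosses sample size (500/1,000/2,500 per time point), test
length (20/40), effect size (0.5/1.0), contamination (10%/30%) and balance,
plus one no-drift cell per (N, I): 54 conditions.  The estimator grid
enumerates the 126 trend estimators compared in the study.  A replication
engine runs seeded replications, sharing the expensive calibrations between
estimators, and an evaluator reduces raw estimates to bias, RMSE and RMSE
relative to the regularized (SBIC, eps = 0.001) reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import (DetectionConfig, detect_iterative, detect_one_step,
                        reestimate_partial_invariance)
from .irt_core import (CalibrationSettings, ItemBank, ResponseData,
                       calibrate_concurrent, calibrate_fixed, calibrate_single,
                       irf_2pl)
from .linking import (LossSpec, SeparateCalibrations, WeightSpec,
                      haberman_link, haebara_link)
from .regularization import EPS_GRID, fit_regularized

logger = logging.getLogger(__name__)

__all__ = [
    "BASE_A", "BASE_D", "TRUE_MU2", "TRUE_SIGMA2",
    "SimulationCondition", "DriftSpec", "EstimatorSpec",
    "base_item_bank", "make_design", "make_drift_spec",
    "enumerate_estimators", "simulate_responses",
    "estimate_trends", "run_replications", "evaluate",
]

#: the 10 base-item discriminations and intercepts of the study design
BASE_A = np.array([1.06, 0.78, 0.91, 1.14, 1.19, 0.89, 0.82, 1.00, 1.00, 1.00])
BASE_D = np.array([-0.17, -0.77, 0.36, 1.37, 2.08, -1.56, 0.72, -0.46, -0.46, -0.46])

#: true time-2 trend parameters of the generating model
TRUE_MU2 = 1.0
TRUE_SIGMA2 = 1.3

N_GRID = (500, 1000, 2500)
I_GRID = (20, 40)
DELTA_GRID = (0.5, 1.0)
PCT_GRID = (10, 30)

REFERENCE_LABEL = "REG eps=0.001"


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design."""

    n: int
    n_items: int
    delta: float
    pct_ipd: int
    ipd_type: str  # 'balanced' | 'unbalanced' | 'none'
    mu2: float = TRUE_MU2
    sigma2: float = TRUE_SIGMA2

    def __post_init__(self):
        if (self.delta == 0) != (self.pct_ipd == 0):
            raise ValueError("delta=0 and pct_ipd=0 must coincide")
        if self.pct_ipd == 0 and self.ipd_type != "none":
            raise ValueError("no-drift conditions use ipd_type='none'")

    @property
    def label(self) -> str:
        if self.pct_ipd == 0:
            return f"N={self.n} I={self.n_items} no-IPD"
        return (f"N={self.n} I={self.n_items} delta={self.delta:g} "
                f"pct={self.pct_ipd} {self.ipd_type}")


@dataclass(frozen=True)
class DriftSpec:
    """Per-item drift effects applied to intercepts at time 2."""

    delta: np.ndarray
    ipd_type: str

    def __post_init__(self):
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=float))
        if self.ipd_type == "balanced" and abs(self.delta.sum()) > 1e-12:
            raise ValueError("balanced drift effects must sum to zero")

    @property
    def biased_positions(self) -> tuple:
        return tuple(np.flatnonzero(self.delta != 0.0))


def base_item_bank(n_items: int = 20) -> ItemBank:
    """The base 10-item bank replicated into ``n_items // 10`` blocks."""
    if n_items % 10 != 0:
        raise ValueError("test length must be a multiple of the 10-item block")
    blocks = n_items // 10
    ids = tuple(f"I{j + 1:02d}" for j in range(n_items))
    return ItemBank(ids, np.tile(BASE_A, blocks), np.tile(BASE_D, blocks))


def make_drift_spec(n_items: int, delta: float, pct_ipd: int,
                    ipd_type: str) -> DriftSpec:
    """Drift assignment for one condition.

    10% contamination drifts item 10 of each block; 30% drifts items 8-10.
    Unbalanced drift sets every affected effect to -|delta|; balanced drift
    alternates +|delta| / -|delta| over the affected-item list so the
    effects sum to zero exactly.
    """
    eff = np.zeros(n_items)
    if pct_ipd == 0:
        return DriftSpec(eff, "none")
    blocks = n_items // 10
    if pct_ipd == 10:
        positions = [10 * b + 9 for b in range(blocks)]
    elif pct_ipd == 30:
        positions = [10 * b + j for b in range(blocks) for j in (7, 8, 9)]
    else:
        raise ValueError("pct_ipd must be 0, 10 or 30")
    mag = abs(delta)
    if ipd_type == "unbalanced":
        for pos in positions:
            eff[pos] = -mag
    elif ipd_type == "balanced":
        for k, pos in enumerate(positions):
            eff[pos] = mag if k % 2 == 0 else -mag
    else:
        raise ValueError("ipd_type must be 'balanced' or 'unbalanced'")
    return DriftSpec(eff, ipd_type)


def make_design() -> list:
    """The full 54-condition design in deterministic order."""
    conditions = []
    for n in N_GRID:
        for n_items in I_GRID:
            conditions.append(SimulationCondition(n, n_items, 0.0, 0, "none"))
            for delta in DELTA_GRID:
                for pct in PCT_GRID:
                    for ipd_type in ("balanced", "unbalanced"):
                        conditions.append(SimulationCondition(
                            n, n_items, delta, pct, ipd_type))
    return conditions


def simulate_responses(condition: SimulationCondition, seed,
                       return_latent: bool = False) -> tuple:
    """Generate two-time-point responses for one condition.

    Returns ``(ResponseData, DriftSpec)`` — or, with ``return_latent``,
    ``(ResponseData, DriftSpec, (theta1, theta2))``.  ``seed`` may be an
    int or a numpy SeedSequence/Generator.
    """
    rng = np.random.default_rng(seed)
    bank = base_item_bank(condition.n_items)
    drift = make_drift_spec(condition.n_items, condition.delta,
                            condition.pct_ipd, condition.ipd_type)
    theta1 = rng.normal(0.0, 1.0, condition.n)
    theta2 = rng.normal(condition.mu2, condition.sigma2, condition.n)
    p1 = irf_2pl(theta1[:, None], bank.a, bank.d)
    p2 = irf_2pl(theta2[:, None], bank.a, bank.d + drift.delta)
    X1 = (rng.random(p1.shape) < p1).astype(float)
    X2 = (rng.random(p2.shape) < p2).astype(float)
    data = ResponseData(
        responses=np.vstack([X1, X2]),
        time=np.concatenate([np.ones(condition.n, dtype=int),
                             np.full(condition.n, 2, dtype=int)]),
        item_ids=bank.item_ids)
    if return_latent:
        return data, drift, (theta1, theta2)
    return data, drift


# ---------------------------------------------------------------------------
# Estimator grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EstimatorSpec:
    """One trend-estimator configuration (resolvable by its unique label)."""

    family: str  # CC | FC | HAB | HAE | LRT | RMSD | REG
    label: str
    params: tuple = ()  # hashable (key, value) pairs

    @property
    def options(self) -> dict:
        return dict(self.params)


def _spec(family, label, **params):
    return EstimatorSpec(family, label, tuple(sorted(params.items())))


RE_ESTIMATORS = ("CC", "HAB-int", "HAB-diff", "HAE-uniform",
                 "HAE-normal0.5", "HAE-normal1", "HAE-normal2")
P_VALUES = (0.0, 0.25, 0.5, 1.0, 2.0)
RMSD_CUTOFFS = (("rmsd-fixed", 0.03), ("rmsd-fixed", 0.05), ("rmsd-fixed", 0.08),
                ("rmsd-dd", 1.7), ("rmsd-dd", 2.7))
LRT_ALPHAS = (0.05, 0.01, "bonferroni")


def enumerate_estimators() -> list:
    """The 126 estimator configurations of the study.

    CC (1) + FC (1) + Haberman 2x5 (10) + Haebara 4x5 (20) + LRT 3x7 (21)
    + RMSD 5 cutoffs x 2 approaches x 7 re-estimators (70) + REG 3 (3).
    """
    specs = [_spec("CC", "CC"), _spec("FC", "FC")]
    for param in ("int", "diff"):
        for p in P_VALUES:
            specs.append(_spec("HAB", f"HAB-{param} p={p:g}",
                               parameterization=param, p=p))
    for weight in ("uniform", "normal0.5", "normal1", "normal2"):
        for p in P_VALUES:
            specs.append(_spec("HAE", f"HAE-{weight} p={p:g}",
                               weight=weight, p=p))
    for alpha in LRT_ALPHAS:
        for re_est in RE_ESTIMATORS:
            specs.append(_spec("LRT", f"LRT alpha={alpha} re={re_est}",
                               alpha=alpha, reestimator=re_est))
    for stat, cutoff in RMSD_CUTOFFS:
        for approach in ("one-step", "iterative"):
            for re_est in RE_ESTIMATORS:
                kind = "FIX" if stat == "rmsd-fixed" else "DD"
                ap = "OS" if approach == "one-step" else "IT"
                specs.append(_spec(
                    "RMSD", f"RMSD-{kind} cut={cutoff:g} {ap} re={re_est}",
                    statistic=stat, cutoff=cutoff, approach=approach,
                    reestimator=re_est))
    for eps in EPS_GRID:
        specs.append(_spec("REG", f"REG eps={eps:g}", eps=eps))
    labels = [s.label for s in specs]
    assert len(labels) == len(set(labels))
    return specs


def resolve_estimators(labels) -> list:
    all_specs = {s.label: s for s in enumerate_estimators()}
    out = []
    for lab in labels:
        if lab not in all_specs:
            raise ValueError(f"unknown estimator label {lab!r}")
        out.append(all_specs[lab])
    return out


# ---------------------------------------------------------------------------
# Replication engine
# ---------------------------------------------------------------------------


class _ReplicationCache:
    """Shares the expensive fits between estimators within one replication."""

    def __init__(self, data: ResponseData, settings: CalibrationSettings):
        self.data = data
        self.settings = settings
        self._cc = None
        self._cc_post = None
        self._sep = None
        self._fit1 = None

    def cc_fit(self, keep_posterior=False):
        if keep_posterior:
            if self._cc_post is None:
                self._cc_post = calibrate_concurrent(
                    self.data, settings=self.settings, keep_posterior=True,
                    start=self._cc)
            return self._cc_post
        if self._cc is None:
            if self._cc_post is not None:
                self._cc = self._cc_post
            else:
                self._cc = calibrate_concurrent(self.data, settings=self.settings)
        return self._cc

    def fit1(self):
        if self._fit1 is None:
            self._fit1 = calibrate_single(self.data.at_time(1),
                                          self.data.item_ids,
                                          settings=self.settings)
        return self._fit1

    def separate(self) -> SeparateCalibrations:
        if self._sep is None:
            fit2 = calibrate_single(self.data.at_time(2), self.data.item_ids,
                                    settings=self.settings)
            self._sep = SeparateCalibrations(self.fit1().banks[1],
                                             fit2.banks[1])
        return self._sep


def estimate_trends(data: ResponseData, estimators,
                    settings: CalibrationSettings | None = None) -> dict:
    """Apply a list of estimator specs to one data set.

    Returns label -> TrendEstimate-like record (mu2, sigma2, converged).
    Calibrations are shared across estimators through an internal cache.
    """
    settings = settings or CalibrationSettings()
    cache = _ReplicationCache(data, settings)
    results = {}
    for spec in estimators:
        try:
            results[spec.label] = _run_estimator(spec, cache)
        except Exception as exc:
            logger.warning("estimator %s failed: %s", spec.label, exc)
            results[spec.label] = None
    return results


def _run_estimator(spec: EstimatorSpec, cache: _ReplicationCache):
    opts = spec.options
    if spec.family == "CC":
        fit = cache.cc_fit()
        return {"mu2": fit.mu2, "sigma2": fit.sigma2, "converged": fit.converged}
    if spec.family == "FC":
        est, _ = calibrate_fixed(cache.data.at_time(2), cache.fit1().banks[1],
                                 settings=cache.settings)
        return {"mu2": est.mu2, "sigma2": est.sigma2, "converged": est.converged}
    if spec.family == "HAB":
        loss = LossSpec(p=opts["p"])
        est = haberman_link(cache.separate(), loss,
                            "intercepts" if opts["parameterization"] == "int"
                            else "difficulties")
        return {"mu2": est.mu2, "sigma2": est.sigma2, "converged": est.converged}
    if spec.family == "HAE":
        loss = LossSpec(p=opts["p"])
        w = opts["weight"]
        weight = (WeightSpec("uniform") if w == "uniform"
                  else WeightSpec("normal", float(w.removeprefix("normal"))))
        est = haebara_link(cache.separate(), weight, loss)
        return {"mu2": est.mu2, "sigma2": est.sigma2, "converged": est.converged}
    if spec.family in ("LRT", "RMSD"):
        if spec.family == "LRT":
            config = DetectionConfig(statistic="lrt", cutoff=opts["alpha"],
                                     approach="one-step",
                                     reestimator=opts["reestimator"])
        else:
            config = DetectionConfig(statistic=opts["statistic"],
                                     cutoff=opts["cutoff"],
                                     approach=opts["approach"],
                                     reestimator=opts["reestimator"])
        baseline = cache.cc_fit(keep_posterior=True)
        if config.approach == "one-step":
            part = detect_one_step(cache.data, config, settings=cache.settings,
                                   baseline=baseline)
        else:
            part = detect_iterative(cache.data, config, settings=cache.settings,
                                    baseline=baseline)
        calibs = None
        if config.reestimator != "CC":
            calibs = cache.separate()
        est = reestimate_partial_invariance(cache.data, part,
                                            config.reestimator,
                                            settings=cache.settings,
                                            calibs=calibs)
        return {"mu2": est.mu2, "sigma2": est.sigma2,
                "converged": est.converged,
                "biased_ids": list(part.biased_ids)}
    if spec.family == "REG":
        _, _, est = fit_regularized(cache.data, eps=opts["eps"],
                                    settings=cache.settings,
                                    cc_fit=cache.cc_fit())
        return {"mu2": est.mu2, "sigma2": est.sigma2, "converged": est.converged}
    raise ValueError(f"unknown estimator family {spec.family!r}")


def replication_seed(master_seed: int, condition_index: int, rep: int):
    """Deterministic child seed for one (condition, replication) pair."""
    return np.random.SeedSequence(int(master_seed),
                                  spawn_key=(int(condition_index), int(rep)))


def run_replications(condition: SimulationCondition, estimators, R: int,
                     master_seed: int, condition_index: int = 0,
                     settings: CalibrationSettings | None = None,
                     progress: bool = False) -> pd.DataFrame:
    """Run R seeded replications of one condition for a set of estimators.

    Returns a long DataFrame with one row per (replication, estimator):
    columns rep, estimator, mu2, sigma2, converged. Failed fits carry NaN
    estimates and converged=False; they are excluded (and counted) by
    :func:`evaluate`.
    """
    rows = []
    for rep in range(R):
        seed = replication_seed(master_seed, condition_index, rep)
        data, _ = simulate_responses(condition, seed)
        res = estimate_trends(data, estimators, settings=settings)
        for spec in estimators:
            rec = res[spec.label]
            rows.append({
                "condition": condition.label,
                "rep": rep,
                "estimator": spec.label,
                "mu2": np.nan if rec is None else rec["mu2"],
                "sigma2": np.nan if rec is None else rec["sigma2"],
                "converged": False if rec is None else bool(rec["converged"]),
            })
        if progress:
            logger.info("condition %s replication %d/%d", condition.label,
                        rep + 1, R)
    return pd.DataFrame(rows)


def evaluate(raw: pd.DataFrame, true_mu2: float = TRUE_MU2,
             true_sigma2: float = TRUE_SIGMA2,
             reference: str | None = REFERENCE_LABEL) -> pd.DataFrame:
    """Bias / RMSE / relative RMSE per condition, estimator and parameter.

    bias = mean(estimate - truth); RMSE = sqrt(mean((estimate - truth)^2));
    relative RMSE = 100 * RMSE / RMSE(reference) within each condition and
    parameter.  Satisfactory flags follow the study thresholds: |bias| <
    0.015 and relative RMSE <= 125.  Failed replications (NaN) are dropped
    with their count reported in ``n_failed``.
    """
    truth = {"mu2": true_mu2, "sigma2": true_sigma2}
    out = []
    for (cond, estimator), grp in raw.groupby(["condition", "estimator"],
                                              sort=False):
        for param, tval in truth.items():
            vals = grp[param].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            err = vals[ok] - tval
            bias = float(err.mean()) if ok.any() else np.nan
            rmse = float(np.sqrt((err**2).mean())) if ok.any() else np.nan
            out.append({
                "condition": cond, "estimator": estimator, "parameter": param,
                "bias": bias, "rmse": rmse, "R": int(ok.sum()),
                "n_failed": int((~ok).sum()),
            })
    table = pd.DataFrame(out)
    if reference is not None:
        if reference not in set(table["estimator"]):
            raise ValueError(f"reference estimator {reference!r} absent from results")
        ref = (table[table["estimator"] == reference]
               .set_index(["condition", "parameter"])["rmse"])
        key = list(zip(table["condition"], table["parameter"]))
        with np.errstate(divide="ignore", invalid="ignore"):
            table["rel_rmse"] = (100.0 * table["rmse"].to_numpy()
                                 / ref.loc[key].to_numpy())
        table["satisfactory_rmse"] = table["rel_rmse"] <= 125.0
    table["satisfactory_bias"] = table["bias"].abs() < 0.015
    return table
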