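"""Drift detection and partial-invariance re-estimation.

Items whose response function changes between time points are detected with
either the RMSD effect-size statistic (against fixed cutoffs or data-driven
robust-z cutoffs) or a likelihood-ratio test, then the trend is re-estimated
under partial invariance: flagged items get time-specific parameters while
the remaining anchor items stay constrained.  A one-step and a forward-only
iterative purification scheme are provided; at least three anchor items are
always retained, and the iterative scheme stops after at most seven rounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .irt_core import (CalibrationFit, CalibrationSettings, ResponseData,
                       calibrate_concurrent, calibrate_single, irf_2pl)
from .linking import (LossSpec, SeparateCalibrations, TrendEstimate,
                      WeightSpec, haberman_link, haebara_link)

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "AnchorPartition",
    "RmsdResult",
    "rmsd_statistic",
    "rmsd_from_fit",
    "robust_zscores",
    "lrt_statistic",
    "lrt_all_items",
    "detect_one_step",
    "detect_iterative",
    "detection_report",
    "reestimate_partial_invariance",
]

#: scaling constant making the MAD consistent for the SD under normality
MAD_SCALE = 1.4826
#: floor applied to a degenerate (zero) MAD
MAD_FLOOR = 1e-8
#: cap on robust z-scores produced by a floored MAD
Z_SENTINEL = 1e6

MIN_ANCHOR = 3
MAX_ITERATIONS = 7


@dataclass(frozen=True)
class DetectionConfig:
    """Configuration of a detection-based trend estimator.

    statistic : 'rmsd-fixed' | 'rmsd-dd' | 'lrt'
    cutoff    : RMSD cutoff (0.03/0.05/0.08), robust-z threshold tau
                (1.7/2.7), or alpha level (0.05/0.01/'bonferroni')
    approach  : 'one-step' | 'iterative' (LRT supports one-step only)
    reestimator : 'CC' | 'HAB-int' | 'HAB-diff' | 'HAE-uniform' |
                'HAE-normal0.5' | 'HAE-normal1' | 'HAE-normal2'
                (linking re-estimators use the squared loss, p = 2)
    """

    statistic: str = "rmsd-fixed"
    cutoff: float | str = 0.05
    approach: str = "one-step"
    reestimator: str = "CC"
    max_iterations: int = MAX_ITERATIONS
    min_anchor: int = MIN_ANCHOR

    def __post_init__(self):
        if self.statistic not in ("rmsd-fixed", "rmsd-dd", "lrt"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.approach not in ("one-step", "iterative"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.statistic == "lrt" and self.approach != "one-step":
            raise ValueError("the likelihood-ratio test uses the one-step approach only")
        if self.min_anchor < MIN_ANCHOR:
            raise ValueError(f"min_anchor must be at least {MIN_ANCHOR}")
        if self.max_iterations > MAX_ITERATIONS:
            raise ValueError(f"max_iterations may not exceed {MAX_ITERATIONS}")


@dataclass
class AnchorPartition:
    """Partition of the common items into anchors A and biased items B."""

    anchor_ids: tuple
    biased_ids: tuple
    statistics: dict = field(default_factory=dict)
    history: list = field(default_factory=list)
    n_iterations: int = 1

    def __post_init__(self):
        a, b = set(self.anchor_ids), set(self.biased_ids)
        if a & b:
            raise ValueError("anchor and biased sets must be disjoint")
        if len(a) < MIN_ANCHOR:
            raise ValueError(f"at least {MIN_ANCHOR} anchor items are required")


@dataclass
class RmsdResult:
    """Per-item, per-time-point RMSD values (probability units)."""

    item_ids: tuple
    values: dict  # time point -> ndarray aligned with item_ids

    def max_over_time(self) -> np.ndarray:
        return np.maximum.reduce([np.asarray(v) for v in self.values.values()])


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------


def rmsd_statistic(p_constrained: np.ndarray, p_timepoint: np.ndarray,
                   density: np.ndarray) -> np.ndarray:
    """Root mean square deviation between IRFs on a grid.

    ``p_constrained`` and ``p_timepoint`` are (Q, I) probability matrices of
    the invariance-constrained and the time-point-specific response
    functions; ``density`` is the ability density on the grid (normalized
    internally).  Returns one value per item, in probability units.
    """
    w = np.asarray(density, dtype=float)
    w = w / w.sum()
    diff2 = (np.asarray(p_timepoint) - np.asarray(p_constrained)) ** 2
    return np.sqrt(w @ diff2)


def rmsd_from_fit(fit: CalibrationFit, item_ids=None) -> RmsdResult:
    """RMSD of anchored items from a constrained concurrent fit.

    The constrained IRF uses the fitted shared parameters; the time-point-
    specific IRF is the pseudo-observed proportion correct at each node
    (posterior-expected counts from the final E-step).  The density f_t is
    the model-implied normal for each time point evaluated on the grid.
    """
    if fit.posterior is None:
        raise ValueError("fit must be run with keep_posterior=True")
    ids = tuple(item_ids) if item_ids is not None else fit.banks[1].item_ids
    nodes = fit.posterior["nodes"]
    bank = fit.banks[1]
    idx = [bank.item_ids.index(i) for i in ids]
    p_model = irf_2pl(nodes[:, None], bank.a[idx], bank.d[idx])
    values = {}
    for g, t in enumerate(sorted(fit.dists)):
        r = fit.posterior["r"][g][:, idx]
        m = fit.posterior["m"][g][:, idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            p_obs = np.where(m > 1e-10, r / np.maximum(m, 1e-10), p_model)
        dist = fit.dists[t]
        z = (nodes - dist.mu) / dist.sigma
        density = np.exp(-0.5 * z**2)
        values[t] = rmsd_statistic(p_model, p_obs, density)
    return RmsdResult(item_ids=ids, values=values)


def robust_zscores(values: np.ndarray) -> np.ndarray:
    """One-sided robust z-scores of RMSD values via the scaled MAD.

    z_i = |x_i - median| / (1.4826 * MAD); a degenerate MAD is floored, so
    exact ties give z = 0 while any value strictly above the median of a
    tied set is assigned a large sentinel.  Scores for values below the
    median are returned as computed but flagging is one-sided (callers flag
    only values above the median).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < MIN_ANCHOR:
        raise ValueError("need at least three values for the robust z-score")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    z = np.abs(x - med) / (MAD_SCALE * max(mad, MAD_FLOOR))
    return np.minimum(z, Z_SENTINEL)


# ---------------------------------------------------------------------------
# Likelihood-ratio test
# ---------------------------------------------------------------------------


def lrt_statistic(data: ResponseData, item_id: str,
                  baseline: CalibrationFit,
                  settings: CalibrationSettings | None = None) -> float:
    """G^2 for one item under the all-other-anchor design.

    The baseline constrains every common item; the alternative frees the
    tested item's (a, d) at both time points.  G^2 = 2 (logL1 - logL0) is
    referred to a chi-square distribution with 2 degrees of freedom.
    """
    cmap = {i: "shared" for i in data.item_ids}
    cmap[str(item_id)] = "free"
    alt = calibrate_concurrent(data, cmap, settings=settings, start=baseline)
    return 2.0 * (alt.loglik - baseline.loglik)


def lrt_all_items(data: ResponseData, baseline: CalibrationFit | None = None,
                  settings: CalibrationSettings | None = None) -> dict:
    """G^2 for every item; items with non-convergent alternatives skipped."""
    if baseline is None:
        baseline = calibrate_concurrent(data, settings=settings)
    stats = {}
    for i in data.item_ids:
        try:
            stats[i] = lrt_statistic(data, i, baseline, settings=settings)
        except Exception as exc:  # non-convergence, degenerate item
            warnings.warn(f"LRT for item {i!r} skipped: {exc}", UserWarning)
    return stats


def lrt_critical(alpha, n_tested: int) -> float:
    """Chi-square(2) critical value; 'bonferroni' uses alpha = 0.05/k."""
    if alpha == "bonferroni":
        alpha = 0.05 / n_tested
    return float(chi2.ppf(1.0 - float(alpha), df=2))


# ---------------------------------------------------------------------------
# Purification
# ---------------------------------------------------------------------------


def _truncate_flags(flagged, stats, n_items, min_anchor):
    """Keep only the top |C| - min_anchor flags by statistic.

    Ties break by larger raw statistic then lower item position (the order
    of ``stats``), which the lexicographic sort below implements.
    """
    max_flags = n_items - min_anchor
    if len(flagged) <= max_flags:
        return flagged
    order = sorted(flagged, key=lambda i: (-stats[i], list(stats).index(i)))
    return set(order[:max_flags])


def _flag_rmsd_fixed(rmsd: RmsdResult, cutoff: float, candidates):
    vals = rmsd.max_over_time()
    return {i for i, v in zip(rmsd.item_ids, vals) if i in candidates and v > cutoff}


def _flag_rmsd_dd(rmsd: RmsdResult, tau: float, candidates):
    """Flag items whose robust z exceeds tau at either time point.

    The MAD and z-scores are computed separately per time point, over the
    current candidate (anchor) items only.
    """
    idx = [k for k, i in enumerate(rmsd.item_ids) if i in candidates]
    ids = [rmsd.item_ids[k] for k in idx]
    flagged = set()
    for t, vals in rmsd.values.items():
        x = np.asarray(vals)[idx]
        med = np.median(x)
        z = robust_zscores(x)
        for i, v, zz in zip(ids, x, z):
            if v > med and zz > tau:
                flagged.add(i)
    return flagged


def detect_one_step(data: ResponseData, config: DetectionConfig,
                    settings: CalibrationSettings | None = None,
                    baseline: CalibrationFit | None = None) -> AnchorPartition:
    """Single detection pass starting from the all-invariant model."""
    if baseline is None:
        baseline = calibrate_concurrent(data, settings=settings,
                                        keep_posterior=True)
    ids = data.item_ids
    if config.statistic == "lrt":
        stats = lrt_all_items(data, baseline, settings=settings)
        crit = lrt_critical(config.cutoff, len(stats))
        flagged = {i for i, g2 in stats.items() if g2 > crit}
        rank_stats = stats
    else:
        rmsd = rmsd_from_fit(baseline)
        vals = rmsd.max_over_time()
        rank_stats = dict(zip(rmsd.item_ids, vals))
        if config.statistic == "rmsd-fixed":
            flagged = _flag_rmsd_fixed(rmsd, float(config.cutoff), set(ids))
        else:
            flagged = _flag_rmsd_dd(rmsd, float(config.cutoff), set(ids))
    flagged = _truncate_flags(flagged, rank_stats, len(ids), config.min_anchor)
    anchors = tuple(i for i in ids if i not in flagged)
    return AnchorPartition(
        anchor_ids=anchors,
        biased_ids=tuple(i for i in ids if i in flagged),
        statistics={i: float(rank_stats.get(i, np.nan)) for i in ids},
        history=[tuple(sorted(flagged))],
        n_iterations=1)


def detect_iterative(data: ResponseData, config: DetectionConfig,
                     settings: CalibrationSettings | None = None,
                     baseline: CalibrationFit | None = None) -> AnchorPartition:
    """Forward-only iterative purification for the RMSD statistics.

    Flagged items are never retested; each round refits the partial-
    invariance model with the current biased set freed, recomputes RMSD on
    the remaining anchors, and stops when no new item is flagged or after
    ``max_iterations`` rounds.
    """
    if config.statistic == "lrt":
        raise ValueError("iterative purification is defined for RMSD statistics only")
    ids = data.item_ids
    biased: set = set()
    history = []
    all_stats: dict = {}
    fit = baseline
    n_iter = 0
    for n_iter in range(1, config.max_iterations + 1):
        cmap = {i: ("free" if i in biased else "shared") for i in ids}
        if fit is None or n_iter > 1:
            fit = calibrate_concurrent(data, cmap, settings=settings,
                                       keep_posterior=True,
                                       start=fit if n_iter > 1 else None)
        anchors_now = [i for i in ids if i not in biased]
        rmsd = rmsd_from_fit(fit, item_ids=anchors_now)
        vals = rmsd.max_over_time()
        stats = dict(zip(rmsd.item_ids, vals))
        all_stats.update(stats)
        if config.statistic == "rmsd-fixed":
            new = _flag_rmsd_fixed(rmsd, float(config.cutoff), set(anchors_now))
        else:
            if len(anchors_now) < MIN_ANCHOR:
                new = set()
            else:
                new = _flag_rmsd_dd(rmsd, float(config.cutoff), set(anchors_now))
        # forward-only: earlier flags are never revisited, so the min-anchor
        # truncation applies to the new flags only
        allowed_new = len(ids) - config.min_anchor - len(biased)
        if len(new) > allowed_new:
            order = sorted(new, key=lambda i: (-all_stats[i], ids.index(i)))
            new = set(order[:max(allowed_new, 0)])
        history.append(tuple(sorted(biased | new)))
        if not new:
            break
        biased |= new
        if len(ids) - len(biased) <= config.min_anchor:
            break
    return AnchorPartition(
        anchor_ids=tuple(i for i in ids if i not in biased),
        biased_ids=tuple(i for i in ids if i in biased),
        statistics={i: float(all_stats.get(i, np.nan)) for i in ids},
        history=history,
        n_iterations=n_iter)


def detection_report(partition: AnchorPartition, config: DetectionConfig):
    """Flat per-item table of a detection run (writable as delimited text)."""
    import pandas as pd

    flagged_at = {}
    for it, flags in enumerate(partition.history, start=1):
        for i in flags:
            flagged_at.setdefault(i, it)
    rows = [{"item_id": i,
             "statistic": partition.statistics.get(i, np.nan),
             "cutoff": config.cutoff,
             "flagged": i in partition.biased_ids,
             "iteration": flagged_at.get(i, 0)}
            for i in (*partition.anchor_ids, *partition.biased_ids)]
    return pd.DataFrame(rows).sort_values("item_id", ignore_index=True)


# ---------------------------------------------------------------------------
# Re-estimation under partial invariance
# ---------------------------------------------------------------------------


def _separate_calibrations(data: ResponseData,
                           settings: CalibrationSettings | None = None
                           ) -> SeparateCalibrations:
    fit1 = calibrate_single(data.at_time(1), data.item_ids, settings=settings)
    fit2 = calibrate_single(data.at_time(2), data.item_ids, settings=settings)
    return SeparateCalibrations(fit1.banks[1], fit2.banks[1])


def reestimate_partial_invariance(data: ResponseData,
                                  partition: AnchorPartition,
                                  reestimator: str = "CC",
                                  settings: CalibrationSettings | None = None,
                                  calibs: SeparateCalibrations | None = None
                                  ) -> TrendEstimate:
    """Trend estimate given an anchor/biased partition.

    'CC' refits the concurrent model with the biased items freed; the
    linking re-estimators link the separate calibrations using the anchor
    items only, with the squared (p = 2) loss.
    """
    if len(partition.anchor_ids) < MIN_ANCHOR:
        raise ValueError(
            f"identification failure: partition has {len(partition.anchor_ids)} "
            f"anchors ({partition.anchor_ids!r}); at least {MIN_ANCHOR} required")
    if reestimator == "CC":
        cmap = {i: ("free" if i in partition.biased_ids else "shared")
                for i in data.item_ids}
        fit = calibrate_concurrent(data, cmap, settings=settings)
        return TrendEstimate(mu2=fit.mu2, sigma2=fit.sigma2,
                             method="CC-partial",
                             settings={"reestimator": "CC"},
                             converged=fit.converged,
                             anchor_ids=partition.anchor_ids)
    if calibs is None:
        calibs = _separate_calibrations(data, settings=settings)
    loss = LossSpec(p=2)
    ids = partition.anchor_ids
    if reestimator == "HAB-int":
        est = haberman_link(calibs, loss, "intercepts", ids=ids)
    elif reestimator == "HAB-diff":
        est = haberman_link(calibs, loss, "difficulties", ids=ids)
    elif reestimator == "HAE-uniform":
        est = haebara_link(calibs, WeightSpec("uniform"), loss, ids=ids)
    elif reestimator.startswith("HAE-normal"):
        sigma = float(reestimator.removeprefix("HAE-normal"))
        est = haebara_link(calibs, WeightSpec("normal", sigma), loss, ids=ids)
    else:
        raise ValueError(f"unknown re-estimator {reestimator!r}")
    est.anchor_ids = ids
    return est
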