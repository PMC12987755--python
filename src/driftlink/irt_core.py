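"""Two-parameter logistic (2PL) IRT model and marginal maximum likelihood calibration.

The 2PL item response function is P(X=1 | theta) = logistic(a*theta - d), with
discrimination a > 0 and intercept d (the "negative intercept" convention, so the
item difficulty is b = d/a).  Calibration maximizes the marginal likelihood in
which the latent trait theta is integrated out against a normal population
density, evaluated on a fixed quadrature grid.  Three calibration modes are
provided:

* single-group calibration with the population fixed at N(0, 1),
* multi-group concurrent calibration of two time points with per-item equality
  constraints (the anchor/biased partition) and a free N(mu2, sigma2) at time 2,
* fixed calibration, in which time-2 data are fit with all item parameters
  frozen and only (mu2, sigma2) estimated.

All fits use a Bock–Aitkin EM algorithm with per-item Newton M-steps; the
deviance trace is recorded and is non-increasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "ItemBank",
    "LatentDistribution",
    "ResponseData",
    "QuadratureGrid",
    "CalibrationFit",
    "CalibrationSettings",
    "irf_2pl",
    "marginal_loglik",
    "calibrate_single",
    "calibrate_concurrent",
    "calibrate_fixed",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemBank:
    """Per-item 2PL parameters.

    Attributes
    ----------
    item_ids : tuple of str
        Unique item labels.
    a : ndarray
        Discriminations, strictly positive.
    d : ndarray
        Intercepts in logit units; the IRF is logistic(a*theta - d).
    """

    item_ids: tuple
    a: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))
        if len(self.item_ids) != len(set(self.item_ids)):
            raise ValueError("item_ids must be unique")
        if a.shape != d.shape or a.ndim != 1 or len(a) != len(self.item_ids):
            raise ValueError("a, d, item_ids must have matching 1-d shapes")
        if np.any(a <= 0):
            raise ValueError("all discriminations must be strictly positive")

    @property
    def b(self) -> np.ndarray:
        """Item difficulties b = d/a."""
        return self.d / self.a

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def subset(self, ids) -> "ItemBank":
        idx = [self.item_ids.index(str(i)) for i in ids]
        return ItemBank(tuple(self.item_ids[j] for j in idx), self.a[idx], self.d[idx])


@dataclass(frozen=True)
class LatentDistribution:
    """Normal latent-trait distribution N(mu, sigma^2)."""

    mu: float = 0.0
    sigma: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class ResponseData:
    """Person-by-item dichotomous responses with a time label per row.

    ``responses`` is an (N, I) float array of 0/1 with NaN for missing;
    ``time`` holds the time-point label (1 or 2) per row.
    """

    responses: np.ndarray
    time: np.ndarray
    item_ids: tuple

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        self.time = np.asarray(self.time, dtype=int)
        self.item_ids = tuple(str(i) for i in self.item_ids)
        if self.responses.ndim != 2:
            raise ValueError("responses must be 2-d")
        if self.responses.shape[0] != len(self.time):
            raise ValueError("time labels must match the number of rows")
        if self.responses.shape[1] != len(self.item_ids):
            raise ValueError("item_ids must match the number of columns")
        vals = self.responses[~np.isnan(self.responses)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("responses must be 0, 1 or missing")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def at_time(self, t: int) -> np.ndarray:
        """Response matrix of time point ``t``."""
        return self.responses[self.time == t]

    def n_at(self, t: int) -> int:
        return int(np.sum(self.time == t))

    def time_points(self) -> tuple:
        return tuple(sorted(np.unique(self.time)))


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed quadrature nodes with normalized nonnegative weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.size == 0:
            raise ValueError("quadrature grid must be non-empty")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        weights = weights / weights.sum()
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def standard(cls, n_nodes: int = 61, bound: float = 6.0) -> "QuadratureGrid":
        """Equally spaced nodes on [-bound, bound], weights ~ standard normal."""
        nodes = np.linspace(-bound, bound, n_nodes)
        w = np.exp(-0.5 * nodes**2)
        return cls(nodes, w)

    def reweight(self, dist: LatentDistribution) -> np.ndarray:
        """Normalized weights proportional to phi(node; mu, sigma)."""
        z = (self.nodes - dist.mu) / dist.sigma
        w = np.exp(-0.5 * z**2)
        return np.clip(w / w.sum(), 1e-300, None)


@dataclass
class CalibrationSettings:
    """Numerical settings shared by all EM calibrations."""

    n_nodes: int = 61
    bound: float = 6.0
    tol: float = 1e-5
    max_iter: int = 1000

    def grid(self) -> QuadratureGrid:
        return QuadratureGrid.standard(self.n_nodes, self.bound)


@dataclass
class CalibrationFit:
    """Result of an EM calibration.

    ``banks`` maps time point -> ItemBank (freed items carry time-specific
    parameters; anchored items are identical across the two banks).
    ``constraint_map`` maps item_id -> 'shared' | 'free'.
    """

    banks: dict
    dists: dict
    loglik: float
    converged: bool
    n_iter: int
    constraint_map: dict
    deviance_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    excluded_items: tuple = ()
    posterior: dict | None = None

    @property
    def mu2(self) -> float:
        return self.dists[2].mu

    @property
    def sigma2(self) -> float:
        return self.dists[2].sigma


# ---------------------------------------------------------------------------
# Item response function and marginal likelihood
# ---------------------------------------------------------------------------


def irf_2pl(theta, a, d):
    """2PL item response probability logistic(a*theta - d).

    Broadcasts over array inputs. Raises for non-positive discrimination.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("discrimination must be strictly positive")
    return expit(a * np.asarray(theta, dtype=float) - np.asarray(d, dtype=float))


def _log_prob_matrix(nodes: np.ndarray, a: np.ndarray, d: np.ndarray):
    """(Q, I) matrices of log P and log(1-P) at the nodes."""
    eta = np.outer(nodes, a) - d  # (Q, I)
    # log(sigmoid(x)) = -log1p(exp(-x)) computed stably
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    return log_p, log_q


def _person_log_matrix(X: np.ndarray, log_p: np.ndarray, log_q: np.ndarray):
    """(N, Q) log-likelihood of each person's responses at each node."""
    miss = np.isnan(X)
    if miss.any():
        X1 = np.where(miss, 0.0, X)
        X0 = np.where(miss, 0.0, 1.0 - X)
    else:
        X1 = X
        X0 = 1.0 - X
    return X1 @ log_p.T + X0 @ log_q.T


def marginal_loglik(bank: ItemBank, dist: LatentDistribution, X: np.ndarray,
                    grid: QuadratureGrid | None = None) -> float:
    """Marginal log-likelihood of a response matrix under a 2PL bank.

    The latent trait is integrated out on the quadrature grid with weights
    proportional to the normal density of ``dist``. Missing responses
    contribute a factor of one. ``X`` is an (N, I) 0/1 matrix (NaN missing)
    whose columns follow ``bank`` order.
    """
    if grid is None:
        grid = QuadratureGrid.standard()
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return 0.0
    if X.shape[1] != bank.n_items:
        raise ValueError("response columns must match the item bank")
    w = grid.reweight(dist)
    log_p, log_q = _log_prob_matrix(grid.nodes, bank.a, bank.d)
    ll = _person_log_matrix(X, log_p, log_q) + np.log(w)
    return float(logsumexp(ll, axis=1).sum())


# ---------------------------------------------------------------------------
# EM machinery
# ---------------------------------------------------------------------------


def _estep(X, nodes, a, d, w):
    """Posterior node weights and expected counts for one group.

    Returns (loglik, nq, r, m): nq (Q,) expected persons per node, r (Q, I)
    expected correct responses, m (Q, I) expected non-missing responses.
    """
    log_p, log_q = _log_prob_matrix(nodes, a, d)
    ll = _person_log_matrix(X, log_p, log_q)
    ll += np.log(w)
    # manual logsumexp/softmax with a single exp pass over the (N, Q) array
    mx = ll.max(axis=1)
    np.subtract(ll, mx[:, None], out=ll)
    np.exp(ll, out=ll)
    row_sum = ll.sum(axis=1)
    norm = np.log(row_sum) + mx
    post = ll
    post /= row_sum[:, None]
    nq = post.sum(axis=0)
    miss = np.isnan(X)
    if miss.any():
        X1 = np.where(miss, 0.0, X)
        M = (~miss).astype(float)
        r = post.T @ X1
        m = post.T @ M
    else:
        r = post.T @ X
        m = np.broadcast_to(nq[:, None], r.shape)
    return float(norm.sum()), nq, r, m, post


def _newton_items(nodes, a, d, r, m, n_steps: int = 5):
    """Per-item Newton updates of (a, d) given expected counts.

    Maximizes sum_q r log P + (m - r) log(1-P) for every item at once.
    A few damped Newton steps per M-step suffice (generalized EM would also
    be monotone; full convergence keeps the deviance trace clean).
    """
    theta = nodes[:, None]
    for _ in range(n_steps):
        p = expit(theta * a - d)  # (Q, I)
        resid = r - m * p
        g_a = (theta * resid).sum(axis=0)
        g_d = -resid.sum(axis=0)
        wgt = m * p * (1.0 - p)
        h_aa = (theta**2 * wgt).sum(axis=0)
        h_ad = -(theta * wgt).sum(axis=0)
        h_dd = wgt.sum(axis=0)
        det = h_aa * h_dd - h_ad**2
        det = np.where(det < 1e-12, 1e-12, det)
        step_a = (h_dd * g_a - h_ad * g_d) / det
        step_d = (-h_ad * g_a + h_aa * g_d) / det
        # damp very large steps for stability
        scale = np.maximum(1.0, np.maximum(np.abs(step_a), np.abs(step_d)) / 1.0)
        a = a + step_a / scale
        d = d + step_d / scale
        a = np.clip(a, 1e-3, 50.0)
        d = np.clip(d, -50.0, 50.0)
        if max(np.abs(step_a).max(initial=0.0), np.abs(step_d).max(initial=0.0)) < 1e-9:
            break
    return a, d


def _fit_latent(nodes, nq, mu0, sigma0):
    """M-step for the group distribution on a fixed grid.

    Maximizes sum_q nq * log wbar_q(mu, sigma) with wbar the renormalized
    normal weights, by Newton iteration in (mu, log sigma) started from the
    posterior moments.
    """
    n_tot = nq.sum()
    mu = float(nq @ nodes / n_tot)
    var = float(nq @ (nodes - mu) ** 2 / n_tot)
    s = 0.5 * np.log(max(var, 1e-6))

    def grad_hess(mu, s):
        sigma = np.exp(s)
        z = (nodes - mu) / sigma
        logphi = -0.5 * z**2
        logphi -= logphi.max()
        phi = np.exp(logphi)
        wbar = phi / phi.sum()
        # d logphi / dmu = z/sigma ; d logphi / ds = z^2
        dmu = z / sigma
        ds = z**2
        g = np.array([
            nq @ dmu - n_tot * (wbar @ dmu),
            nq @ ds - n_tot * (wbar @ ds),
        ])
        # Fisher-type Hessian via weight covariance (expected information)
        e_dmu = wbar @ dmu
        e_ds = wbar @ ds
        cov = np.array([
            [wbar @ (dmu * dmu) - e_dmu**2, wbar @ (dmu * ds) - e_dmu * e_ds],
            [wbar @ (dmu * ds) - e_dmu * e_ds, wbar @ (ds * ds) - e_ds**2],
        ])
        return g, n_tot * cov

    for _ in range(25):
        g, h = grad_hess(mu, s)
        try:
            step = np.linalg.solve(h + 1e-10 * np.eye(2), g)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -0.5, 0.5)
        mu += step[0]
        s += step[1]
        if np.abs(step).max() < 1e-10:
            break
    return float(mu), float(np.exp(s))


def screen_degenerate_items(X: np.ndarray, item_ids) -> list:
    """Indices of items whose observed responses are all 0 or all 1."""
    bad = []
    for j in range(X.shape[1]):
        col = X[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0 or col.min() == col.max():
            bad.append(j)
            warnings.warn(
                f"item {item_ids[j]!r} has a single observed response category; "
                "excluded from calibration", UserWarning, stacklevel=3)
    return bad


def _run_em(groups, a, d, free_mask, est_dist, settings, keep_posterior=False,
            fixed_items=False):
    """Generic EM for one or two groups on a shared grid.

    Parameters
    ----------
    groups : list of dict
        Each with keys 'X' (response matrix) and 'dist' (LatentDistribution);
        the first group's distribution is always held at its given value.
    a, d : start values, shape (I,) for shared plus, when items are freed,
        the freed items are carried per group in ``a_free``/``d_free`` below.
    free_mask : bool array (I,), True for items with time-specific parameters.
    est_dist : bool per group; True if (mu, sigma) is estimated.
    fixed_items : if True, no item parameters are updated at all.
    """
    grid = settings.grid()
    nodes = grid.nodes
    n_groups = len(groups)
    I = len(a)
    # per-group parameter copies; shared items kept equal after each M-step
    A = [a.copy() for _ in range(n_groups)]
    D = [d.copy() for _ in range(n_groups)]
    dists = [g["dist"] for g in groups]

    deviances = []
    converged = False
    it = 0
    prev_params = None
    loglik = -np.inf
    posts = None
    for it in range(1, settings.max_iter + 1):
        loglik = 0.0
        nqs, rs, ms, posts = [], [], [], []
        for g in range(n_groups):
            w = grid.reweight(dists[g])
            ll, nq, r, m, post = _estep(groups[g]["X"], nodes, A[g], D[g], w)
            loglik += ll
            nqs.append(nq)
            rs.append(r)
            ms.append(m)
            posts.append(post)
        deviances.append(-2.0 * loglik)

        if not fixed_items:
            # shared items: pool expected counts across groups (same nodes)
            r_pool = sum(rs)
            m_pool = sum(ms)
            shared = ~free_mask
            if shared.any():
                a_new, d_new = _newton_items(
                    nodes, A[0][shared], D[0][shared],
                    r_pool[:, shared], m_pool[:, shared])
                for g in range(n_groups):
                    A[g][shared] = a_new
                    D[g][shared] = d_new
            if free_mask.any():
                for g in range(n_groups):
                    a_f, d_f = _newton_items(
                        nodes, A[g][free_mask], D[g][free_mask],
                        rs[g][:, free_mask], ms[g][:, free_mask])
                    A[g][free_mask] = a_f
                    D[g][free_mask] = d_f
        for g in range(n_groups):
            if est_dist[g]:
                mu, sigma = _fit_latent(nodes, nqs[g], dists[g].mu, dists[g].sigma)
                dists[g] = LatentDistribution(mu, sigma)

        params = np.concatenate(
            [np.concatenate([A[g], D[g]]) for g in range(n_groups)]
            + [np.array([dists[g].mu, dists[g].sigma]) for g in range(n_groups)])
        if prev_params is not None:
            if np.abs(params - prev_params).max() < settings.tol:
                converged = True
                prev_params = params
                break
        prev_params = params

    # final E-step loglik at the converged parameters
    loglik = 0.0
    posts_final = []
    nqs_final = []
    rs_final = []
    ms_final = []
    for g in range(n_groups):
        w = grid.reweight(dists[g])
        ll, nq, r, m, post = _estep(groups[g]["X"], nodes, A[g], D[g], w)
        loglik += ll
        posts_final.append(post)
        nqs_final.append(nq)
        rs_final.append(r)
        ms_final.append(m)
    deviances.append(-2.0 * loglik)

    posterior = None
    if keep_posterior:
        posterior = {
            "nodes": nodes,
            "nq": nqs_final,
            "r": rs_final,
            "m": ms_final,
        }
    return A, D, dists, loglik, converged, it, np.asarray(deviances), posterior


def _make_fit(item_ids, A, D, dists, loglik, converged, n_iter, trace,
              constraint_map, time_points, excluded=(), posterior=None):
    banks = {t: ItemBank(item_ids, A[g], D[g]) for g, t in enumerate(time_points)}
    dd = {t: dists[g] for g, t in enumerate(time_points)}
    return CalibrationFit(banks=banks, dists=dd, loglik=loglik,
                          converged=converged, n_iter=n_iter,
                          constraint_map=dict(constraint_map),
                          deviance_trace=trace, excluded_items=tuple(excluded),
                          posterior=posterior)


# ---------------------------------------------------------------------------
# Public calibrations
# ---------------------------------------------------------------------------


def calibrate_single(X: np.ndarray, item_ids, settings: CalibrationSettings | None = None,
                     start: ItemBank | None = None) -> CalibrationFit:
    """Single-group 2PL calibration with the population fixed at N(0, 1).

    Items with a single observed response category are excluded with a
    warning (their logits diverge). Returns a :class:`CalibrationFit` whose
    bank is stored under time point 1.
    """
    settings = settings or CalibrationSettings()
    X = np.asarray(X, dtype=float)
    item_ids = tuple(str(i) for i in item_ids)
    bad = screen_degenerate_items(X, item_ids)
    keep = [j for j in range(X.shape[1]) if j not in bad]
    Xk = X[:, keep]
    ids_k = tuple(item_ids[j] for j in keep)
    if start is not None:
        a0 = np.array([start.a[start.item_ids.index(i)] for i in ids_k])
        d0 = np.array([start.d[start.item_ids.index(i)] for i in ids_k])
    else:
        a0 = np.ones(len(keep))
        d0 = _start_intercepts(Xk)
    groups = [{"X": Xk, "dist": LatentDistribution(0.0, 1.0)}]
    free = np.zeros(len(keep), dtype=bool)
    A, D, dists, ll, conv, it, trace, post = _run_em(
        groups, a0, d0, free, [False], settings)
    cmap = {i: "shared" for i in ids_k}
    return _make_fit(ids_k, A, D, dists, ll, conv, it, trace, cmap, (1,),
                     excluded=tuple(item_ids[j] for j in bad), posterior=post)


def _start_intercepts(X: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=0)
    p = np.clip(p, 0.02, 0.98)
    return -np.log(p / (1.0 - p))


def calibrate_concurrent(data: ResponseData,
                         constraint_map: dict | None = None,
                         settings: CalibrationSettings | None = None,
                         start: CalibrationFit | None = None,
                         keep_posterior: bool = False) -> CalibrationFit:
    """Concurrent (multiple-group) calibration of two time points.

    Time point 1 is fixed at N(0, 1); (mu2, sigma2) are estimated. Items
    marked ``'shared'`` in ``constraint_map`` (the default for every item)
    have one (a, d) pair across time points; items marked ``'free'`` get
    time-specific parameters.  At least one shared item is required for
    identification (callers enforcing anchor rules require three).
    """
    settings = settings or CalibrationSettings()
    item_ids = data.item_ids
    constraint_map = dict(constraint_map or {i: "shared" for i in item_ids})
    for i in item_ids:
        constraint_map.setdefault(i, "shared")
    free_mask = np.array([constraint_map[i] == "free" for i in item_ids])
    if free_mask.all():
        raise ValueError(
            "identification error: all items freed while (mu2, sigma2) are free")
    X1, X2 = data.at_time(1), data.at_time(2)
    if start is not None:
        b1, b2 = start.banks[1], start.banks[2]
        a0 = np.array([b1.a[b1.item_ids.index(i)] for i in item_ids])
        d0 = np.array([b1.d[b1.item_ids.index(i)] for i in item_ids])
        dist2 = start.dists[2]
    else:
        a0 = np.ones(len(item_ids))
        d0 = _start_intercepts(np.vstack([X1, X2]))
        dist2 = LatentDistribution(0.0, 1.0)
    groups = [
        {"X": X1, "dist": LatentDistribution(0.0, 1.0)},
        {"X": X2, "dist": dist2},
    ]
    A, D, dists, ll, conv, it, trace, post = _run_em(
        groups, a0, d0, free_mask, [False, True], settings,
        keep_posterior=keep_posterior)
    return _make_fit(item_ids, A, D, dists, ll, conv, it, trace,
                     constraint_map, (1, 2), posterior=post)


def calibrate_fixed(X2: np.ndarray, fixed_bank: ItemBank,
                    settings: CalibrationSettings | None = None):
    """Fixed calibration: fit (mu2, sigma2) with item parameters frozen.

    ``fixed_bank`` must cover every column of ``X2``.  Returns a
    :class:`CalibrationFit` with the bank stored bit-identically.
    """
    from .linking import TrendEstimate  # local import to avoid a cycle

    settings = settings or CalibrationSettings()
    X2 = np.asarray(X2, dtype=float)
    if X2.shape[1] != fixed_bank.n_items:
        raise ValueError("fixed_bank must cover all time-2 items")
    groups = [{"X": X2, "dist": LatentDistribution(0.0, 1.0)}]
    free = np.zeros(fixed_bank.n_items, dtype=bool)
    A, D, dists, ll, conv, it, trace, post = _run_em(
        groups, fixed_bank.a.copy(), fixed_bank.d.copy(), free, [True],
        settings, fixed_items=True)
    est = TrendEstimate(mu2=dists[0].mu, sigma2=dists[0].sigma,
                        method="FC", settings={"n_nodes": settings.n_nodes},
                        converged=conv)
    fit = _make_fit(fixed_bank.item_ids, [fixed_bank.a.copy()],
                    [fixed_bank.d.copy()], dists, ll, conv, it, trace,
                    {i: "shared" for i in fixed_bank.item_ids}, (2,))
    return est, fit
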