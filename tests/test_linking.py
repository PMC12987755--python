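"""Loss functions and Haberman / Haebara linking, checked against grid oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from driftlink.irt_core import ItemBank
from driftlink.linking import (LossSpec, SeparateCalibrations, TrendEstimate,
                               WeightSpec, haberman_link,
                               haberman_mean_difficulties,
                               haberman_mean_intercepts, haberman_sd,
                               haebara_link, loss_value)


def make_calibs(a1, d1, a2, d2):
    ids = tuple(f"i{k}" for k in range(len(a1)))
    return SeparateCalibrations(ItemBank(ids, a1, d1), ItemBank(ids, a2, d2))


def transformed_calibs(a, d, mu2, sigma2, extra_d2_shift=None):
    """Noiseless separate calibrations implied by theta* = sigma2*theta + mu2."""
    a = np.asarray(a, float)
    d = np.asarray(d, float)
    a2 = a * sigma2
    d2 = d - (a2 / sigma2) * mu2
    if extra_d2_shift is not None:
        d2 = d2 + np.asarray(extra_d2_shift, float)
    return make_calibs(a, d, a2, d2)


A10 = np.array([1.06, 0.78, 0.91, 1.14, 1.19, 0.89, 0.82, 1.00, 1.00, 1.00])
D10 = np.array([-0.17, -0.77, 0.36, 1.37, 2.08, -1.56, 0.72, -0.46, -0.46, -0.46])


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("x, spec, expected", [
    (2.0, LossSpec(p=2), 4.0),
    (0.0, LossSpec(p=0, epsilon=0.01), 0.0),
    (1.0, LossSpec(p=0, epsilon=0.01), 1.0 / 1.01),
    (0.0, LossSpec(p=0.5), 0.0),
    (3.0, LossSpec(p=1, smooth=False), 3.0),
    (3.0, LossSpec(p=0, smooth=False), 1.0),
])
def test_loss_values(x, spec, expected):
    assert loss_value(x, spec) == pytest.approx(expected, abs=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(x1=st.floats(-5, 5), x2=st.floats(-5, 5),
       p=st.sampled_from([0.0, 0.25, 0.5, 1.0, 2.0]),
       smooth=st.booleans())
def test_loss_monotone_in_magnitude(x1, x2, p, smooth):
    spec = LossSpec(p=p, smooth=smooth)
    lo, hi = sorted([abs(x1), abs(x2)])
    assert loss_value(lo, spec) <= loss_value(hi, spec) + 1e-12
    assert loss_value(-x1, spec) == loss_value(x1, spec)


def test_smooth_l0_limits():
    spec = LossSpec(p=0, epsilon=0.01)
    assert loss_value(1e6, spec) == pytest.approx(1.0, abs=1e-9)
    # pointwise convergence to the indicator as epsilon shrinks
    vals = [loss_value(0.5, LossSpec(p=0, epsilon=e))
            for e in (1e-2, 1e-4, 1e-6)]
    assert np.all(np.diff(vals) > 0)
    assert vals[-1] == pytest.approx(1.0, abs=1e-5)
    assert loss_value(0.0, LossSpec(p=0, epsilon=1e-6)) == 0.0


def test_loss_spec_defaults_and_validation():
    assert LossSpec(p=0).epsilon == 0.01
    assert LossSpec(p=0.5).epsilon == 0.001
    with pytest.raises(ValueError):
        LossSpec(p=-1)
    with pytest.raises(ValueError):
        LossSpec(p=1, epsilon=0.0)


# ---------------------------------------------------------------------------
# grid-search oracles
# ---------------------------------------------------------------------------


def profile_grid_1d(outer_vals, inner_residuals, loss):
    """Oracle: minimize sum_i min_k [rho(u_i - k) + rho(v_i(s) - k)] over a grid.

    ``inner_residuals(s)`` returns (u, v) arrays; the per-item nuisance is
    profiled on its own dense grid.
    """
    best_s, best_obj = None, np.inf
    for s in outer_vals:
        u, v = inner_residuals(s)
        lo = np.minimum(u, v) - 0.05
        hi = np.maximum(u, v) + 0.05
        obj = 0.0
        for ui, vi, l, h in zip(u, v, lo, hi):
            kgrid = np.linspace(l, h, 801)
            obj += float(np.min(loss_value(ui - kgrid, loss)
                                + loss_value(vi - kgrid, loss)))
        if obj < best_obj:
            best_s, best_obj = s, obj
    return best_s


# ---------------------------------------------------------------------------
# Haberman SD step
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("p", [0.0, 0.25, 0.5, 1.0, 2.0])
def test_haberman_sd_noiseless_scaling(p):
    calibs = make_calibs(A10, D10, 1.3 * A10, D10)
    sigma2, _ = haberman_sd(calibs, LossSpec(p=p))
    assert sigma2 == pytest.approx(1.3, abs=1e-5)


def test_haberman_sd_identity():
    calibs = make_calibs(A10, D10, A10, D10)
    sigma2, _ = haberman_sd(calibs, LossSpec(p=0))
    assert sigma2 == pytest.approx(1.0, abs=1e-6)


def test_haberman_sd_l0_downweights_outlier_matches_oracle():
    """One doubled discrimination: the L0 fit ignores it entirely."""
    a2 = A10.copy()
    a2[4] *= 2.0
    calibs = make_calibs(A10, D10, a2, D10)
    loss = LossSpec(p=0, epsilon=0.01)
    sigma2, _ = haberman_sd(calibs, loss)
    x, y = np.log(A10), np.log(a2)

    coarse = np.arange(-0.5, 1.0, 1e-3)
    s_star = profile_grid_1d(coarse, lambda s: (x, y - s), loss)
    fine = np.arange(s_star - 2e-3, s_star + 2e-3, 1e-4)
    s_star = profile_grid_1d(fine, lambda s: (x, y - s), loss)

    assert np.log(sigma2) == pytest.approx(s_star, abs=2e-4)
    assert sigma2 == pytest.approx(1.0, abs=0.01)


def test_haberman_sd_immune_to_intercept_drift():
    """The SD step never touches intercepts: output exactly invariant."""
    rng = np.random.default_rng(0)
    base = make_calibs(A10, D10, 1.2 * A10, D10)
    drifted = make_calibs(A10, D10, 1.2 * A10, D10 + rng.normal(0, 5, 10))
    for p in (0.0, 0.5, 2.0):
        s_base, k_base = haberman_sd(base, LossSpec(p=p))
        s_drift, k_drift = haberman_sd(drifted, LossSpec(p=p))
        assert s_base == s_drift
        assert np.array_equal(k_base, k_drift)


def test_haberman_sd_rejects_nonpositive_discrimination():
    with pytest.raises(ValueError):
        ItemBank(("i0",), [-1.0], [0.0])


# ---------------------------------------------------------------------------
# Haberman mean step
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("p", [0.0, 0.5, 2.0])
def test_haberman_mean_intercepts_noiseless(p):
    calibs = transformed_calibs(A10, D10, mu2=1.0, sigma2=1.3)
    mu2, _ = haberman_mean_intercepts(calibs, 1.3, LossSpec(p=p))
    assert mu2 == pytest.approx(1.0, abs=1e-5)


def test_haberman_mean_intercepts_l0_resists_contamination():
    shift = np.zeros(10)
    shift[6] = -1.0
    calibs = transformed_calibs(A10, D10, 1.0, 1.3, extra_d2_shift=shift)
    loss = LossSpec(p=0, epsilon=0.01)
    mu2, _ = haberman_mean_intercepts(calibs, 1.3, loss)
    assert mu2 == pytest.approx(1.0, abs=0.01)

    _, d1, a2, d2 = calibs.arrays()
    c = a2 / 1.3
    coarse = np.arange(0.0, 2.0, 1e-3)

    def resid(mu):
        return d1, d2 + c * mu

    m_star = profile_grid_1d(coarse, resid, loss)
    fine = np.arange(m_star - 2e-3, m_star + 2e-3, 1e-4)
    m_star = profile_grid_1d(fine, resid, loss)
    assert mu2 == pytest.approx(m_star, abs=2e-4)


def test_haberman_mean_intercepts_l2_equals_closed_form():
    """Squared loss follows the contamination: matches the LS solution."""
    shift = np.zeros(10)
    shift[6] = -1.0
    calibs = transformed_calibs(A10, D10, 1.0, 1.3, extra_d2_shift=shift)
    mu2, _ = haberman_mean_intercepts(calibs, 1.3, LossSpec(p=2))
    _, d1, a2, d2 = calibs.arrays()
    c = a2 / 1.3
    mu_ls = -(c @ (d2 - d1)) / (c @ c)
    assert mu2 == pytest.approx(mu_ls, abs=1e-10)
    # a negative intercept shift makes the item easier at time 2, which the
    # squared loss misreads as growth: upward bias
    assert mu2 > 1.0 + 0.02


def test_haberman_mean_intercepts_shift_equivariance():
    """Shifting every d_i2 by -c*(a_i2/sigma2) moves mu2 by exactly +c."""
    rng = np.random.default_rng(12)
    d2 = D10 + rng.normal(0, 0.1, 10)
    calibs = make_calibs(A10, D10, 1.3 * A10, d2)
    c = 0.7
    shifted = make_calibs(A10, D10, 1.3 * A10, d2 - c * (1.3 * A10) / 1.3)
    mu_a, _ = haberman_mean_intercepts(calibs, 1.3, LossSpec(p=2))
    mu_b, _ = haberman_mean_intercepts(shifted, 1.3, LossSpec(p=2))
    assert mu_b - mu_a == pytest.approx(c, abs=1e-10)


def test_haberman_mean_difficulties_noiseless():
    calibs = transformed_calibs(A10, D10, 1.0, 1.3)
    mu2, _ = haberman_mean_difficulties(calibs, 1.3, LossSpec(p=2))
    assert mu2 == pytest.approx(1.0, abs=1e-10)
    identity = make_calibs(A10, D10, A10, D10)
    mu0, _ = haberman_mean_difficulties(identity, 1.0, LossSpec(p=2))
    assert mu0 == pytest.approx(0.0, abs=1e-10)


def test_intercept_variant_less_variable_than_difficulty_variant():
    """Under calibration noise, difficulty linking is the noisier mean step.

    Emulates estimation error by perturbing (a, d) with independent normal
    noise; the induced error on b = d/a inflates the difficulty variant.
    """
    rng = np.random.default_rng(99)
    mus_int, mus_diff = [], []
    for _ in range(200):
        a1 = A10 * np.exp(rng.normal(0, 0.05, 10))
        a2 = 1.3 * A10 * np.exp(rng.normal(0, 0.05, 10))
        d1 = D10 + rng.normal(0, 0.08, 10)
        d2 = D10 - A10 * 1.0 + rng.normal(0, 0.08, 10)
        calibs = make_calibs(a1, d1, a2, d2)
        mu_i, _ = haberman_mean_intercepts(calibs, 1.3, LossSpec(p=2))
        mu_d, _ = haberman_mean_difficulties(calibs, 1.3, LossSpec(p=2))
        mus_int.append(mu_i)
        mus_diff.append(mu_d)
    assert np.var(mus_diff) >= np.var(mus_int)


def test_haberman_link_full_pipeline():
    calibs = transformed_calibs(A10, D10, 1.0, 1.3)
    est = haberman_link(calibs, LossSpec(p=2), "intercepts")
    assert est.mu2 == pytest.approx(1.0, abs=1e-6)
    assert est.sigma2 == pytest.approx(1.3, abs=1e-6)
    assert est.method == "HAB-int"


# ---------------------------------------------------------------------------
# Haebara linking
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("weight", [WeightSpec("uniform"),
                                    WeightSpec("normal", 0.5),
                                    WeightSpec("normal", 2.0)])
def test_haebara_noiseless_recovery(weight):
    calibs = transformed_calibs(A10, D10, 1.0, 1.3)
    est = haebara_link(calibs, weight, LossSpec(p=2))
    assert est.mu2 == pytest.approx(1.0, abs=1e-4)
    assert est.sigma2 == pytest.approx(1.3, abs=1e-4)


def test_haebara_identity():
    calibs = make_calibs(A10, D10, A10, D10)
    est = haebara_link(calibs, WeightSpec("normal", 1.0), LossSpec(p=2))
    assert est.mu2 == pytest.approx(0.0, abs=1e-4)
    assert est.sigma2 == pytest.approx(1.0, abs=1e-4)


def test_haebara_matches_2d_grid_oracle():
    """Noisy 5-item instance: optimum within the oracle's 0.005 resolution."""
    rng = np.random.default_rng(7)
    a1 = A10[:5] * np.exp(rng.normal(0, 0.1, 5))
    d1 = D10[:5] + rng.normal(0, 0.15, 5)
    a2 = 1.3 * A10[:5] * np.exp(rng.normal(0, 0.1, 5))
    d2 = D10[:5] - A10[:5] + rng.normal(0, 0.15, 5)
    calibs = make_calibs(a1, d1, a2, d2)
    weight = WeightSpec("normal", 1.0)
    loss = LossSpec(p=2)
    est = haebara_link(calibs, weight, loss)

    theta, w = weight.grid()
    b1, b2 = d1 / a1, d2 / a2
    best = (np.inf, None, None)
    for mu in np.arange(0.5, 1.5, 0.005):
        for s2 in np.arange(0.9, 1.8, 0.005):
            p1 = expit(np.outer(theta * s2 + mu, a1) - d1)
            p2 = expit(np.outer(theta, a2) - d2)
            obj = float((((p1 - p2) ** 2).sum(axis=1) * w).sum())
            if obj < best[0]:
                best = (obj, mu, s2)
    assert est.mu2 == pytest.approx(best[1], abs=0.006)
    assert est.sigma2 == pytest.approx(best[2], abs=0.006)


def test_weight_spec_validation():
    with pytest.raises(ValueError):
        WeightSpec("triangular")
    with pytest.raises(ValueError):
        WeightSpec("normal", 0.0)
    theta, w = WeightSpec("uniform").grid()
    assert w.sum() == pytest.approx(1.0)
    assert np.all(w >= 0)


def test_trend_estimate_requires_positive_sigma():
    with pytest.raises(ValueError):
        TrendEstimate(mu2=0.0, sigma2=-1.0, method="x")
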