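"""LCGA engine: basis, likelihood, EM steps, diagnostics, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glyctraj.lcga import (
    BasisSpec,
    LcgaParams,
    RankDeficiencyError,
    StackedData,
    appa,
    bic,
    design_matrix,
    design_row,
    e_step,
    fit_em,
    log_likelihood,
    m_step,
    posterior_predict,
    scaled_entropy,
    select_model,
    theta_from_props,
)


# ---------------------------------------------------------------- basis ----


@pytest.mark.parametrize(
    "t, shape, expected",
    [
        (0.0, "logarithmic", (1.0, 0.0)),
        (0.0, "exponential", (1.0, 1.0)),
        (100.0, "cubic", (1.0, 1.0, 1.0, 1.0)),
        (50.0, "linear", (1.0, 0.5)),
        (100.0, "quadratic", (1.0, 1.0, 1.0)),
    ],
)
def test_design_row_values(t, shape, expected):
    np.testing.assert_allclose(design_row(t, BasisSpec(shape)), expected, atol=1e-12)


def test_design_rejects_negative_time():
    with pytest.raises(ValueError):
        design_row(-1.0, BasisSpec("linear"))


def test_basis_validation():
    with pytest.raises(ValueError):
        BasisSpec("spline")
    with pytest.raises(ValueError):
        BasisSpec("linear", time_scale=0.0)


# ----------------------------------------------------------- likelihood ----


def _params(basis, beta, pi, sigma):
    beta = np.atleast_2d(beta)
    return LcgaParams(
        basis=basis, k=beta.shape[0], beta=beta,
        theta=theta_from_props(np.asarray(pi)), sigma=np.asarray(sigma),
    )


def test_single_component_equals_gaussian_loglik(two_level_stacked):
    st_ = two_level_stacked
    basis = BasisSpec("linear")
    beta = np.array([7.0, 0.1])
    sigma = 0.6
    p = _params(basis, beta, [1.0], sigma)
    r = st_.y - st_.X @ beta
    direct = float(
        -0.5 * st_.m * np.log(2 * np.pi * sigma**2) - (r @ r) / (2 * sigma**2)
    )
    assert log_likelihood(st_, p) == pytest.approx(direct, abs=1e-10)


def test_duplicated_component_equals_single(two_level_stacked):
    basis = BasisSpec("linear")
    beta = np.array([7.0, 0.1])
    p1 = _params(basis, beta, [1.0], 0.6)
    p2 = _params(basis, np.vstack([beta, beta]), [0.5, 0.5], 0.6)
    assert log_likelihood(two_level_stacked, p2) == pytest.approx(
        log_likelihood(two_level_stacked, p1), abs=1e-10
    )


def test_loglik_matches_bruteforce_density_product():
    # 3 subjects x 2 points, hand-set parameters, independent arithmetic
    basis = BasisSpec("linear")
    times = [np.array([0.0, 50.0])] * 3
    vals = [np.array([6.0, 6.5]), np.array([8.0, 8.4]), np.array([7.0, 7.2])]
    st_ = StackedData.build((times, vals), basis)
    beta = np.array([[6.1, 0.5], [7.9, 0.6]])
    pi = np.array([0.4, 0.6])
    sigma = 0.5

    def phi(y, mu):
        return np.exp(-0.5 * ((y - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))

    total = 0.0
    for t, y in zip(times, vals):
        like = 0.0
        for j in range(2):
            mu = beta[j, 0] + beta[j, 1] * t / 100.0
            like += pi[j] * phi(y[0], mu[0]) * phi(y[1], mu[1])
        total += np.log(like)
    p = _params(basis, beta, pi, sigma)
    assert log_likelihood(st_, p) == pytest.approx(total, abs=1e-10)


def test_sigma_must_be_positive():
    with pytest.raises(ValueError):
        _params(BasisSpec("linear"), np.array([7.0, 0.0]), [1.0], 0.0)


# ---------------------------------------------------------------- e-step ----


def test_e_step_single_class_is_all_ones(two_level_stacked):
    p = _params(BasisSpec("linear"), np.array([7.0, 0.0]), [1.0], 0.5)
    post, _ = e_step(two_level_stacked, p)
    np.testing.assert_allclose(post, 1.0)


def test_e_step_identical_components_uniform(two_level_stacked):
    beta = np.array([7.0, 0.0])
    p = _params(BasisSpec("linear"), np.vstack([beta] * 3), [1 / 3] * 3, 0.5)
    post, _ = e_step(two_level_stacked, p)
    np.testing.assert_allclose(post, 1 / 3, atol=1e-12)


def test_e_step_separated_components_are_decisive():
    basis = BasisSpec("linear")
    times = [np.linspace(0, 100, 8)]
    vals = [6.0 + 0.0 * times[0]]  # exactly on component 1's curve
    st_ = StackedData.build((times, vals), basis)
    p = _params(basis, np.array([[6.0, 0.0], [9.0, 0.0]]), [0.5, 0.5], 0.5)
    post, _ = e_step(st_, p)
    assert post[0, 0] > 0.999


def test_e_step_no_underflow_with_many_measurements():
    basis = BasisSpec("linear")
    times = [np.linspace(0, 300, 40)]
    vals = [6.0 + np.zeros(40)]
    st_ = StackedData.build((times, vals), basis)
    p = _params(basis, np.array([[6.0, 0.0], [20.0, 0.0]]), [0.5, 0.5], 0.5)
    post, ll = e_step(st_, p)
    assert np.isfinite(ll)
    assert post[0, 0] == pytest.approx(1.0)


# ---------------------------------------------------------------- m-step ----


def _ols(X, y, w=None):
    w = np.ones(len(y)) if w is None else w
    A = X.T @ (X * w[:, None])
    return np.linalg.solve(A, X.T @ (w * y))


def test_m_step_one_hot_reduces_to_per_class_ols(two_level_stacked):
    st_ = two_level_stacked
    basis = BasisSpec("linear")
    post = np.zeros((st_.n, 2))
    post[::2, 0] = 1.0
    post[1::2, 1] = 1.0
    p0 = _params(basis, np.array([[6.0, 0.0], [8.0, 0.0]]), [0.5, 0.5], 0.5)
    p1 = m_step(st_, post, p0)
    for j in range(2):
        mask = post[st_.idx, j] == 1.0
        np.testing.assert_allclose(
            p1.beta[j], _ols(st_.X[mask], st_.y[mask]), atol=1e-10
        )


def test_m_step_uniform_posterior_gives_global_ols(two_level_stacked):
    st_ = two_level_stacked
    basis = BasisSpec("linear")
    post = np.full((st_.n, 2), 0.5)
    p1 = m_step(st_, post, _params(basis, np.zeros((2, 2)) + [7, 0], [0.5, 0.5], 0.5))
    global_beta = _ols(st_.X, st_.y)
    np.testing.assert_allclose(p1.beta[0], global_beta, atol=1e-10)
    np.testing.assert_allclose(p1.beta[1], global_beta, atol=1e-10)


def test_m_step_never_decreases_loglik(two_level_stacked):
    st_ = two_level_stacked
    basis = BasisSpec("linear")
    p = _params(basis, np.array([[6.0, 0.3], [8.5, -0.2]]), [0.3, 0.7], 0.8)
    for _ in range(5):
        post, ll_before = e_step(st_, p)
        p = m_step(st_, post, p)
        _, ll_after = e_step(st_, p)
        assert ll_after >= ll_before - 1e-9
    assert ll_after > -1e9


def test_m_step_singular_design_names_class():
    basis = BasisSpec("cubic")
    times = [np.full(4, 50.0)] * 6  # every measurement at one time point
    vals = [np.full(4, 7.0) + 0.1 * i for i in range(6)]
    st_ = StackedData.build((times, vals), basis)
    post = np.ones((6, 1))
    p = _params(basis, np.array([[7.0, 0, 0, 0]]), [1.0], 0.5)
    with pytest.raises(RankDeficiencyError, match="class 1"):
        m_step(st_, post, p)


# ---------------------------------------------------------------- fit_em ----


def test_fit_k1_equals_closed_form(two_level_stacked):
    st_ = two_level_stacked
    basis = BasisSpec("linear")
    fit = fit_em(st_, basis, 1, seed=0)
    np.testing.assert_allclose(fit.params.beta[0], _ols(st_.X, st_.y), atol=1e-10)
    assert fit.bic == pytest.approx(-2 * fit.loglik + 3 * np.log(st_.n), abs=1e-9)
    assert fit.params.n_params == 3  # 2 curve coefficients + sigma


def test_fit_recovers_well_separated_classes():
    rng = np.random.default_rng(12)
    times, vals, labels = [], [], []
    for i in range(600):
        lab = i % 3
        t = np.sort(rng.uniform(0, 250, 10))
        mu = (6.0, 8.0, 10.0)[lab] - 0.001 * t
        times.append(t)
        vals.append(mu + rng.normal(0, 0.3, 10))
        labels.append(lab)
    fit = fit_em((times, vals), BasisSpec("linear"), 3, n_starts=5, seed=1)
    # canonical order is descending level: fitted 1 ~ level 10, 3 ~ level 6
    expected = {0: 3, 1: 2, 2: 1}
    acc = np.mean([fit.modal_class[i] == expected[lab] for i, lab in enumerate(labels)])
    assert acc >= 0.99
    assert fit.converged


def test_fit_same_seed_is_identical(two_level_data):
    a = fit_em(two_level_data, BasisSpec("linear"), 2, n_starts=4, seed=5)
    b = fit_em(two_level_data, BasisSpec("linear"), 2, n_starts=4, seed=5)
    assert a.loglik == b.loglik
    np.testing.assert_array_equal(a.params.beta, b.params.beta)
    np.testing.assert_array_equal(a.posterior, b.posterior)


def test_fit_classes_ordered_by_descending_level(two_level_data):
    fit = fit_em(two_level_data, BasisSpec("linear"), 2, n_starts=4, seed=5)
    means = (design_matrix(np.linspace(0, 200, 20), fit.params.basis) @ fit.params.beta.T)
    assert means.mean(axis=0)[0] > means.mean(axis=0)[1]


def test_em_trace_is_monotone(two_level_data):
    fit = fit_em(two_level_data, BasisSpec("linear"), 2, n_starts=6, seed=2)
    assert np.all(np.diff(fit.trace) >= -1e-7)
    for tr in fit.burnin_traces:
        assert np.all(np.diff(tr) >= -1e-7)


def test_permutation_invariance(two_level_data):
    times, vals = two_level_data
    fit = fit_em((times, vals), BasisSpec("linear"), 2, n_starts=4, seed=3)
    order = np.random.default_rng(0).permutation(len(times))
    fit2 = fit_em(
        ([times[i] for i in order], [vals[i] for i in order]),
        BasisSpec("linear"), 2, n_starts=4, seed=3,
    )
    assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-10)
    np.testing.assert_allclose(fit2.params.beta, fit.params.beta, atol=1e-8)
    np.testing.assert_allclose(fit2.posterior[np.argsort(order)], fit.posterior, atol=1e-8)


# ----------------------------------------------------------- diagnostics ----


def test_bic_formula():
    assert bic(-100.0, 5, 100) == pytest.approx(200 + 5 * np.log(100))
    with pytest.raises(ValueError):
        bic(0.0, 1, 0)


def test_appa_values():
    post = np.array([[0.9, 0.1], [0.6, 0.4], [0.2, 0.8]])
    modal = np.array([1, 1, 2])
    np.testing.assert_allclose(appa(post, modal), [0.75, 0.8])
    one_hot = np.eye(3)
    np.testing.assert_allclose(appa(one_hot, np.array([1, 2, 3])), 1.0)


def test_appa_empty_class_is_nan_with_warning():
    post = np.array([[0.9, 0.1], [0.8, 0.2]])
    with pytest.warns(UserWarning, match="class 2"):
        out = appa(post, np.array([1, 1]))
    assert np.isnan(out[1]) and out[0] == pytest.approx(0.85)


def test_scaled_entropy_bounds_and_values():
    assert scaled_entropy(np.eye(4)) == pytest.approx(1.0)
    assert scaled_entropy(np.full((5, 4), 0.25)) == pytest.approx(0.0, abs=1e-12)
    rows = np.array([[1.0, 0.0], [0.5, 0.5]])
    assert scaled_entropy(rows) == pytest.approx(0.5)
    assert np.isnan(scaled_entropy(np.ones((3, 1))))


# ------------------------------------------------------------- selection ----


def test_selection_minimum_proportion_forces_k1():
    rng = np.random.default_rng(8)
    times, vals = [], []
    for i in range(30):
        t = np.sort(rng.uniform(0, 200, 6))
        level = 12.0 if i >= 28 else 7.0  # two far outliers
        times.append(t)
        vals.append(level + rng.normal(0, 0.05, 6))
    rep = select_model(
        (times, vals), k_max=2, shapes=("linear",), min_prop=0.1,
        cv_folds=0, seed=0, n_starts=4,
    )
    assert rep.chosen == ("linear", 1)
    row = rep.grid[(rep.grid["shape"] == "linear") & (rep.grid["k"] == 2)].iloc[0]
    assert not row["admissible"]


def test_selection_records_cv_when_requested(two_level_data):
    rep = select_model(
        two_level_data, k_max=2, shapes=("linear",), min_prop=0.03,
        cv_folds=3, seed=0, n_starts=3,
    )
    assert rep.grid["cv_mean_heldout_loglik"].notna().all()
    # held-out fit should prefer the true two-class structure
    cv = rep.grid.set_index("k")["cv_mean_heldout_loglik"]
    assert cv[2] > cv[1]


# ---------------------------------------------------- posterior_predict ----


def test_predict_training_subjects_matches_fit(two_level_data):
    fit = fit_em(two_level_data, BasisSpec("linear"), 2, n_starts=4, seed=5)
    post, modal, report = posterior_predict(two_level_data, fit.params)
    np.testing.assert_allclose(post, fit.posterior, atol=1e-12)
    np.testing.assert_array_equal(modal, fit.modal_class)
    assert report["excluded_ids"] == []


def test_predict_likelihood_tie_returns_prior_ratio():
    basis = BasisSpec("linear")
    p = _params(basis, np.array([[7.0, 1.0], [7.0, -1.0]]), [0.7, 0.3], 0.5)
    post, _, _ = posterior_predict(([np.array([0.0])], [np.array([7.0])]), p)
    np.testing.assert_allclose(post[0], [0.7, 0.3], atol=1e-12)


def test_predict_excludes_empty_subjects():
    basis = BasisSpec("linear")
    p = _params(basis, np.array([[7.0, 0.0]]), [1.0], 0.5)
    post, modal, report = posterior_predict(
        ([np.array([0.0, 1.0]), np.array([])], [np.array([7.0, 7.1]), np.array([])]), p
    )
    assert post.shape == (1, 1)
    assert report["excluded_ids"] == [1]


# -------------------------------------------------------- property tests ----


@given(
    seed=st.integers(0, 10_000),
    k=st.integers(2, 4),
    n=st.integers(3, 12),
)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_posterior_rows_normalize_and_entropy_bounded(seed, k, n):
    rng = np.random.default_rng(seed)
    basis = BasisSpec("linear")
    times = [np.sort(rng.uniform(0, 100, rng.integers(1, 6))) for _ in range(n)]
    vals = [rng.normal(7, 1.5, len(t)) for t in times]
    beta = rng.normal(7, 1, size=(k, 2))
    pi = rng.dirichlet(np.ones(k))
    p = _params(basis, beta, pi, float(rng.uniform(0.2, 1.5)))
    post, ll = e_step((times, vals), p)
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
    assert np.isfinite(ll)
    se = scaled_entropy(post)
    assert -1e-9 <= se <= 1 + 1e-9
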