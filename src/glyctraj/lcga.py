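"""Latent class growth analysis (LCGA) for longitudinal biomarker trajectories.

LCGA — also called group-based trajectory modelling — assumes the population
is a finite mixture of K latent classes, each following a fixed-effect mean
curve over time.  For subject i with measurements ``y_ij`` at times ``t_ij``
the likelihood is

    L_i = sum_k pi_k * prod_j Normal(y_ij | x(t_ij)' beta_k, sigma^2)

where ``x(t)`` is a shape-specific basis expansion of time, ``pi_k`` are
mixing proportions (intercept-only multinomial logit) and ``sigma`` is the
residual standard deviation (shared across classes by default, optionally
class-specific).  There are no random effects: within a class all subjects
share one mean curve, and all within-class variation is residual.

Estimation is EM with a burn-in-then-refine multi-start strategy; model
selection combines BIC with a minimum-class-proportion rule and optional
subject-level cross-validation.  Diagnostics include the average posterior
probability of assignment (APPA) and the scaled entropy.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

SHAPES = ("linear", "quadratic", "cubic", "logarithmic", "exponential")

#: basis dimension by shape (intercept included)
_SHAPE_DIM = {
    "linear": 2,
    "quadratic": 3,
    "cubic": 4,
    "logarithmic": 2,
    "exponential": 2,
}


class LcgaError(Exception):
    """Base class for LCGA estimation errors."""


class RankDeficiencyError(LcgaError):
    """Weighted design matrix is singular for some class."""


class FitFailureError(LcgaError):
    """No EM start reached a finite likelihood."""


class SelectionError(LcgaError):
    """No admissible model in the selection grid."""


# ---------------------------------------------------------------------------
# Time basis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BasisSpec:
    """Time-link shape for the class mean curves.

    Parameters
    ----------
    shape
        One of ``linear``, ``quadratic``, ``cubic``, ``logarithmic``,
        ``exponential``.
    time_scale
        Divisor applied to time (weeks) before evaluating the polynomial
        bases; keeps coefficients O(1) over multi-year follow-up.
    exp_timescale_weeks
        Decay constant of the exponential basis ``exp(-t / tau)``.  The
        default (26 weeks, about six months) puts most of the decay in the
        first ~30 weeks after baseline.
    """

    shape: str
    time_scale: float = 100.0
    exp_timescale_weeks: float = 26.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        if self.time_scale <= 0:
            raise ValueError("time_scale must be > 0")
        if self.exp_timescale_weeks <= 0:
            raise ValueError("exp_timescale_weeks must be > 0")

    @property
    def dimension(self) -> int:
        return _SHAPE_DIM[self.shape]


def design_matrix(t_weeks: np.ndarray, basis: BasisSpec) -> np.ndarray:
    """Evaluate the basis at times ``t_weeks`` (>= 0), one row per time.

    linear       (1, s),  s = t / time_scale
    quadratic    (1, s, s^2)
    cubic        (1, s, s^2, s^3)
    logarithmic  (1, log(t + 1))         -- t in weeks
    exponential  (1, exp(-t / tau))
    """
    t = np.asarray(t_weeks, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative (weeks from baseline)")
    s = t / basis.time_scale
    if basis.shape == "linear":
        cols = [np.ones_like(s), s]
    elif basis.shape == "quadratic":
        cols = [np.ones_like(s), s, s**2]
    elif basis.shape == "cubic":
        cols = [np.ones_like(s), s, s**2, s**3]
    elif basis.shape == "logarithmic":
        cols = [np.ones_like(s), np.log(t + 1.0)]
    else:  # exponential
        cols = [np.ones_like(s), np.exp(-t / basis.exp_timescale_weeks)]
    return np.column_stack(cols)


def design_row(t_weeks: float, basis: BasisSpec) -> np.ndarray:
    """Single-time version of :func:`design_matrix`."""
    return design_matrix(np.array([t_weeks]), basis)[0]


def mean_curve(beta_k: np.ndarray, t_weeks: np.ndarray, basis: BasisSpec) -> np.ndarray:
    """Class mean trajectory evaluated on a time grid."""
    return design_matrix(t_weeks, basis) @ np.asarray(beta_k, dtype=float)


# ---------------------------------------------------------------------------
# Parameters and fits
# ---------------------------------------------------------------------------


def softmax_props(theta: np.ndarray) -> np.ndarray:
    """Mixing proportions from (k-1) multinomial-logit intercepts (last class
    is the reference with logit 0)."""
    z = np.concatenate([np.asarray(theta, dtype=float).ravel(), [0.0]])
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def theta_from_props(pi: np.ndarray) -> np.ndarray:
    pi = np.clip(np.asarray(pi, dtype=float), 1e-12, None)
    return np.log(pi[:-1] / pi[-1])


@dataclass
class LcgaParams:
    """Parameters of a K-class growth mixture.

    ``beta`` is (k, d): one coefficient row per class on the basis of
    ``basis``.  ``theta`` holds the (k-1) mixing logits (last class is the
    reference).  ``sigma`` is the residual SD in outcome units; a scalar when
    shared, a length-k vector when class-specific.
    """

    basis: BasisSpec
    k: int
    beta: np.ndarray
    theta: np.ndarray
    sigma: np.ndarray  # shape () or (k,)

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.beta.shape != (self.k, self.basis.dimension):
            raise ValueError(
                f"beta must be ({self.k}, {self.basis.dimension}), got {self.beta.shape}"
            )
        if self.theta.shape != (self.k - 1,):
            raise ValueError(f"theta must have length k-1={self.k - 1}")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be > 0")
        if self.sigma.ndim not in (0, 1) or (
            self.sigma.ndim == 1 and self.sigma.shape != (self.k,)
        ):
            raise ValueError("sigma must be scalar or length-k")

    @property
    def pi(self) -> np.ndarray:
        return softmax_props(self.theta)

    @property
    def sigma_by_class(self) -> np.ndarray:
        return np.broadcast_to(self.sigma, (self.k,))

    @property
    def n_params(self) -> int:
        n_sigma = 1 if self.sigma.ndim == 0 else self.k
        return self.k * self.basis.dimension + (self.k - 1) + n_sigma

    def to_dict(self) -> dict:
        return {
            "basis": {
                "shape": self.basis.shape,
                "time_scale": self.basis.time_scale,
                "exp_timescale_weeks": self.basis.exp_timescale_weeks,
            },
            "k": self.k,
            "beta": self.beta.tolist(),
            "theta": self.theta.tolist(),
            "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LcgaParams":
        return cls(
            basis=BasisSpec(**d["basis"]),
            k=int(d["k"]),
            beta=np.asarray(d["beta"], dtype=float),
            theta=np.asarray(d["theta"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
        )


@dataclass
class LcgaFit:
    """A fitted LCGA model with posteriors and separation diagnostics."""

    params: LcgaParams
    loglik: float
    bic: float
    posterior: np.ndarray  # (n, k)
    modal_class: np.ndarray  # (n,), labels 1..k
    class_proportions: np.ndarray  # modal-assignment fractions, (k,)
    appa: np.ndarray  # (k,)
    scaled_entropy: float
    n_subjects: int
    converged: bool
    n_starts_used: int
    subject_ids: list = field(default_factory=list)
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    burnin_traces: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "bic": self.bic,
            "class_proportions": self.class_proportions.tolist(),
            "appa": self.appa.tolist(),
            "scaled_entropy": self.scaled_entropy,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def posterior_frame(self) -> pd.DataFrame:
        k = self.params.k
        ids = self.subject_ids if self.subject_ids else list(range(self.n_subjects))
        df = pd.DataFrame(self.posterior, columns=[f"p_{j + 1}" for j in range(k)])
        df.insert(0, "subject_id", ids)
        df["modal_class"] = self.modal_class
        return df


# ---------------------------------------------------------------------------
# Long-format stacking
# ---------------------------------------------------------------------------


class StackedData:
    """Measurements stacked in long format with a subject index.

    Accepts any object with a ``trajectories()`` method returning
    ``(ids, times_list, values_list)`` (e.g. :class:`glyctraj.cohort.Cohort`),
    or a ``(times_list, values_list)`` pair of sequences of 1-d arrays.
    """

    def __init__(self, y, X, subject_index, n_subjects, ids):
        self.y = y
        self.X = X
        self.idx = subject_index
        self.n = n_subjects
        self.ids = ids
        self.counts = np.bincount(subject_index, minlength=n_subjects).astype(float)
        self.m = y.size

    @classmethod
    def build(cls, cohort, basis: BasisSpec) -> "StackedData":
        ids, times_list, values_list = _extract_trajectories(cohort)
        if len(times_list) == 0:
            raise ValueError("empty cohort")
        t = np.concatenate([np.asarray(ti, dtype=float) for ti in times_list])
        y = np.concatenate([np.asarray(vi, dtype=float) for vi in values_list])
        idx = np.repeat(np.arange(len(times_list)), [len(ti) for ti in times_list])
        X = design_matrix(t, basis)
        return cls(y, X, idx, len(times_list), ids)


def _extract_trajectories(cohort):
    if hasattr(cohort, "trajectories"):
        return cohort.trajectories()
    times_list, values_list = cohort
    return list(range(len(times_list))), times_list, values_list


def _subject_class_loglik(st: StackedData, params: LcgaParams) -> np.ndarray:
    """(n, k) matrix of per-subject log densities under each class curve."""
    k = params.k
    sig = params.sigma_by_class
    out = np.empty((st.n, k))
    for j in range(k):
        r = st.y - st.X @ params.beta[j]
        ssq = np.bincount(st.idx, weights=r * r, minlength=st.n)
        out[:, j] = -0.5 * st.counts * np.log(2.0 * np.pi * sig[j] ** 2) - ssq / (
            2.0 * sig[j] ** 2
        )
    return out


# ---------------------------------------------------------------------------
# Likelihood, E-step, M-step
# ---------------------------------------------------------------------------


def log_likelihood(cohort, params: LcgaParams) -> float:
    """Mixture log-likelihood sum_i log sum_k pi_k prod_j phi(y_ij)."""
    st = cohort if isinstance(cohort, StackedData) else StackedData.build(cohort, params.basis)
    ll_ik = _subject_class_loglik(st, params)
    return float(logsumexp(ll_ik + np.log(params.pi), axis=1).sum())


def e_step(cohort, params: LcgaParams):
    """Posterior class membership probabilities (rows normalized via
    log-sum-exp) and the current log-likelihood."""
    st = cohort if isinstance(cohort, StackedData) else StackedData.build(cohort, params.basis)
    logw = _subject_class_loglik(st, params) + np.log(np.clip(params.pi, 1e-300, None))
    norm = logsumexp(logw, axis=1)
    post = np.exp(logw - norm[:, None])
    return post, float(norm.sum())


def m_step(cohort, posterior: np.ndarray, params: LcgaParams) -> LcgaParams:
    """Maximize the expected complete-data log-likelihood.

    pi_k is the mean posterior, beta_k the posterior-weighted least-squares
    solution pooling all of a subject's measurements at its weight, and
    sigma^2 the pooled weighted mean squared residual.  Never decreases the
    observed-data log-likelihood.
    """
    st = cohort if isinstance(cohort, StackedData) else StackedData.build(cohort, params.basis)
    k = params.k
    d = params.basis.dimension
    pi = posterior.mean(axis=0)
    beta = params.beta.copy()
    ssq_k = np.empty(k)
    wsum_k = np.empty(k)
    for j in range(k):
        w = posterior[st.idx, j]
        wtot = w.sum()
        wsum_k[j] = wtot
        if wtot < 1e-10 * st.m:
            # class has effectively no mass: freeze its curve
            r = st.y - st.X @ beta[j]
            ssq_k[j] = float((w * r * r).sum())
            continue
        Xw = st.X * w[:, None]
        A = st.X.T @ Xw
        b = Xw.T @ st.y
        # guard against a degenerate weighted design (e.g. all mass at one time)
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise RankDeficiencyError(
                f"weighted design matrix is rank-deficient for class {j + 1} "
                f"(condition number {cond:.3g}, basis dimension {d})"
            )
        beta[j] = np.linalg.solve(A, b)
        r = st.y - st.X @ beta[j]
        ssq_k[j] = float((w * r * r).sum())
    if params.sigma.ndim == 0:
        sigma = np.sqrt(max(ssq_k.sum() / st.m, 1e-12))
        sigma = np.asarray(sigma)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            sig2 = ssq_k / np.maximum(wsum_k, 1e-12)
        sigma = np.sqrt(np.clip(sig2, 1e-12, None))
    return LcgaParams(
        basis=params.basis, k=k, beta=beta, theta=theta_from_props(pi), sigma=sigma
    )


# ---------------------------------------------------------------------------
# EM with multi-start
# ---------------------------------------------------------------------------


def _ols(st: StackedData):
    beta, *_ = np.linalg.lstsq(st.X, st.y, rcond=None)
    resid = st.y - st.X @ beta
    sigma = np.sqrt(max(float(resid @ resid) / st.m, 1e-12))
    return beta, sigma


def _initial_params(st, basis, k, seed, n_starts, shared_sigma):
    """Start 1 is deterministic: the global OLS curve replicated with ordered
    intercept offsets placed at the k quantiles of the subject-level mean
    residuals (so initial classes straddle the real level strata); later
    starts add Gaussian perturbations scaled to the data."""
    beta0, sigma0 = _ols(st)
    col_scale = np.sqrt((st.X**2).mean(axis=0))
    starts = []
    rng = np.random.default_rng(seed)
    if k > 1:
        resid = st.y - st.X @ beta0
        subj_mean = np.bincount(st.idx, weights=resid, minlength=st.n) / st.counts
        # tail-anchored quantiles: rare classes tend to live in the extremes
        offsets = np.quantile(subj_mean, np.linspace(0.02, 0.98, k))
    else:
        offsets = np.zeros(1)
    base = np.tile(beta0, (k, 1))
    base[:, 0] += offsets
    sigma_init = np.asarray(sigma0) if shared_sigma else np.full(k, sigma0)
    starts.append(
        LcgaParams(basis=basis, k=k, beta=base, theta=np.zeros(k - 1), sigma=sigma_init)
    )
    for _ in range(n_starts - 1):
        noise = rng.normal(0.0, 0.7 * sigma0, size=base.shape) / col_scale[None, :]
        starts.append(
            LcgaParams(
                basis=basis,
                k=k,
                beta=base + noise,
                theta=np.zeros(k - 1),
                sigma=sigma_init,
            )
        )
    return starts


def _run_em(st, params, n_iters, tol=None):
    """Run EM; returns (params, trace).  Stops early when the relative
    log-likelihood change drops below tol (if given)."""
    trace = []
    post, ll = e_step(st, params)
    trace.append(ll)
    for _ in range(n_iters):
        params = m_step(st, post, params)
        post, ll_new = e_step(st, params)
        trace.append(ll_new)
        if tol is not None and abs(ll_new - ll) <= tol * max(abs(ll), 1.0):
            return params, np.asarray(trace), True
        ll = ll_new
    return params, np.asarray(trace), tol is None


def _canonical_order(st: StackedData, params: LcgaParams) -> np.ndarray:
    """Permutation putting classes in descending mean fitted level over the
    cohort's observed time grid (resolves label switching)."""
    means = (st.X @ params.beta.T).mean(axis=0)
    return np.argsort(-means, kind="stable")


def fit_em(
    cohort,
    basis: BasisSpec,
    k: int,
    n_starts: int = 20,
    burn_in_iters: int = 30,
    tol: float = 1e-6,
    max_iters: int = 500,
    seed: int = 0,
    shared_sigma: bool = True,
) -> LcgaFit:
    """Fit a K-class LCGA by multi-start EM.

    Each random start runs ``burn_in_iters`` EM iterations; the start with
    the best burn-in log-likelihood is refined until the relative change in
    log-likelihood falls below ``tol`` (or ``max_iters``).  Classes are then
    relabeled in descending order of mean fitted level.  Deterministic given
    ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    st = cohort if isinstance(cohort, StackedData) else StackedData.build(cohort, basis)
    if st.n < k:
        raise ValueError(f"cohort has {st.n} subjects < k={k}")

    if k == 1:
        beta0, sigma0 = _ols(st)
        params = LcgaParams(
            basis=basis,
            k=1,
            beta=beta0[None, :],
            theta=np.zeros(0),
            sigma=np.asarray(sigma0) if shared_sigma else np.array([sigma0]),
        )
        post, ll = e_step(st, params)
        return _finalize(st, params, ll, post, True, 1, np.asarray([ll]), [])

    starts = _initial_params(st, basis, k, seed, n_starts, shared_sigma)
    burn_results = []
    burn_traces = []
    for p0 in starts:
        try:
            p1, trace, _ = _run_em(st, p0, burn_in_iters)
        except RankDeficiencyError:
            raise
        except np.linalg.LinAlgError:
            continue
        if np.isfinite(trace[-1]):
            burn_results.append((trace[-1], p1))
            burn_traces.append(trace)
    if not burn_results:
        raise FitFailureError("no EM start achieved a finite likelihood")
    best_ll, best_params = max(burn_results, key=lambda t: t[0])
    params, trace, converged = _run_em(st, best_params, max_iters, tol=tol)
    post, ll = e_step(st, params)
    return _finalize(st, params, ll, post, converged, len(burn_results), trace, burn_traces)


def _finalize(st, params, ll, post, converged, n_starts_used, trace, burn_traces):
    order = _canonical_order(st, params)
    pi = params.pi[order]
    params = LcgaParams(
        basis=params.basis,
        k=params.k,
        beta=params.beta[order],
        theta=theta_from_props(pi),
        sigma=params.sigma if params.sigma.ndim == 0 else params.sigma[order],
    )
    post = post[:, order]
    modal = post.argmax(axis=1) + 1
    props = np.bincount(modal - 1, minlength=params.k) / st.n
    fit = LcgaFit(
        params=params,
        loglik=ll,
        bic=bic(ll, params.n_params, st.n),
        posterior=post,
        modal_class=modal,
        class_proportions=props,
        appa=appa(post, modal),
        scaled_entropy=scaled_entropy(post) if params.k >= 2 else float("nan"),
        n_subjects=st.n,
        converged=bool(converged),
        n_starts_used=n_starts_used,
        subject_ids=list(st.ids),
        trace=np.asarray(trace),
        burnin_traces=burn_traces,
    )
    return fit


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def bic(loglik: float, n_params: int, n_subjects: int) -> float:
    """Bayesian Information Criterion, -2 loglik + n_params log(n).

    ``n_subjects`` counts subjects (the independent units of the mixture),
    not measurements.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_subjects)


def appa(posterior: np.ndarray, modal_class: np.ndarray) -> np.ndarray:
    """Average posterior probability of assignment per class.

    APPA_k = mean of p_ik over subjects modally assigned to class k; NaN
    (with a warning) for classes with no modal members.
    """
    posterior = np.asarray(posterior, dtype=float)
    k = posterior.shape[1]
    out = np.full(k, np.nan)
    for j in range(k):
        mask = modal_class == j + 1
        if mask.any():
            out[j] = posterior[mask, j].mean()
        else:
            warnings.warn(f"class {j + 1} has no modal members; APPA undefined")
    return out


def scaled_entropy(posterior: np.ndarray) -> float:
    """1 - (total posterior entropy) / (n log k); 1 = perfect separation,
    0 = uninformative.  Undefined (NaN) for k = 1."""
    posterior = np.asarray(posterior, dtype=float)
    n, k = posterior.shape
    if k < 2:
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(posterior > 0, posterior * np.log(posterior), 0.0)
    ent = -plogp.sum()
    return float(1.0 - ent / (n * np.log(k)))


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionReport:
    """Grid of candidate fits with the BIC + minimum-proportion decision."""

    grid: pd.DataFrame
    chosen: tuple  # (shape, k)
    rationale: str
    best_fit: LcgaFit | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "grid": self.grid.to_dict(orient="records"),
            "chosen": {"shape": self.chosen[0], "k": int(self.chosen[1])},
            "rationale": self.rationale,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def select_model(
    cohort,
    k_max: int = 10,
    shapes: Sequence[str] = SHAPES,
    min_prop: float = 0.03,
    cv_folds: int = 10,
    seed: int = 0,
    n_starts: int = 20,
    burn_in_iters: int = 30,
    max_iters: int = 500,
    use_modal_proportions: bool = True,
    basis_kwargs: dict | None = None,
) -> SelectionReport:
    """Fit every (shape, k) candidate and apply the selection rule.

    A cell is admissible when its smallest class proportion is at least
    ``min_prop``.  The chosen K is the largest K at which *every* shape is
    still admissible; among the shapes at that K, the one with the lowest BIC
    wins.  Held-out log-likelihood from subject-level K-fold CV (when
    ``cv_folds >= 2``) is recorded per cell as corroboration only — it never
    overrides the BIC + proportion rule.
    """
    basis_kwargs = basis_kwargs or {}
    rows = []
    fits = {}
    ids, times_list, values_list = _extract_trajectories(cohort)
    for shape in shapes:
        basis = BasisSpec(shape, **basis_kwargs)
        st = StackedData.build((times_list, values_list), basis)
        st.ids = list(ids)
        for k in range(1, k_max + 1):
            fit = fit_em(
                st,
                basis,
                k,
                n_starts=n_starts,
                burn_in_iters=burn_in_iters,
                max_iters=max_iters,
                seed=seed,
            )
            props = fit.class_proportions if use_modal_proportions else fit.params.pi
            minp = float(props.min())
            fits[(shape, k)] = fit
            rows.append(
                {
                    "shape": shape,
                    "k": k,
                    "loglik": fit.loglik,
                    "bic": fit.bic,
                    "min_class_proportion": minp,
                    "admissible": minp >= min_prop,
                    "cv_mean_heldout_loglik": np.nan,
                }
            )
            logger.info(
                "selection grid: shape=%s k=%d bic=%.1f min_prop=%.4f", shape, k, fit.bic, minp
            )
    grid = pd.DataFrame(rows)

    if cv_folds >= 2:
        _add_cv_column(grid, ids, times_list, values_list, cv_folds, seed, n_starts,
                       burn_in_iters, max_iters, basis_kwargs)

    admissible_by_k = grid.groupby("k")["admissible"].all()
    candidates = [int(k) for k, ok in admissible_by_k.items() if ok]
    if not candidates:
        raise SelectionError("no (shape, k) cell satisfies the minimum-proportion rule")
    chosen_k = max(candidates)
    at_k = grid[(grid["k"] == chosen_k)]
    chosen_shape = at_k.loc[at_k["bic"].idxmin(), "shape"]
    rationale = (
        f"K={chosen_k} is the largest class count at which every shape keeps all "
        f"class proportions >= {min_prop:.0%}; among shapes at K={chosen_k}, "
        f"{chosen_shape} minimizes BIC."
    )
    return SelectionReport(
        grid=grid,
        chosen=(chosen_shape, chosen_k),
        rationale=rationale,
        best_fit=fits[(chosen_shape, chosen_k)],
    )


def _add_cv_column(grid, ids, times_list, values_list, cv_folds, seed, n_starts,
                   burn_in_iters, max_iters, basis_kwargs):
    n = len(times_list)
    rng = np.random.default_rng(seed + 1)
    fold = rng.permuted(np.arange(n) % cv_folds)
    cv_vals = np.full(len(grid), np.nan)
    for row_i, row in grid.iterrows():
        basis = BasisSpec(row["shape"], **basis_kwargs)
        k = int(row["k"])
        heldout = []
        for f in range(cv_folds):
            tr = [i for i in range(n) if fold[i] != f]
            te = [i for i in range(n) if fold[i] == f]
            if len(tr) < k or not te:
                continue
            fit = fit_em(
                ([times_list[i] for i in tr], [values_list[i] for i in tr]),
                basis,
                k,
                n_starts=n_starts,
                burn_in_iters=burn_in_iters,
                max_iters=max_iters,
                seed=seed,
            )
            st_te = StackedData.build(
                ([times_list[i] for i in te], [values_list[i] for i in te]), basis
            )
            ll_ik = _subject_class_loglik(st_te, fit.params)
            heldout.extend(logsumexp(ll_ik + np.log(fit.params.pi), axis=1).tolist())
        if heldout:
            cv_vals[row_i] = float(np.mean(heldout))
    grid["cv_mean_heldout_loglik"] = cv_vals


# ---------------------------------------------------------------------------
# Posterior prediction for new subjects
# ---------------------------------------------------------------------------


def posterior_predict(new_subjects, params: LcgaParams):
    """Posterior class probabilities for new subjects under frozen parameters.

    ``new_subjects`` is anything :class:`StackedData` accepts.  Subjects with
    zero measurements are excluded and listed in the returned report rather
    than silently dropped.

    Returns
    -------
    posterior : (n_ok, k) array
    modal : (n_ok,) array of labels 1..k
    report : dict with ``ids`` (included) and ``excluded_ids``
    """
    ids, times_list, values_list = _extract_trajectories(new_subjects)
    keep, excluded = [], []
    for i, t in enumerate(times_list):
        (keep if len(t) > 0 else excluded).append(i)
    if not keep:
        raise ValueError("no subject has any measurement")
    st = StackedData.build(
        ([times_list[i] for i in keep], [values_list[i] for i in keep]), params.basis
    )
    post, _ = e_step(st, params)
    modal = post.argmax(axis=1) + 1
    report = {
        "ids": [ids[i] for i in keep],
        "excluded_ids": [ids[i] for i in excluded],
    }
    return post, modal, report
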