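"""End-to-end analyses: trajectory extraction + HHF association, baseline
sensitivity, diagnosis-date re-seeding sensitivity, and split-sample
predictive validation.

Each stage consumes the raw registry tables (synthetic or real, same
schemas) and logs its seeds and counts; everything is reproducible
bit-for-bit given the config seeds.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import cohort as cohort_mod
from . import lcga
from . import survival as surv
from .cohort import Cohort, build_cohort
from .lcga import BasisSpec, LcgaFit, fit_em, posterior_predict, select_model, mean_curve

logger = logging.getLogger(__name__)

ETHNICITY_LEVELS = ("Malay", "Indian", "Other")  # Chinese is the reference


@dataclass
class AnalysisConfig:
    """Settings shared by the pipeline stages.

    Seeds: ``ddd_seed`` drives diagnosis-date imputation, ``lcga_seed`` the
    EM multi-start draws, ``split_seed`` the train/validation split.
    """

    k_max: int = 10
    shapes: tuple = lcga.SHAPES
    min_prop: float = 0.03
    cv_folds: int = 0
    n_starts: int = 20
    burn_in_iters: int = 30
    max_iters: int = 500
    fixed_shape: str | None = None  # skip the selection grid when both set
    fixed_k: int | None = None
    reference_class: int | None = None  # Cox reference; default lowest-level class
    split_fraction: float = 0.8
    window_width_weeks: float = 50.0
    n_windows: int = 7
    baseline_shift_weeks: float = 50.0
    ddd_seed: int = 0
    lcga_seed: int = 0
    split_seed: int = 0
    censor_at: str = "last_measurement"

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.window_width_weeks <= 0:
            raise ValueError("window_width_weeks must be > 0")

    def fit_kwargs(self) -> dict:
        return dict(
            n_starts=self.n_starts,
            burn_in_iters=self.burn_in_iters,
            max_iters=self.max_iters,
            seed=self.lcga_seed,
        )


@dataclass
class AnalysisReport:
    selection: lcga.SelectionReport | None
    fit: LcgaFit
    cohort: Cohort
    km_by_class: dict
    logrank_omnibus: surv.LogrankResult
    logrank_pairwise: pd.DataFrame
    cox: surv.CoxFit
    extras: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        d = {
            "n_subjects": self.fit.n_subjects,
            "chosen": None
            if self.selection is None
            else {"shape": self.selection.chosen[0], "k": int(self.selection.chosen[1])},
            "class_proportions": self.fit.class_proportions.tolist(),
            "appa": self.fit.appa.tolist(),
            "scaled_entropy": self.fit.scaled_entropy,
            "bic": self.fit.bic,
            "logrank_chi2": self.logrank_omnibus.statistic,
            "logrank_p": self.logrank_omnibus.p_value,
            "cox_table": self.cox.summary().round(6).reset_index().to_dict(orient="records"),
        }
        return d

    def write(self, directory) -> None:
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "report.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)
        self.fit.posterior_frame().to_csv(directory / "assignments.csv", index=False)
        self.cox.summary().to_csv(directory / "cox_table.csv")
        km_rows = []
        for label, curve in self.km_by_class.items():
            df = curve.to_frame()
            df.insert(0, "class", label)
            km_rows.append(df)
        pd.concat(km_rows).to_csv(directory / "km_curves.csv", index=False)
        if self.selection is not None:
            self.selection.to_json(directory / "selection.json")


# ---------------------------------------------------------------------------
# Cox design construction
# ---------------------------------------------------------------------------


def build_cox_design(
    cohort: Cohort, class_labels: np.ndarray, k: int, reference_class: int | None = None
) -> pd.DataFrame:
    """Covariate frame: class indicators (reference omitted), male, ethnicity
    indicators (Chinese reference), age at diagnosis, ten prior-complication
    indicators and a missing-complications indicator.

    Subjects with unrecorded prior complications keep zero flags and raise
    the ``missing_prior_complications`` indicator instead of being dropped.
    ``reference_class`` defaults to class ``k`` — the lowest mean trajectory
    under the canonical (descending-level) class ordering.
    """
    if reference_class is None:
        reference_class = k
    rows = {}
    for j in range(1, k + 1):
        if j != reference_class:
            rows[f"class_{j}"] = (class_labels == j).astype(float)
    rows["male"] = np.array([s.covariates["sex"] == "M" for s in cohort.subjects], dtype=float)
    eth = np.array([s.covariates["ethnicity"] for s in cohort.subjects])
    for level in ETHNICITY_LEVELS:
        rows[f"ethnicity_{level}"] = (eth == level).astype(float)
    rows["age_at_diagnosis"] = np.array(
        [s.covariates["age_at_diagnosis"] for s in cohort.subjects], dtype=float
    )
    flags = np.array(
        [[s.covariates[c] for c in cohort_mod.PRIOR_COMPLICATION_COLS] for s in cohort.subjects],
        dtype=float,
    )
    missing = np.isnan(flags).any(axis=1).astype(float)
    flags = np.nan_to_num(flags, nan=0.0)
    for i, c in enumerate(cohort_mod.PRIOR_COMPLICATION_COLS):
        rows[c] = flags[:, i]
    rows["missing_prior_complications"] = missing
    return pd.DataFrame(rows, index=[s.id for s in cohort.subjects])


def prune_nonidentifiable_indicators(design: pd.DataFrame, events) -> pd.DataFrame:
    """Drop 0/1 indicator columns whose partial-likelihood MLE is infinite.

    A binary covariate with zero events among carriers (or among
    non-carriers) has a monotone partial likelihood; its coefficient
    diverges and would dominate risk ranking with pure noise.  At registry
    scale every indicator carries events, but in small cohorts rare classes
    or rare complications often do not, so those columns are excluded from
    that fit (logged).
    """
    events = np.asarray(events, dtype=bool)
    keep = []
    for col in design.columns:
        v = design[col].to_numpy()
        is_indicator = np.all(np.isin(v, (0.0, 1.0)))
        if is_indicator and 0 < v.sum() < len(v):
            carriers = v > 0
            if events[carriers].sum() == 0 or events[~carriers].sum() == 0:
                logger.info("dropping non-identifiable indicator %r (no events on one side)",
                            col)
                continue
        keep.append(col)
    out = design[keep]
    # small cohorts can also make columns collinear (duplicated rare flags,
    # empty factor levels); keep a maximal independent subset, original order
    A = out.to_numpy(dtype=float)
    A = A - A.mean(axis=0)
    if A.shape[1] > 1:
        from scipy.linalg import qr

        _, r, piv = qr(A, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        rank = int((diag > max(diag.max(), 1e-300) * 1e-10).sum())
        if rank < A.shape[1]:
            chosen = sorted(piv[:rank])
            dropped = [c for i, c in enumerate(out.columns) if i not in chosen]
            logger.info("dropping collinear/empty columns: %s", dropped)
            out = out.iloc[:, chosen]
    return out


def _times_events(cohort: Cohort):
    t = np.array([s.event_weeks for s in cohort.subjects], dtype=float)
    e = np.array([s.event_indicator for s in cohort.subjects], dtype=int)
    return t, e


# ---------------------------------------------------------------------------
# Class matching across refits
# ---------------------------------------------------------------------------


def match_classes(
    params_a: lcga.LcgaParams, params_b: lcga.LcgaParams, t_grid=None
) -> np.ndarray:
    """Optimal one-to-one matching of B's classes onto A's.

    Minimizes the summed squared distance between class mean curves over a
    common time grid (Hungarian assignment).  Returns ``m`` with
    ``m[j_b] = j_a`` (0-based), i.e. the A-label for each B class.
    """
    if params_a.k != params_b.k:
        raise ValueError("class matching requires equal k")
    if t_grid is None:
        t_grid = np.linspace(0.0, 250.0, 26)
    curves_a = np.stack([mean_curve(b, t_grid, params_a.basis) for b in params_a.beta])
    curves_b = np.stack([mean_curve(b, t_grid, params_b.basis) for b in params_b.beta])
    cost = ((curves_b[:, None, :] - curves_a[None, :, :]) ** 2).sum(axis=2)
    row, col = linear_sum_assignment(cost)
    m = np.empty(params_b.k, dtype=int)
    m[row] = col
    return m


# ---------------------------------------------------------------------------
# Primary analysis
# ---------------------------------------------------------------------------


def run_primary_analysis(
    measurements: pd.DataFrame,
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    config: AnalysisConfig,
) -> AnalysisReport:
    """Cohort build -> model selection (or fixed fit) -> KM / log-rank ->
    covariate-adjusted Cox with class indicators."""
    logger.info("building cohort (ddd_seed=%d)", config.ddd_seed)
    cohort = build_cohort(
        measurements, subjects, events, rng_seed=config.ddd_seed, censor_at=config.censor_at
    )
    logger.info("cohort: %s", cohort.provenance)

    selection = None
    if config.fixed_shape is not None and config.fixed_k is not None:
        fit = fit_em(
            cohort, BasisSpec(config.fixed_shape), config.fixed_k, **config.fit_kwargs()
        )
    else:
        selection = select_model(
            cohort,
            k_max=config.k_max,
            shapes=config.shapes,
            min_prop=config.min_prop,
            cv_folds=config.cv_folds,
            seed=config.lcga_seed,
            n_starts=config.n_starts,
            burn_in_iters=config.burn_in_iters,
            max_iters=config.max_iters,
        )
        fit = selection.best_fit
        logger.info("selected %s", selection.chosen)

    times, ev = _times_events(cohort)
    labels = fit.modal_class
    km_by_class = {
        int(c): surv.kaplan_meier(times[labels == c], ev[labels == c])
        for c in np.unique(labels)
    }
    omnibus = surv.logrank_test(times, ev, labels)
    pairs = []
    classes = sorted(np.unique(labels).tolist())
    for a in classes:
        for b in classes:
            if a < b:
                mask = (labels == a) | (labels == b)
                res = surv.logrank_test(times[mask], ev[mask], labels[mask])
                pairs.append(
                    {"class_a": a, "class_b": b, "chi2": res.statistic, "p": res.p_value}
                )
    design = prune_nonidentifiable_indicators(
        build_cox_design(cohort, labels, fit.params.k, config.reference_class), ev
    )
    cox = surv.cox_fit(design.values, times, ev, names=list(design.columns))
    return AnalysisReport(
        selection=selection,
        fit=fit,
        cohort=cohort,
        km_by_class=km_by_class,
        logrank_omnibus=omnibus,
        logrank_pairwise=pd.DataFrame(pairs),
        cox=cox,
    )


# ---------------------------------------------------------------------------
# Baseline-shift sensitivity
# ---------------------------------------------------------------------------


def baseline_shift_analysis(
    cohort: Cohort,
    fit: LcgaFit,
    config: AnalysisConfig,
    shift_weeks: float | None = None,
    target_flow: tuple | None = None,
) -> dict:
    """Re-cluster from a later baseline and account for the class flows.

    Measurements before ``shift_weeks`` are dropped, remaining times are
    re-zeroed, the selected model is refit on the shifted data, and new
    classes are matched one-to-one onto the original ones by mean-curve
    distance.  A Cox model then contrasts HHF risk (time origin unchanged,
    from DDD) of subjects *newly* flowing into a target class against
    subjects originally in it, adjusted for the full covariate set.
    ``target_flow=(src, dst)`` picks the flow; default is the largest
    off-diagonal flow in the retention matrix.
    """
    if shift_weeks is None:
        shift_weeks = config.baseline_shift_weeks
    k = fit.params.k
    ids, times_list, values_list = cohort.trajectories()
    keep_idx, shifted_t, shifted_y, excluded = [], [], [], []
    for i, (t, y) in enumerate(zip(times_list, values_list)):
        mask = t >= shift_weeks
        if mask.sum() < 2:
            excluded.append(ids[i])
            continue
        keep_idx.append(i)
        shifted_t.append(t[mask] - shift_weeks)
        shifted_y.append(y[mask])

    if shift_weeks == 0:
        new_fit = fit
        new_labels_matched = fit.modal_class.copy()
        kept_orig = fit.modal_class.copy()
    else:
        new_fit = fit_em((shifted_t, shifted_y), fit.params.basis, k, **config.fit_kwargs())
        m = match_classes(fit.params, new_fit.params)
        new_labels_matched = m[new_fit.modal_class - 1] + 1
        kept_orig = fit.modal_class[keep_idx]

    retention = pd.DataFrame(
        np.zeros((k, k), dtype=int),
        index=[f"orig_{j}" for j in range(1, k + 1)],
        columns=[f"new_{j}" for j in range(1, k + 1)],
    )
    for o, nlab in zip(kept_orig, new_labels_matched):
        retention.iloc[o - 1, nlab - 1] += 1
    diag = np.diag(retention.values)
    row_sums = retention.values.sum(axis=1)
    with np.errstate(invalid="ignore"):
        retention_frac = np.where(row_sums > 0, diag / np.maximum(row_sums, 1), np.nan)

    flows = retention.values.astype(float).copy()
    np.fill_diagonal(flows, -1)
    if target_flow is None:
        src, dst = np.unravel_index(int(np.argmax(flows)), flows.shape)
        src, dst = src + 1, dst + 1
    else:
        src, dst = target_flow
    cox_cmp = _regrouped_cox(cohort, fit, keep_idx if shift_weeks else list(range(len(ids))),
                             kept_orig, new_labels_matched, src, dst, config)
    return {
        "shift_weeks": shift_weeks,
        "retention_matrix": retention,
        "retention_fraction": retention_frac,
        "excluded_ids": excluded,
        "new_fit": new_fit,
        "flow": (int(src), int(dst)),
        "regrouped_cox": cox_cmp,
    }


def _regrouped_cox(cohort, fit, keep_idx, kept_orig, new_labels, src, dst, config):
    """Cox on {originally dst} vs {originally src, regrouped to dst}."""
    subj = cohort.subjects
    orig_all = fit.modal_class
    sel, indicator = [], []
    regrouped = {
        subj[keep_idx[i]].id
        for i in range(len(keep_idx))
        if kept_orig[i] == src and new_labels[i] == dst
    }
    for i, s in enumerate(subj):
        if orig_all[i] == dst:
            sel.append(i)
            indicator.append(0.0)
        elif s.id in regrouped:
            sel.append(i)
            indicator.append(1.0)
    if not sel or sum(indicator) == 0:
        return None
    sub = Cohort(subjects=[subj[i] for i in sel])
    t, e = _times_events(sub)
    if e.sum() == 0:
        return None
    design = build_cox_design(sub, np.full(len(sel), dst), fit.params.k, config.reference_class)
    design.insert(0, "regrouped", indicator)
    design = prune_nonidentifiable_indicators(design, e)
    if "regrouped" not in design.columns:
        return {"adjusted": None, "unadjusted": None, "n": len(sel),
                "n_regrouped": int(sum(indicator))}
    try:
        adjusted = surv.cox_fit(design.values, t, e, names=list(design.columns))
    except (surv.CoxConvergenceError, surv.CoxRankError):
        adjusted = None
    try:
        unadjusted = surv.cox_fit(
            np.asarray(indicator)[:, None], t, e, names=["regrouped"]
        )
    except (surv.CoxConvergenceError, surv.CoxRankError):
        unadjusted = None
    return {"adjusted": adjusted, "unadjusted": unadjusted, "n": len(sel),
            "n_regrouped": int(sum(indicator))}


# ---------------------------------------------------------------------------
# DDD re-seeding sensitivity
# ---------------------------------------------------------------------------


def seed_sensitivity_analysis(
    measurements: pd.DataFrame,
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    config: AnalysisConfig,
    seed_a: int,
    seed_b: int,
    shape: str,
    k: int,
) -> dict:
    """Rebuild the cohort under two diagnosis-date imputation seeds, refit
    the selected model under identical settings, match classes, and compare.

    Reports the fraction of (common) subjects keeping their matched modal
    class and a per-class log-rank comparing the survival curves of class-k
    members under the two assignments.
    """
    fits, cohorts = [], []
    for sd in (seed_a, seed_b):
        co = build_cohort(measurements, subjects, events, rng_seed=sd,
                          censor_at=config.censor_at)
        fits.append(fit_em(co, BasisSpec(shape), k, **config.fit_kwargs()))
        cohorts.append(co)
    fit_a, fit_b = fits
    co_a, co_b = cohorts
    m = match_classes(fit_a.params, fit_b.params)
    labels_a = {s.id: int(c) for s, c in zip(co_a.subjects, fit_a.modal_class)}
    labels_b = {
        s.id: int(m[c - 1] + 1) for s, c in zip(co_b.subjects, fit_b.modal_class)
    }
    common = sorted(set(labels_a) & set(labels_b))
    same = sum(labels_a[i] == labels_b[i] for i in common)
    retention = same / len(common)

    t_a, e_a = _times_events(co_a)
    idx_a = {s.id: i for i, s in enumerate(co_a.subjects)}
    per_class = []
    for c in range(1, k + 1):
        ids_ac = [i for i in common if labels_a[i] == c]
        ids_bc = [i for i in common if labels_b[i] == c]
        if not ids_ac or not ids_bc:
            per_class.append({"class": c, "chi2": np.nan, "p": np.nan})
            continue
        if set(ids_ac) == set(ids_bc):
            per_class.append({"class": c, "chi2": 0.0, "p": 1.0})
            continue
        rows = [(t_a[idx_a[i]], e_a[idx_a[i]], 0) for i in ids_ac] + [
            (t_a[idx_a[i]], e_a[idx_a[i]], 1) for i in ids_bc
        ]
        tt = np.array([r[0] for r in rows])
        ee = np.array([r[1] for r in rows])
        gg = np.array([r[2] for r in rows])
        if ee.sum() == 0:
            per_class.append({"class": c, "chi2": 0.0, "p": 1.0})
            continue
        res = surv.logrank_test(tt, ee, gg)
        per_class.append({"class": c, "chi2": res.statistic, "p": res.p_value})
    return {
        "retention": retention,
        "n_common": len(common),
        "per_class_logrank": pd.DataFrame(per_class),
        "fit_a": fit_a,
        "fit_b": fit_b,
    }


# ---------------------------------------------------------------------------
# Split-sample predictive validation
# ---------------------------------------------------------------------------


def predictive_validation(
    cohort: Cohort, config: AnalysisConfig, shape: str, k: int
) -> dict:
    """80/20 split; class prediction and windowed concordance on held-out
    subjects.

    The LCGA and Cox models are fitted on the training split only.  Held-out
    class retention compares the validation subjects' predicted modal class
    (training parameters, full trajectories) with a full-data fit.  For each
    cumulative window [0, w] the validation trajectories are truncated, class
    membership is re-predicted, fixed training Cox coefficients produce risk
    scores, and Harrell's C is computed on the full validation follow-up.
    Subjects with no measurement inside the first window are excluded once.
    A no-class Cox model gives the reference concordance.
    """
    n = len(cohort)
    rng = np.random.default_rng(config.split_seed)
    perm = rng.permutation(n)
    n_train = int(round(config.split_fraction * n))
    train_idx = np.sort(perm[:n_train])
    valid_idx = np.sort(perm[n_train:])
    train = Cohort(subjects=[cohort.subjects[i] for i in train_idx])
    valid = Cohort(subjects=[cohort.subjects[i] for i in valid_idx])
    logger.info("split: %d train / %d validation (seed %d)", len(train), len(valid),
                config.split_seed)

    basis = BasisSpec(shape)
    fit_train = fit_em(train, basis, k, **config.fit_kwargs())
    fit_full = fit_em(cohort, basis, k, **config.fit_kwargs())
    m = match_classes(fit_full.params, fit_train.params)  # train label -> full label

    post_v, modal_v, _ = posterior_predict(valid, fit_train.params)
    modal_v_fullref = m[modal_v - 1] + 1
    full_labels = {s.id: int(c) for s, c in zip(cohort.subjects, fit_full.modal_class)}
    same = sum(
        int(modal_v_fullref[i]) == full_labels[s.id] for i, s in enumerate(valid.subjects)
    )
    retention = same / len(valid)

    # training Cox with class indicators (training-fit labels)
    t_tr, e_tr = _times_events(train)
    design_tr = prune_nonidentifiable_indicators(
        build_cox_design(train, fit_train.modal_class, k, config.reference_class), e_tr
    )
    cox_full = surv.cox_fit(design_tr.values, t_tr, e_tr, names=list(design_tr.columns))
    noclass_cols = [c for c in design_tr.columns if not c.startswith("class_")]
    cox_noclass = surv.cox_fit(
        design_tr[noclass_cols].values, t_tr, e_tr, names=noclass_cols
    )

    # window loop on the validation split
    width = config.window_width_weeks
    ids_v, times_v, values_v = valid.trajectories()
    in_first = [i for i, t in enumerate(times_v) if np.any(t <= width)]
    excluded_n = len(valid) - len(in_first)
    sub_valid = Cohort(subjects=[valid.subjects[i] for i in in_first])
    t_v, e_v = _times_events(sub_valid)

    def _design_for(labels):
        d = build_cox_design(sub_valid, labels, k, config.reference_class)
        return d[cox_full.names].values

    windows, concordances = [], []
    for w_i in range(1, config.n_windows + 1):
        w = width * w_i
        tl, vl = [], []
        for i in in_first:
            mask = times_v[i] <= w
            tl.append(times_v[i][mask])
            vl.append(values_v[i][mask])
        _, modal_w, _ = posterior_predict((tl, vl), fit_train.params)
        risk = surv.cox_predict_risk(cox_full, _design_for(modal_w))
        if e_v.sum() == 0:
            c = float("nan")
        else:
            c = surv.concordance_index(t_v, e_v, risk)
        windows.append(w)
        concordances.append(c)

    d_nc = build_cox_design(sub_valid, np.ones(len(sub_valid), dtype=int), k,
                            config.reference_class)
    risk_nc = surv.cox_predict_risk(cox_noclass, d_nc[cox_noclass.names].values)
    c_noclass = surv.concordance_index(t_v, e_v, risk_nc) if e_v.sum() else float("nan")

    return {
        "retention": retention,
        "n_valid": len(valid),
        "n_windowed": len(sub_valid),
        "excluded_first_window": excluded_n,
        "windows": windows,
        "concordance": concordances,
        "concordance_noclass": c_noclass,
        "fit_train": fit_train,
        "fit_full": fit_full,
        "cox_train": cox_full,
        "cox_noclass": cox_noclass,
    }
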