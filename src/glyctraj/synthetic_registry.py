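"""Synthetic diabetes-registry generator.

Emulates a hospital diabetes registry of newly diagnosed type 2 diabetes
patients: per-subject HbA1c laboratory series on irregular visit schedules,
demographics and prior-complication flags, and time to first hospitalization
for heart failure (HHF).  Subjects belong to latent trajectory classes, each
with its own mean HbA1c curve, residual noise, covariate mix and constant
HHF hazard, so trajectory-recovery and association analyses can be tested
against known ground truth.

The default configuration (:func:`default_registry_config`) encodes a
five-class population — low stable, moderate-low stable, high decreasing,
high with a sharp early decline, and moderate-high decreasing — with class
sizes 35.5/41.1/3.4/10.7/9.2%, baseline HbA1c means 6.23/7.16/10.6/7.69/8.73%,
roughly 13.5-16.5 measurements per subject over ~234-253 weeks of follow-up,
19% of subjects whose first specimen falls in the calendar year after the
diagnosis year, and class-wise cumulative HHF incidence of ~1.0-3.6%.

The emitted ``true_class`` column is ground truth for recovery tests only;
analysis stages must never read it.
"""

from __future__ import annotations

import datetime as dt
import json
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .lcga import BasisSpec, design_matrix, SHAPES

ETHNICITIES = ("Chinese", "Malay", "Indian", "Other")
COMPLICATIONS = (
    "prior_cvd",
    "prior_ihd",
    "prior_pad",
    "prior_hstroke",
    "prior_istroke",
    "prior_tia",
    "prior_af",
    "prior_neuropathy",
    "prior_dpa",
    "prior_hf",
)


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


def _check_prob_vector(name, v, tol=1e-9):
    v = np.asarray(v, dtype=float)
    if np.any(v < 0) or abs(v.sum() - 1.0) > tol:
        raise ConfigError(f"{name} must be non-negative and sum to 1 (got sum {v.sum()!r})")


@dataclass
class TrueClassSpec:
    """Generating description of one latent trajectory class."""

    label: int
    proportion: float
    curve_coefficients: tuple
    residual_sd: float
    event_rate: float  # constant HHF hazard, per week
    age_mean: float
    age_sd: float
    ethnicity_probs: tuple  # Chinese / Malay / Indian / Other
    male_prob: float
    prior_complication_probs: dict

    def validate(self) -> None:
        if self.residual_sd <= 0:
            raise ConfigError(f"class {self.label}: residual_sd must be > 0")
        if self.event_rate < 0:
            raise ConfigError(f"class {self.label}: event_rate must be >= 0")
        if not 0 < self.proportion < 1:
            raise ConfigError(f"class {self.label}: proportion must be in (0, 1)")
        _check_prob_vector(f"class {self.label}: ethnicity_probs", self.ethnicity_probs)
        if not 0 <= self.male_prob <= 1:
            raise ConfigError(f"class {self.label}: male_prob must be in [0, 1]")
        for name, p in self.prior_complication_probs.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"class {self.label}: {name} probability must be in [0, 1]")


@dataclass
class GeneratorConfig:
    n_subjects: int
    class_specs: list
    generating_shape: str = "logarithmic"
    visits_mean: float = 15.2
    visits_sd: float = 5.5
    followup_mean_weeks: float = 245.6
    followup_sd_weeks: float = 68.0
    ddd_mismatch_fraction: float = 0.19
    admin_censor_weeks: float = 364.0
    seed: int = 0
    diagnosis_years: tuple = (2013, 2016)  # inclusive range
    eligibility_floor_prob: float = 0.95
    complication_missing_fraction: float = 0.13
    covariate_effects: dict | None = None  # optional log-hazard effects
    basis_kwargs: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.generating_shape not in SHAPES:
            raise ConfigError(f"generating_shape must be one of {SHAPES}")
        if self.visits_mean < 5:
            raise ConfigError("visits_mean must be >= 5 so most subjects pass eligibility")
        if not 0 <= self.ddd_mismatch_fraction <= 1:
            raise ConfigError("ddd_mismatch_fraction must be in [0, 1]")
        if self.followup_mean_weeks <= 0 or self.followup_sd_weeks < 0:
            raise ConfigError("followup_mean_weeks must be > 0 and followup_sd_weeks >= 0")
        if not self.class_specs:
            raise ConfigError("class_specs must be non-empty")
        props = [c.proportion for c in self.class_specs]
        _check_prob_vector("class proportions", props)
        for c in self.class_specs:
            c.validate()

    @property
    def basis(self) -> BasisSpec:
        return BasisSpec(self.generating_shape, **self.basis_kwargs)

    def to_json(self, path=None) -> str:
        d = asdict(self)
        text = json.dumps(d, indent=2)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "GeneratorConfig":
        s = str(text_or_path)
        try:
            is_file = pathlib.Path(s).is_file()
        except OSError:  # raw JSON text can exceed filename limits
            is_file = False
        text = pathlib.Path(s).read_text() if is_file else s
        d = json.loads(text)
        d["class_specs"] = [TrueClassSpec(**c) for c in d["class_specs"]]
        return cls(**d)


def hazard_for_cumulative(prob: float, t_weeks: float) -> float:
    """Constant hazard giving cumulative event probability ``prob`` by
    ``t_weeks``: lambda = -log(1 - p) / t."""
    if not 0 <= prob < 1:
        raise ValueError("prob must be in [0, 1)")
    return -np.log1p(-prob) / t_weeks


# Class anchors: size %, baseline HbA1c mean, cumulative HHF %, mean
# observational period (weeks), mean visit count, demographics.  Slopes on
# the log(weeks+1) basis and residual SDs are free modelling choices: classes
# 1-2 near-flat, 3-5 decreasing, class 4 declining steeply enough to cross
# the class-2 curve near week ~25 and end below it.
_DEFAULT_ROWS = [
    # label, prop, intercept, slope, resid_sd, hhf_cum, followup, age_mean, age_sd,
    #   male, (ethnicity), {complications %}
    (1, 0.355, 6.23, -0.04, 0.40, 0.0143, 239.9, 61.6, 10.9, 0.490,
     (0.770, 0.137, 0.061, 0.032),
     (16.1, 9.61, 0.37, 0.57, 5.2, 1.34, 1.38, 0.34, 0.292, 0.437)),
    (2, 0.411, 7.16, -0.05, 0.45, 0.0105, 252.5, 57.8, 10.7, 0.517,
     (0.714, 0.162, 0.087, 0.037),
     (13.36, 8.24, 0.32, 0.35, 3.27, 0.89, 0.99, 0.364, 0.238, 0.504)),
    (3, 0.034, 10.60, -0.33, 0.90, 0.0337, 244.6, 49.2, 11.7, 0.542,
     (0.417, 0.341, 0.168, 0.074),
     (7.74, 5.05, 0.84, 0.0, 1.01, 0.67, 0.51, 1.35, 1.35, 0.673)),
    (4, 0.107, 7.69, -0.26, 0.50, 0.0289, 233.9, 55.4, 10.5, 0.576,
     (0.641, 0.226, 0.096, 0.037),
     (10.05, 5.94, 0.695, 0.268, 2.68, 0.43, 1.07, 1.02, 1.50, 0.59)),
    (5, 0.092, 8.73, -0.20, 0.65, 0.0355, 252.8, 53.2, 12.1, 0.535,
     (0.524, 0.275, 0.133, 0.068),
     (11.96, 8.03, 0.31, 0.44, 1.99, 0.81, 0.934, 0.498, 0.56, 1.18)),
]


def default_registry_config(n_subjects: int = 17389, seed: int = 0) -> GeneratorConfig:
    """Five-class default configuration (the reference study population).

    Class proportions, baseline HbA1c means, demographics, prior-complication
    frequencies and cumulative HHF incidence are fixed population anchors;
    each class's constant hazard is solved from its cumulative incidence over
    its mean follow-up via ``1 - exp(-lambda t)``.
    """
    specs = []
    for (label, prop, icpt, slope, sd, hhf, fup, age_m, age_s, male, eth, comp) in _DEFAULT_ROWS:
        specs.append(
            TrueClassSpec(
                label=label,
                proportion=prop,
                curve_coefficients=(icpt, slope),
                residual_sd=sd,
                event_rate=hazard_for_cumulative(hhf, fup),
                age_mean=age_m,
                age_sd=age_s,
                ethnicity_probs=eth,
                male_prob=male,
                prior_complication_probs={
                    name: pct / 100.0 for name, pct in zip(COMPLICATIONS, comp)
                },
            )
        )
    total = sum(s.proportion for s in specs)
    for s in specs:  # printed percentages sum to 99.9; rescale to exactly 1
        s.proportion /= total
    return GeneratorConfig(n_subjects=n_subjects, class_specs=specs, seed=seed)



@dataclass
class SimulatedRegistry:
    measurements: pd.DataFrame
    subjects: pd.DataFrame
    events: pd.DataFrame
    config: GeneratorConfig

    def write(self, directory) -> None:
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(directory / "measurements.csv", index=False)
        self.subjects.to_csv(directory / "subjects.csv", index=False)
        self.events.to_csv(directory / "events.csv", index=False)
        self.config.to_json(directory / "generator_config.json")


def _random_date_in_year(rng, year: int) -> dt.date:
    return dt.date(year, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365)))


def generate_cohort(config: GeneratorConfig) -> SimulatedRegistry:
    """Draw a full synthetic registry: measurements, subjects, events.

    For each subject a latent class is drawn from the configured proportions;
    follow-up length and visit count come from truncated normals (floored at
    eligibility-passing values with probability ``eligibility_floor_prob`` so
    the downstream filter stays non-trivial); visit times are uniform over
    follow-up plus a mandatory time-0 visit; HbA1c is the class mean curve
    plus Gaussian noise; the HHF time is exponential with the class's
    constant hazard, censored at min(follow-up end, administrative horizon).
    With probability ``ddd_mismatch_fraction`` the whole specimen schedule is
    shifted so the first specimen falls in the calendar year after the
    diagnosis year (the trajectory clock still runs from the true diagnosis
    date).  Deterministic given ``config.seed``.

    ``events.event_weeks`` is expressed in weeks from the first specimen
    date, the anchor that remains observable downstream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    basis = config.basis
    specs = config.class_specs
    props = np.array([c.proportion for c in specs])
    y0, y1 = config.diagnosis_years

    m_rows, s_rows, e_rows = [], [], []
    z_draw = rng.choice(len(specs), size=config.n_subjects, p=props)
    for i in range(config.n_subjects):
        spec = specs[z_draw[i]]
        sid = f"S{i + 1:06d}"
        year = int(rng.integers(y0, y1 + 1))
        ddd = _random_date_in_year(rng, year)

        n_vis = int(round(rng.normal(config.visits_mean, config.visits_sd)))
        followup = rng.normal(config.followup_mean_weeks, config.followup_sd_weeks)
        if rng.random() < config.eligibility_floor_prob:
            n_vis = max(n_vis, 6)
            followup = max(followup, 165.0)
        else:
            n_vis = max(n_vis, 2)
            followup = max(followup, 10.0)

        t = np.concatenate([[0.0], np.sort(rng.uniform(0.0, followup, size=n_vis - 1))])

        mismatch = rng.random() < config.ddd_mismatch_fraction
        if mismatch:
            first_spec = _random_date_in_year(rng, year + 1)
            offset_weeks = (first_spec - ddd).days / 7.0
        else:
            first_spec = ddd
            offset_weeks = 0.0

        t_true = t + offset_weeks  # weeks from the true diagnosis date
        mu = design_matrix(t_true, basis) @ np.asarray(spec.curve_coefficients, dtype=float)
        y = mu + rng.normal(0.0, spec.residual_sd, size=len(t))

        day_offsets = np.round(t * 7.0).astype(int)
        for d_off, val in zip(day_offsets, y):
            date = first_spec + dt.timedelta(days=int(d_off))
            m_rows.append((sid, date.isoformat(), round(float(val), 3)))

        covs = _draw_covariates(rng, spec, config)
        s_rows.append(
            {
                "subject_id": sid,
                "diagnosis_year": year,
                **covs,
                "true_class": spec.label,  # oracle-only ground truth
            }
        )

        lam = spec.event_rate * _covariate_hazard_multiplier(covs, config)
        event_from_ddd = rng.exponential(1.0 / lam) if lam > 0 else np.inf
        cens_fs = min(followup, config.admin_censor_weeks)
        event_fs = event_from_ddd - offset_weeks
        if event_fs <= cens_fs and np.isfinite(event_fs):
            e_rows.append((sid, round(float(event_fs), 4), 1))
        else:
            e_rows.append((sid, round(float(cens_fs), 4), 0))

    measurements = pd.DataFrame(m_rows, columns=["subject_id", "specimen_date", "hba1c_pct"])
    subjects = pd.DataFrame(s_rows)
    events = pd.DataFrame(e_rows, columns=["subject_id", "event_weeks", "event_indicator"])
    return SimulatedRegistry(measurements, subjects, events, config)


def _draw_covariates(rng, spec: TrueClassSpec, config: GeneratorConfig) -> dict:
    cov = {
        "sex": "M" if rng.random() < spec.male_prob else "F",
        "ethnicity": ETHNICITIES[rng.choice(4, p=np.asarray(spec.ethnicity_probs))],
        "age_at_diagnosis": round(float(rng.normal(spec.age_mean, spec.age_sd)), 1),
    }
    missing = rng.random() < config.complication_missing_fraction
    for name in COMPLICATIONS:
        if missing:
            cov[name] = np.nan
        else:
            p = spec.prior_complication_probs.get(name, 0.0)
            cov[name] = int(rng.random() < p)
    return cov


def _covariate_hazard_multiplier(covs: dict, config: GeneratorConfig) -> float:
    """Optional log-linear covariate effects on the hazard (off by default so
    the class-level recovery tests stay interpretable).  Age enters centered
    at 57.5 years to keep rates in a sane range."""
    if not config.covariate_effects:
        return 1.0
    lp = 0.0
    for name, coef in config.covariate_effects.items():
        if name == "male":
            lp += coef * (covs["sex"] == "M")
        elif name == "age_at_diagnosis":
            lp += coef * (covs["age_at_diagnosis"] - 57.5)
        elif name in covs and not (isinstance(covs[name], float) and np.isnan(covs[name])):
            lp += coef * float(covs[name])
    return float(np.exp(lp))
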