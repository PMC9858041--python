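"""Cohort construction: eligibility filtering, diagnosis-date imputation and
time re-basing.

The trajectory time origin is the diabetes diagnosis date (DDD).  When the
first HbA1c specimen falls in the same calendar year as the recorded
diagnosis year, the DDD is taken to be that first specimen date.  When the
first specimen falls in a later year, the DDD is imputed uniformly over the
days of the diagnosis year (deterministically per subject given a seed).
All measurement and event times are then expressed in weeks from the DDD.

Eligibility requires at least 5 HbA1c measurements spanning at least 3 years
(3 x 365.25 days, leap-year neutral).
"""

from __future__ import annotations

import datetime as dt
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DAYS_PER_WEEK = 7.0
MIN_SAMPLES = 5
MIN_SPAN_DAYS = 3 * 365.25  # 1095.75
MIN_SPAN_WEEKS = MIN_SPAN_DAYS / DAYS_PER_WEEK

PRIOR_COMPLICATION_COLS = [
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
]


class DataIntegrityError(ValueError):
    """Raised when the input tables are mutually inconsistent."""


class EmptyCohortError(ValueError):
    """Raised when every subject is excluded by the eligibility filter."""


@dataclass
class Subject:
    """One registry member with times re-based to weeks from DDD."""

    id: str
    diagnosis_year: int
    ddd: dt.date
    times_weeks: np.ndarray
    hba1c: np.ndarray
    covariates: dict
    event_weeks: float
    event_indicator: int


@dataclass
class Cohort:
    subjects: list
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    def trajectories(self):
        """(ids, times_list, values_list) view consumed by the LCGA engine."""
        ids = [s.id for s in self.subjects]
        return ids, [s.times_weeks for s in self.subjects], [s.hba1c for s in self.subjects]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for t, y in zip(s.times_weeks, s.hba1c):
                rows.append((s.id, t, y))
        return pd.DataFrame(rows, columns=["subject_id", "weeks", "hba1c"])

    def write(self, directory) -> None:
        """cohort.csv (long format) + cohort_meta.json (provenance)."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_long_frame().to_csv(directory / "cohort.csv", index=False)
        with open(directory / "cohort_meta.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)


def _subject_rng(rng_seed: int, subject_id) -> np.random.Generator:
    """Deterministic per-subject stream: the draw depends only on the seed
    and the subject id, not on iteration order."""
    tag = zlib.crc32(str(subject_id).encode())
    return np.random.default_rng([int(rng_seed), tag])


def impute_ddd(diagnosis_year: int, first_specimen_date, rng_seed: int, subject_id="") -> dt.date:
    """Impute the diabetes diagnosis date.

    Same calendar year as the first specimen: the DDD *is* the first specimen
    date.  Diagnosis year earlier: Jan 1 of the diagnosis year plus a day
    offset uniform on {0, ..., 364} (365 would overflow non-leap years),
    deterministic given ``rng_seed`` and ``subject_id``.
    """
    first = pd.Timestamp(first_specimen_date).date()
    if diagnosis_year > first.year:
        raise DataIntegrityError(
            f"subject {subject_id!r}: diagnosis year {diagnosis_year} is after "
            f"first specimen year {first.year}"
        )
    if first.year == diagnosis_year:
        return first
    offset = int(_subject_rng(rng_seed, subject_id).integers(0, 365))
    return dt.date(diagnosis_year, 1, 1) + dt.timedelta(days=offset)


def filter_eligible(measurements: pd.DataFrame, subjects: pd.DataFrame):
    """Apply the eligibility filter on raw tables.

    Keeps subjects with >= 5 HbA1c measurements spanning >= 3 years.  Returns
    ``(kept_ids, excluded)`` where ``excluded`` maps subject id to the failed
    criterion (``too_few_samples`` or ``span_too_short``).
    """
    meas_ids = set(measurements["subject_id"])
    subj_ids = set(subjects["subject_id"])
    orphans = sorted(meas_ids - subj_ids)
    if orphans:
        raise DataIntegrityError(
            f"measurements reference subjects absent from the subjects table: {orphans[:10]}"
        )
    dates = pd.to_datetime(measurements["specimen_date"])
    g = measurements.assign(_d=dates).groupby("subject_id")["_d"]
    counts = g.count()
    spans = (g.max() - g.min()).dt.total_seconds() / 86400.0

    kept, excluded = [], {}
    for sid in subjects["subject_id"]:
        n = int(counts.get(sid, 0))
        if n < MIN_SAMPLES:
            excluded[sid] = "too_few_samples"
        elif float(spans[sid]) < MIN_SPAN_DAYS:
            excluded[sid] = "span_too_short"
        else:
            kept.append(sid)
    return kept, excluded


def _covariates_from_row(row: pd.Series) -> dict:
    cov = {
        "age_at_diagnosis": float(row["age_at_diagnosis"]),
        "sex": row["sex"],
        "ethnicity": row["ethnicity"],
    }
    for c in PRIOR_COMPLICATION_COLS:
        v = row.get(c, np.nan)
        cov[c] = float(v) if pd.notna(v) else np.nan  # NaN encodes "missing"
    return cov


def build_cohort(
    measurements: pd.DataFrame,
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    rng_seed: int = 0,
    censor_at: str = "last_measurement",
) -> Cohort:
    """Assemble the analysis cohort from the three raw tables.

    Pipeline: eligibility filter -> per-subject DDD imputation -> re-base
    specimen dates to weeks from DDD -> drop measurements predating an
    imputed DDD -> re-check eligibility -> attach the first-HHF outcome.

    ``events.event_weeks`` is measured from the subject's first specimen
    date; only an event strictly after the DDD counts, otherwise the subject
    is censored.  Event-free subjects are censored at their last measurement
    by default or at the events-table censoring time with
    ``censor_at='events_table'``.
    """
    if censor_at not in ("last_measurement", "events_table"):
        raise ValueError("censor_at must be 'last_measurement' or 'events_table'")
    kept, excluded = filter_eligible(measurements, subjects)
    meas = measurements.assign(_date=pd.to_datetime(measurements["specimen_date"]))
    by_subject = {
        sid: df.sort_values("_date", kind="stable")  # stable: same-day order kept
        for sid, df in meas.groupby("subject_id")
    }
    subj_rows = subjects.set_index("subject_id")
    ev = events.set_index("subject_id") if len(events) else pd.DataFrame()

    out = []
    dropped_after_recheck = {}
    for sid in kept:
        df = by_subject[sid]
        first = df["_date"].iloc[0].date()
        year = int(subj_rows.loc[sid, "diagnosis_year"])
        ddd = impute_ddd(year, first, rng_seed, subject_id=sid)
        days = np.array([(d.date() - ddd).days for d in df["_date"]], dtype=float)
        keep_mask = days >= 0  # measurements predating an imputed DDD are dropped
        days = days[keep_mask]
        values = df["hba1c_pct"].to_numpy(dtype=float)[keep_mask]
        weeks = days / DAYS_PER_WEEK
        if len(weeks) < MIN_SAMPLES or (weeks.max() - weeks.min()) < MIN_SPAN_WEEKS:
            dropped_after_recheck[sid] = "ineligible_after_ddd_rebase"
            continue

        event_weeks, indicator = _resolve_outcome(sid, ev, first, ddd, weeks, censor_at)
        out.append(
            Subject(
                id=sid,
                diagnosis_year=year,
                ddd=ddd,
                times_weeks=weeks,
                hba1c=values,
                covariates=_covariates_from_row(subj_rows.loc[sid]),
                event_weeks=event_weeks,
                event_indicator=indicator,
            )
        )
    if not out:
        raise EmptyCohortError("every subject was excluded by the eligibility filter")
    excluded_all = {**excluded, **dropped_after_recheck}
    provenance = {
        "raw_n": int(len(subjects)),
        "excluded_n": int(len(excluded_all)),
        "final_n": int(len(out)),
        "exclusion_reasons": {
            r: sum(1 for v in excluded_all.values() if v == r)
            for r in set(excluded_all.values())
        },
        "ddd_seed": int(rng_seed),
        "censor_at": censor_at,
    }
    return Cohort(subjects=out, provenance=provenance)


def _resolve_outcome(sid, ev, first_specimen, ddd, weeks, censor_at):
    last_obs = float(weeks.max())
    if sid not in getattr(ev, "index", []):
        return last_obs, 0
    row = ev.loc[sid]
    ev_weeks_fs = float(row["event_weeks"])
    indicator = int(row["event_indicator"])
    ev_date_days = (first_specimen - ddd).days + ev_weeks_fs * DAYS_PER_WEEK
    if indicator == 1 and ev_date_days > 0:
        return ev_date_days / DAYS_PER_WEEK, 1
    if indicator == 1:
        # the only HHF predates the DDD: treated as event-free, censored at
        # the last observed measurement
        return last_obs, 0
    if censor_at == "events_table" and ev_date_days > 0:
        return ev_date_days / DAYS_PER_WEEK, 0
    return last_obs, 0


def cohort_to_tables(cohort: Cohort):
    """Re-serialize a cohort into the three raw tables.

    Measurement dates are reconstructed as DDD + round(weeks * 7) days and
    the events table is re-expressed relative to the (reconstructed) first
    specimen date, so ``build_cohort`` on the output with the same seed
    reproduces the cohort.
    """
    m_rows, s_rows, e_rows = [], [], []
    for s in cohort.subjects:
        dates = [s.ddd + dt.timedelta(days=round(t * DAYS_PER_WEEK)) for t in s.times_weeks]
        for d, y in zip(dates, s.hba1c):
            m_rows.append((s.id, d.isoformat(), y))
        row = {
            "subject_id": s.id,
            "diagnosis_year": s.diagnosis_year,
            "sex": s.covariates["sex"],
            "ethnicity": s.covariates["ethnicity"],
            "age_at_diagnosis": s.covariates["age_at_diagnosis"],
        }
        for c in PRIOR_COMPLICATION_COLS:
            row[c] = s.covariates[c]
        row["true_class"] = ""
        s_rows.append(row)
        fs_weeks = (dates[0] - s.ddd).days / DAYS_PER_WEEK
        e_rows.append((s.id, s.event_weeks - fs_weeks, s.event_indicator))
    measurements = pd.DataFrame(m_rows, columns=["subject_id", "specimen_date", "hba1c_pct"])
    subjects = pd.DataFrame(s_rows)
    events = pd.DataFrame(e_rows, columns=["subject_id", "event_weeks", "event_indicator"])
    return measurements, subjects, events
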