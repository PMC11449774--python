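"""Longitudinal cohort ingestion, validation, filtering and imputation.

The cohort is held as two tables: a long-format visit table
(``participant_id, visit_time_days, fbg_mmol_l``) and a one-row-per-person
covariate table.  Comorbidity flags follow standard clinical definitions:
hypertension is SBP >= 140 mmHg or DBP >= 90 mmHg or self-reported history
or current antihypertensive use; dyslipidemia is LDL-C >= 3.37 mmol/L or
HDL-C < 1.04 or TC >= 5.18 or TG >= 1.7 or self-reported history or
lipid-lowering medication use.

Eligibility mirrors a multi-wave screening cohort with an ophthalmic
outcome ascertained at the final wave: participants need at least three
FBG measurements, an FBG test in the final screening window, and a
gradable (non-missing) retinopathy status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "FilterLog",
    "read_cohort",
    "derive_comorbidity_flags",
    "apply_eligibility_filters",
    "impute_missing_covariates",
    "CLASSICAL_COVARIATES",
]

VISIT_COLUMNS = ("participant_id", "visit_time_days", "fbg_mmol_l")

# numeric covariates imputed by the cohort mean
CONTINUOUS_COVARIATES = ("age", "bmi", "sbp", "dbp", "ldl_c", "hdl_c", "tc", "tg")
# 0/1-coded covariates imputed by the median of the coding (ties -> 0)
CATEGORICAL_COVARIATES = (
    "female",
    "education_low",
    "income_low",
    "current_smoking",
    "current_drinking",
    "hypertension",
    "dyslipidemia",
)

#: adjustment set for the risk models: age, sex, BMI, education, income,
#: smoking, drinking, hypertension, dyslipidemia.
CLASSICAL_COVARIATES = (
    "age",
    "female",
    "bmi",
    "education_low",
    "income_low",
    "current_smoking",
    "current_drinking",
    "hypertension",
    "dyslipidemia",
)

# thresholds for derived comorbidity flags
SBP_THRESHOLD = 140.0   # mmHg
DBP_THRESHOLD = 90.0    # mmHg
LDL_THRESHOLD = 3.37    # mmol/L, >=
HDL_THRESHOLD = 1.04    # mmol/L, <
TC_THRESHOLD = 5.18     # mmol/L, >=
TG_THRESHOLD = 1.70     # mmol/L, >=


@dataclass
class Cohort:
    """Visit table plus participant covariate table.

    Invariants: every visit's ``participant_id`` exists in
    ``participants``; visits are sorted by ``(participant_id,
    visit_time_days)``; ``(participant_id, visit_time_days)`` is unique.
    """

    visits: pd.DataFrame
    participants: pd.DataFrame

    def n_participants(self) -> int:
        return len(self.participants)


@dataclass
class FilterLog:
    """Per-criterion exclusion counts, in application order."""

    rows: list = field(default_factory=list)

    def add(self, criterion: str, n_before: int, n_excluded: int) -> None:
        self.rows.append(
            {
                "criterion": criterion,
                "n_before": n_before,
                "n_excluded": n_excluded,
                "n_after": n_before - n_excluded,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["criterion", "n_before", "n_excluded", "n_after"]
        )


def _check_visits(visits: pd.DataFrame) -> pd.DataFrame:
    missing = set(VISIT_COLUMNS) - set(visits.columns)
    if missing:
        raise ValueError(f"visits file missing columns: {sorted(missing)}")
    v = visits.copy()
    v["visit_time_days"] = pd.to_numeric(v["visit_time_days"], errors="raise")
    v["fbg_mmol_l"] = pd.to_numeric(v["fbg_mmol_l"], errors="raise")
    bad_t = v.index[(v["visit_time_days"] < 0) | v["visit_time_days"].isna()]
    if len(bad_t):
        raise ValueError(
            f"visit row {bad_t[0]}: visit_time_days must be non-negative "
            f"(got {v.loc[bad_t[0], 'visit_time_days']!r})"
        )
    bad_f = v.index[~(v["fbg_mmol_l"] > 0)]
    if len(bad_f):
        raise ValueError(
            f"visit row {bad_f[0]}: fbg_mmol_l must be positive "
            f"(got {v.loc[bad_f[0], 'fbg_mmol_l']!r})"
        )
    dup = v.duplicated(subset=["participant_id", "visit_time_days"])
    if dup.any():
        row = v.index[dup][0]
        raise ValueError(
            f"visit row {row}: duplicate (participant_id, visit_time_days) pair "
            f"({v.loc[row, 'participant_id']!r}, {v.loc[row, 'visit_time_days']!r})"
        )
    return v.sort_values(["participant_id", "visit_time_days"], kind="mergesort")


def _encode_categoricals(p: pd.DataFrame) -> pd.DataFrame:
    """Map string-coded sex/education/income to 0/1 analysis columns."""
    p = p.copy()
    if "sex" in p.columns and "female" not in p.columns:
        sex = p["sex"].astype("string").str.lower()
        ok = sex.isna() | sex.isin(["female", "male"])
        if not ok.all():
            row = p.index[~ok][0]
            raise ValueError(f"participant row {row}: sex must be female/male")
        p["female"] = sex.map({"female": 1.0, "male": 0.0}).astype(float)
    if "education" in p.columns and "education_low" not in p.columns:
        edu = p["education"].astype("string").str.lower()
        p["education_low"] = edu.map({"low": 1.0, "high": 0.0}).astype(float)
    if "income" in p.columns and "income_low" not in p.columns:
        inc = p["income"].astype("string").str.lower()
        p["income_low"] = inc.map({"low": 1.0, "high": 0.0}).astype(float)
    return p


def read_cohort(
    visits_path,
    participants_path,
    sep: str = "\t",
    final_window_days: tuple[float, float] | None = None,
) -> Cohort:
    """Read and validate the two delimited-text cohort files.

    ``final_window_days``: optional ``(start, end)`` interval; when given
    and the participants file lacks ``has_final_window_fbg``, the flag is
    derived as "has at least one visit with ``start <= visit_time_days <=
    end``".

    Raises ``ValueError`` naming the offending row for unparseable values,
    invariant violations, duplicate visit keys, or visits referencing
    unknown participants.
    """
    visits = pd.read_csv(visits_path, sep=sep)
    participants = pd.read_csv(participants_path, sep=sep)
    visits = _check_visits(visits)

    if "participant_id" not in participants.columns:
        raise ValueError("participants file missing column participant_id")
    if participants["participant_id"].duplicated().any():
        row = participants.index[participants["participant_id"].duplicated()][0]
        raise ValueError(f"participant row {row}: duplicate participant_id")
    participants = _encode_categoricals(participants)
    if "age" in participants.columns:
        bad = participants.index[participants["age"].notna() & ~(participants["age"] > 0)]
        if len(bad):
            raise ValueError(f"participant row {bad[0]}: age must be positive")
    if "bmi" in participants.columns:
        bad = participants.index[participants["bmi"].notna() & ~(participants["bmi"] > 0)]
        if len(bad):
            raise ValueError(f"participant row {bad[0]}: bmi must be positive")

    known = set(participants["participant_id"])
    orphan = ~visits["participant_id"].isin(known)
    if orphan.any():
        row = visits.index[orphan][0]
        raise ValueError(
            f"visit row {row}: unknown participant_id "
            f"{visits.loc[row, 'participant_id']!r}"
        )

    if "has_final_window_fbg" not in participants.columns:
        if final_window_days is None:
            raise ValueError(
                "participants file lacks has_final_window_fbg; pass "
                "final_window_days=(start, end) to derive it from visit dates"
            )
        lo, hi = final_window_days
        in_win = visits[
            (visits["visit_time_days"] >= lo) & (visits["visit_time_days"] <= hi)
        ]
        flag = participants["participant_id"].isin(set(in_win["participant_id"]))
        participants = participants.assign(has_final_window_fbg=flag.astype(int))

    return Cohort(visits=visits.reset_index(drop=True), participants=participants.reset_index(drop=True))


def derive_comorbidity_flags(participants: pd.DataFrame) -> pd.DataFrame:
    """Derive hypertension and dyslipidemia flags where not pre-supplied.

    A flag already present and non-missing is respected and never
    overwritten.  Where every input to a flag is missing and no
    pre-supplied value exists, the flag stays missing (for later
    imputation).  Derivation is deterministic: a flag is 1 if any
    criterion holds, 0 if at least one input is observed and none holds.
    """
    p = participants.copy()

    def _any_criterion(criteria: list[pd.Series]) -> pd.Series:
        # OR with three-valued logic: 1 if any True; 0 if any observed and
        # none True; NaN if everything missing.
        stacked = pd.concat(criteria, axis=1)
        any_true = (stacked == 1).any(axis=1)
        any_obs = stacked.notna().any(axis=1)
        out = pd.Series(np.nan, index=p.index, dtype=float)
        out[any_obs] = 0.0
        out[any_true] = 1.0
        return out

    def _col(name: str) -> pd.Series:
        if name in p.columns:
            return pd.to_numeric(p[name], errors="coerce")
        return pd.Series(np.nan, index=p.index, dtype=float)

    def _thresh(name: str, op, thr: float) -> pd.Series:
        x = _col(name)
        out = pd.Series(np.nan, index=p.index, dtype=float)
        obs = x.notna()
        out[obs] = op(x[obs], thr).astype(float)
        return out

    import operator

    htn = _any_criterion(
        [
            _thresh("sbp", operator.ge, SBP_THRESHOLD),
            _thresh("dbp", operator.ge, DBP_THRESHOLD),
            _col("self_reported_hypertension"),
            _col("antihypertensive_use"),
        ]
    )
    dys = _any_criterion(
        [
            _thresh("ldl_c", operator.ge, LDL_THRESHOLD),
            _thresh("hdl_c", operator.lt, HDL_THRESHOLD),
            _thresh("tc", operator.ge, TC_THRESHOLD),
            _thresh("tg", operator.ge, TG_THRESHOLD),
            _col("self_reported_dyslipidemia"),
            _col("lipid_lowering_use"),
        ]
    )

    for name, derived in (("hypertension", htn), ("dyslipidemia", dys)):
        if name in p.columns:
            given = pd.to_numeric(p[name], errors="coerce")
            p[name] = given.where(given.notna(), derived)
        else:
            p[name] = derived
    return p


def apply_eligibility_filters(
    cohort: Cohort, min_visits: int = 3
) -> tuple[Cohort, FilterLog]:
    """Retain analysable participants; log exclusions per criterion.

    Criteria, applied in order: (1) at least ``min_visits`` FBG
    measurements; (2) an FBG test in the final screening window; (3) a
    non-missing retinopathy outcome.  Idempotent: filtering a filtered
    cohort removes no one.
    """
    log = FilterLog()
    p = cohort.participants
    if len(p) == 0:
        return Cohort(cohort.visits.iloc[0:0], p.iloc[0:0]), log

    counts = cohort.visits.groupby("participant_id").size()
    n_vis = p["participant_id"].map(counts).fillna(0).astype(int)
    keep = n_vis >= min_visits
    log.add(f"fewer than {min_visits} FBG tests", len(p), int((~keep).sum()))
    p = p[keep]

    if "has_final_window_fbg" not in p.columns:
        raise ValueError("participants table lacks has_final_window_fbg")
    flag = pd.to_numeric(p["has_final_window_fbg"], errors="coerce")
    keep = flag == 1
    log.add("no FBG test in final window", len(p), int((~keep).sum()))
    p = p[keep]

    dr = pd.to_numeric(p.get("dr_status"), errors="coerce")
    keep = dr.notna()
    log.add("missing retinopathy outcome", len(p), int((~keep).sum()))
    p = p[keep]

    visits = cohort.visits[
        cohort.visits["participant_id"].isin(set(p["participant_id"]))
    ]
    return Cohort(visits.reset_index(drop=True), p.reset_index(drop=True)), log


def impute_missing_covariates(
    cohort: Cohort,
    continuous: tuple = CONTINUOUS_COVARIATES,
    categorical: tuple = CATEGORICAL_COVARIATES,
) -> tuple[Cohort, pd.DataFrame]:
    """Single-value imputation of missing covariates.

    Continuous covariates are replaced by the cohort mean of observed
    values; 0/1 categorical covariates by the median of the numeric coding
    (which is the mode for binary variables; an exact tie, median 0.5,
    rounds down to 0).  Observed values are never altered.  Returns the
    imputed cohort and a report with one row per imputed variable.

    Raises ``ValueError`` if a listed covariate present in the table is
    missing for every participant.
    """
    p = cohort.participants.copy()
    report = []
    for col in continuous:
        if col not in p.columns:
            continue
        x = pd.to_numeric(p[col], errors="coerce")
        n_miss = int(x.isna().sum())
        if n_miss == 0:
            continue
        if n_miss == len(x):
            raise ValueError(f"covariate {col!r} missing for all participants")
        fill = float(x.mean())
        p[col] = x.fillna(fill)
        report.append({"variable": col, "n_imputed": n_miss, "fill_value": fill})
    for col in categorical:
        if col not in p.columns:
            continue
        x = pd.to_numeric(p[col], errors="coerce")
        n_miss = int(x.isna().sum())
        if n_miss == 0:
            continue
        if n_miss == len(x):
            raise ValueError(f"covariate {col!r} missing for all participants")
        med = float(x.median())
        fill = 0.0 if med == 0.5 else float(round(med))
        p[col] = x.fillna(fill)
        report.append({"variable": col, "n_imputed": n_miss, "fill_value": fill})
    report_df = pd.DataFrame(report, columns=["variable", "n_imputed", "fill_value"])
    return Cohort(cohort.visits, p), report_df
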