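"""Seeded synthetic longitudinal glucose cohort.

Emulates a community screening cohort in which participants attend up to
five health-screening waves over roughly eight years, give a fasting
glucose (FBG) measurement at each attended wave, and receive a binary
retinopathy outcome at the final ophthalmic examination.

The generative model, per participant:

* a latent glycemic class (normoglycemic / prediabetes / diabetes) drawn
  from a fixed mixture;
* a latent FBG level drawn around the class mean, plus a small linear
  drift per year, plus independent (optionally AR(1)) visit noise,
  truncated below at a physiologic floor;
* covariates with marginals matching a middle-aged community cohort
  (mean age ~46, about half female) and mild dependencies (men smoke and
  drink more, hypertension rises with age, dyslipidemia with BMI,
  education falls with age);
* a retinopathy label drawn from a logistic model whose linear predictor
  combines the participant's *true* cumulative FBG load (or, optionally,
  mean FBG or FBG standard deviation) with the covariates.  The default
  intercept is calibrated so that outcome prevalence is near 3.1%.

Latent truth (class, level, linear predictor, true glycemic burden) is
kept alongside the cohort so parameter-recovery tests have a known
target.  Regenerating with the same parameters and seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort
from .indices import DEFAULT_THRESHOLD, _segment_areas

__all__ = ["GeneratorParams", "SyntheticCohort", "generate_cohort", "truth_report"]


def _default_covariate_coefs() -> dict:
    # log-odds per unit of each covariate in the outcome model
    return {
        "age": 0.045,            # per year
        "female": -0.35,
        "bmi": 0.04,             # per kg/m^2
        "education_low": 0.50,
        "income_low": 0.25,
        "current_smoking": 0.30,
        "current_drinking": 0.25,
        "hypertension": 0.55,
        "dyslipidemia": 0.45,
    }


@dataclass
class GeneratorParams:
    """All knobs of the synthetic cohort, with study-scale defaults."""

    n_participants: int = 5054
    seed: int = 0

    # screening waves, days since cohort baseline, and attendance rates
    visit_wave_days: tuple = (0.0, 550.0, 1280.0, 2000.0, 2750.0)
    wave_attendance_prob: tuple = (0.95, 0.80, 0.80, 0.80, 0.85)

    # glycemic classes: normoglycemic / prediabetes / diabetes
    class_proportions: tuple = (0.55, 0.35, 0.10)
    class_level_mean: tuple = (5.15, 6.00, 8.00)    # mmol/L
    class_level_sd: tuple = (0.30, 0.45, 1.30)      # between-participant
    class_visit_sd: tuple = (0.40, 0.55, 1.10)      # within-participant, per visit
    class_drift_per_year: tuple = (0.0, 0.03, 0.08)  # mmol/L per year
    fbg_floor: float = 3.0                          # mmol/L
    ar1_rho: float = 0.0                            # visit-noise autocorrelation

    # covariate marginals
    age_mean: float = 46.3
    age_sd: float = 11.4
    female_frac: float = 0.52
    education_low_frac: float = 0.29
    income_low_frac: float = 0.81
    smoking_frac: float = 0.176
    drinking_frac: float = 0.217
    hypertension_frac: float = 0.265
    dyslipidemia_frac: float = 0.578
    bmi_mean: float = 24.6
    bmi_sd: float = 3.45

    # outcome model
    outcome_driver: str = "cum_load"        # or "m_fbg" / "sd"
    driver_coef: float = 0.08               # log-odds per unit of the driver
    covariate_coefs: dict = field(default_factory=_default_covariate_coefs)
    outcome_intercept: float = -8.506       # calibrated for ~3.1% prevalence
    glucose_threshold: float = DEFAULT_THRESHOLD

    # observed-data imperfections
    dr_missing_frac: float = 0.02
    covariate_missing_frac: float = 0.02

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        if len(self.visit_wave_days) != len(self.wave_attendance_prob):
            raise ValueError("one attendance probability per wave is required")
        if any(b <= a for a, b in zip(self.visit_wave_days, self.visit_wave_days[1:])):
            raise ValueError("visit_wave_days must be strictly increasing")
        if not np.isclose(sum(self.class_proportions), 1.0):
            raise ValueError("class_proportions must sum to 1")
        for name in ("wave_attendance_prob", "class_proportions"):
            vals = getattr(self, name)
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        for name in (
            "female_frac", "education_low_frac", "income_low_frac",
            "smoking_frac", "drinking_frac", "hypertension_frac",
            "dyslipidemia_frac", "dr_missing_frac", "covariate_missing_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.outcome_driver not in ("cum_load", "m_fbg", "sd"):
            raise ValueError("outcome_driver must be cum_load, m_fbg or sd")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in (-1, 1)")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its latent truth."""

    cohort: Cohort
    truth: pd.DataFrame
    params: GeneratorParams

    def write(self, outdir, sep: str = "\t") -> dict:
        """Write visits/participants (and the truth table) as delimited text."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "visits": outdir / "visits.tsv",
            "participants": outdir / "participants.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.cohort.visits.to_csv(paths["visits"], sep=sep, index=False)
        self.cohort.participants.to_csv(paths["participants"], sep=sep, index=False)
        self.truth.to_csv(paths["truth"], sep=sep, index=False)
        return paths


def _true_driver(
    visits: pd.DataFrame, pid_order: np.ndarray, driver: str, threshold: float
) -> np.ndarray:
    """True glycemic burden per participant, aligned to ``pid_order``.

    Single-visit participants get the constant-curve closed form for the
    load, the visit value itself for the mean, and 0 for the sd.
    """
    grp = visits.groupby("participant_id", sort=False)["fbg_mmol_l"]
    if driver == "m_fbg":
        return grp.mean().reindex(pid_order).to_numpy()
    if driver == "sd":
        return grp.std(ddof=1).reindex(pid_order).fillna(0.0).to_numpy()
    t = visits["visit_time_days"].to_numpy(dtype=float)
    f = visits["fbg_mmol_l"].to_numpy(dtype=float)
    ids = visits["participant_id"].to_numpy()
    same = ids[1:] == ids[:-1]
    total_seg, above_seg = _segment_areas(t[:-1], t[1:], f[:-1], f[1:], threshold)
    seg_pid = ids[1:][same]
    total = pd.Series(total_seg[same]).groupby(seg_pid).sum()
    above = pd.Series(above_seg[same]).groupby(seg_pid).sum()
    load = (100.0 * above / total).reindex(pid_order)
    # constant closed form for participants with a single visit
    single = grp.size().reindex(pid_order) == 1
    if single.any():
        one_val = grp.first().reindex(pid_order)
        load[single] = 100.0 * np.maximum(1.0 - threshold / one_val[single], 0.0)
    return load.to_numpy()


def generate_cohort(params: GeneratorParams | None = None) -> SyntheticCohort:
    """Draw one synthetic cohort from ``params`` (validated first)."""
    params = params or GeneratorParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    w = len(params.visit_wave_days)
    wave_t = np.asarray(params.visit_wave_days, dtype=float)

    if n == 0:
        empty_visits = pd.DataFrame(
            columns=["participant_id", "visit_time_days", "fbg_mmol_l"]
        )
        empty_participants = pd.DataFrame(columns=["participant_id"])
        return SyntheticCohort(
            Cohort(empty_visits, empty_participants), pd.DataFrame(), params
        )

    pid = np.array([f"P{i:06d}" for i in range(n)])

    # --- glycemic trajectory -------------------------------------------------
    cls = rng.choice(len(params.class_proportions), size=n,
                     p=np.asarray(params.class_proportions))
    level = rng.normal(np.asarray(params.class_level_mean)[cls],
                       np.asarray(params.class_level_sd)[cls])
    level = np.maximum(level, params.fbg_floor + 0.5)
    drift = np.asarray(params.class_drift_per_year)[cls]
    visit_sd = np.asarray(params.class_visit_sd)[cls]

    z = rng.standard_normal((n, w))
    if params.ar1_rho != 0.0:
        rho = params.ar1_rho
        e = np.empty_like(z)
        e[:, 0] = z[:, 0]
        for j in range(1, w):
            e[:, j] = rho * e[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
        z = e
    fbg = (
        level[:, None]
        + drift[:, None] * wave_t[None, :] / 365.25
        + visit_sd[:, None] * z
    )
    fbg = np.maximum(fbg, params.fbg_floor)

    attended = rng.random((n, w)) < np.asarray(params.wave_attendance_prob)[None, :]
    none_attended = ~attended.any(axis=1)
    attended[none_attended, 0] = True   # everyone enters the cohort at least once
    fbg_obs = np.where(attended, fbg, np.nan)

    # --- covariates ----------------------------------------------------------
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 20.0, 85.0)
    female = (rng.random(n) < params.female_frac).astype(float)
    bmi = np.clip(rng.normal(params.bmi_mean, params.bmi_sd, n), 15.0, 45.0)

    def _sex_split(target: float, p_female: float) -> np.ndarray:
        male_frac = 1.0 - params.female_frac
        p_male = np.clip((target - params.female_frac * p_female) / male_frac, 0, 1)
        return np.where(female == 1, p_female, p_male)

    smoking = (rng.random(n) < _sex_split(params.smoking_frac, 0.05)).astype(float)
    drinking = (rng.random(n) < _sex_split(params.drinking_frac, 0.07)).astype(float)
    logit = lambda p: np.log(p / (1 - p))
    htn_p = expit(logit(params.hypertension_frac) + 0.06 * (age - params.age_mean))
    hypertension = (rng.random(n) < htn_p).astype(float)
    dys_p = expit(logit(params.dyslipidemia_frac) + 0.08 * (bmi - params.bmi_mean))
    dyslipidemia = (rng.random(n) < dys_p).astype(float)
    edu_p = expit(logit(params.education_low_frac) + 0.05 * (age - params.age_mean))
    education_low = (rng.random(n) < edu_p).astype(float)
    income_low = (rng.random(n) < params.income_low_frac).astype(float)

    # --- visit table (needed for the true glycemic burden) -------------------
    v_rows, v_cols = np.nonzero(attended)
    visits = pd.DataFrame(
        {
            "participant_id": pid[v_rows],
            "visit_time_days": wave_t[v_cols],
            "fbg_mmol_l": np.round(fbg_obs[v_rows, v_cols], 6),
        }
    ).sort_values(["participant_id", "visit_time_days"], kind="mergesort")
    visits = visits.reset_index(drop=True)

    # --- outcome -------------------------------------------------------------
    driver = _true_driver(
        visits, pid, params.outcome_driver, params.glucose_threshold
    )
    covs = {
        "age": age, "female": female, "bmi": bmi,
        "education_low": education_low, "income_low": income_low,
        "current_smoking": smoking, "current_drinking": drinking,
        "hypertension": hypertension, "dyslipidemia": dyslipidemia,
    }
    lp = np.full(n, params.outcome_intercept)
    lp += params.driver_coef * driver
    for name, coef in params.covariate_coefs.items():
        lp += coef * covs[name]
    p_dr = expit(lp)
    dr = (rng.random(n) < p_dr).astype(float)
    dr_missing = rng.random(n) < params.dr_missing_frac
    dr_obs = np.where(dr_missing, np.nan, dr)

    # --- assemble tables -----------------------------------------------------
    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "age": np.round(age, 2),
            "sex": np.where(female == 1, "female", "male"),
            "education": np.where(education_low == 1, "low", "high"),
            "income": np.where(income_low == 1, "low", "high"),
            "current_smoking": smoking,
            "current_drinking": drinking,
            "bmi": np.round(bmi, 2),
            "hypertension": hypertension,
            "dyslipidemia": dyslipidemia,
            "dr_status": dr_obs,
            "has_final_window_fbg": attended[:, -1].astype(int),
            "female": female,
            "education_low": education_low,
            "income_low": income_low,
        }
    )
    if params.covariate_missing_frac > 0:
        for col in ("bmi", "current_smoking", "current_drinking", "hypertension"):
            mask = rng.random(n) < params.covariate_missing_frac
            participants.loc[mask, col] = np.nan

    truth = pd.DataFrame(
        {
            "participant_id": pid,
            "glycemic_class": np.array(["normo", "pre", "diabetes"])[cls],
            "level": level,
            "drift_per_year": drift,
            "true_driver": driver,
            "linear_predictor": lp,
            "p_dr": p_dr,
            "dr_latent": dr,
        }
    )
    return SyntheticCohort(Cohort(visits, participants), truth, params)


def truth_report(sc: SyntheticCohort) -> pd.DataFrame:
    """Realized marginals versus generator targets, one row per quantity."""
    if len(sc.truth) == 0:
        return pd.DataFrame(columns=["quantity", "target", "realized"])
    p = sc.cohort.participants
    v = sc.cohort.visits
    params = sc.params
    counts = sc.truth["glycemic_class"].value_counts()
    rows = [
        ("n_participants", params.n_participants, len(p)),
        ("class_normo", params.class_proportions[0],
         counts.get("normo", 0) / len(p)),
        ("class_pre", params.class_proportions[1], counts.get("pre", 0) / len(p)),
        ("class_diabetes", params.class_proportions[2],
         counts.get("diabetes", 0) / len(p)),
        ("female_frac", params.female_frac, float((p["female"] == 1).mean())),
        ("mean_age", params.age_mean, float(p["age"].mean())),
        ("mean_fbg", np.nan, float(v["fbg_mmol_l"].mean())),
        ("dr_prevalence", np.nan, float(pd.to_numeric(p["dr_status"]).mean())),
        ("driver_coef", params.driver_coef, params.driver_coef),
        ("outcome_intercept", params.outcome_intercept, params.outcome_intercept),
    ]
    return pd.DataFrame(rows, columns=["quantity", "target", "realized"])
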