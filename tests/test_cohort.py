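"""Tests for cohort ingestion, comorbidity flags, filters and imputation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fbgrisk.cohort import (
    Cohort,
    apply_eligibility_filters,
    derive_comorbidity_flags,
    impute_missing_covariates,
    read_cohort,
)


def write_files(tmp_path, visits: pd.DataFrame, participants: pd.DataFrame):
    vp = tmp_path / "visits.tsv"
    pp = tmp_path / "participants.tsv"
    visits.to_csv(vp, sep="\t", index=False)
    participants.to_csv(pp, sep="\t", index=False)
    return vp, pp


class TestReadCohort:
    def test_round_trip(self, tmp_path, toy_cohort):
        vp, pp = write_files(tmp_path, toy_cohort.visits, toy_cohort.participants)
        cohort = read_cohort(vp, pp)
        assert cohort.n_participants() == 3
        assert len(cohort.visits) == 10
        # visits come back time-sorted within participant
        for _, grp in cohort.visits.groupby("participant_id"):
            assert grp["visit_time_days"].is_monotonic_increasing

    def test_negative_fbg_names_row(self, tmp_path, toy_cohort):
        v = toy_cohort.visits.copy()
        v.loc[4, "fbg_mmol_l"] = -1.0
        vp, pp = write_files(tmp_path, v, toy_cohort.participants)
        with pytest.raises(ValueError, match="fbg_mmol_l must be positive"):
            read_cohort(vp, pp)

    def test_unknown_participant_is_referential_error(self, tmp_path, toy_cohort):
        v = toy_cohort.visits.copy()
        v.loc[0, "participant_id"] = "ghost"
        vp, pp = write_files(tmp_path, v, toy_cohort.participants)
        with pytest.raises(ValueError, match="unknown participant_id"):
            read_cohort(vp, pp)

    def test_duplicate_visit_key_rejected(self, tmp_path, toy_cohort):
        v = pd.concat([toy_cohort.visits, toy_cohort.visits.iloc[[0]]])
        vp, pp = write_files(tmp_path, v, toy_cohort.participants)
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort(vp, pp)

    def test_missing_column_rejected(self, tmp_path, toy_cohort):
        v = toy_cohort.visits.drop(columns=["fbg_mmol_l"])
        vp, pp = write_files(tmp_path, v, toy_cohort.participants)
        with pytest.raises(ValueError, match="missing columns"):
            read_cohort(vp, pp)

    def test_final_window_derived_from_dates(self, tmp_path, toy_cohort):
        p = toy_cohort.participants.drop(columns=["has_final_window_fbg"])
        vp, pp = write_files(tmp_path, toy_cohort.visits, p)
        cohort = read_cohort(vp, pp, final_window_days=(900, 1200))
        got = cohort.participants.set_index("participant_id")["has_final_window_fbg"]
        # a has a visit at 900, b at 1100, c at 1000
        assert got.to_dict() == {"a": 1, "b": 1, "c": 1}
        cohort = read_cohort(vp, pp, final_window_days=(1050, 1200))
        got = cohort.participants.set_index("participant_id")["has_final_window_fbg"]
        assert got.to_dict() == {"a": 0, "b": 1, "c": 0}

    def test_sex_strings_encoded(self, tmp_path, toy_cohort):
        p = toy_cohort.participants.drop(columns=["female"]).assign(
            sex=["female", "male", "female"]
        )
        vp, pp = write_files(tmp_path, toy_cohort.visits, p)
        cohort = read_cohort(vp, pp)
        assert cohort.participants["female"].tolist() == [1.0, 0.0, 1.0]


def brute_force_flag(criteria):
    """Three-valued OR over criterion values in {0, 1, None}."""
    vals = [c for c in criteria if c is not None]
    if any(c == 1 for c in vals):
        return 1.0
    if vals:
        return 0.0
    return np.nan


class TestComorbidityFlags:
    def test_dbp_alone_triggers_hypertension(self):
        p = pd.DataFrame({"participant_id": ["x"], "sbp": [138.0], "dbp": [92.0]})
        out = derive_comorbidity_flags(p)
        assert out.loc[0, "hypertension"] == 1.0

    def test_tg_just_below_threshold(self):
        p = pd.DataFrame(
            {
                "participant_id": ["x"],
                "ldl_c": [2.0],
                "hdl_c": [1.5],
                "tc": [4.0],
                "tg": [1.69],
            }
        )
        out = derive_comorbidity_flags(p)
        assert out.loc[0, "dyslipidemia"] == 0.0

    def test_self_report_alone_suffices(self):
        p = pd.DataFrame(
            {"participant_id": ["x"], "self_reported_dyslipidemia": [1.0]}
        )
        out = derive_comorbidity_flags(p)
        assert out.loc[0, "dyslipidemia"] == 1.0

    def test_all_inputs_missing_leaves_flag_missing(self):
        p = pd.DataFrame({"participant_id": ["x"]})
        out = derive_comorbidity_flags(p)
        assert np.isnan(out.loc[0, "hypertension"])
        assert np.isnan(out.loc[0, "dyslipidemia"])

    def test_pre_supplied_flag_never_overwritten(self):
        # measurements say hypertensive, but a pre-supplied 0 wins
        p = pd.DataFrame(
            {"participant_id": ["x"], "sbp": [160.0], "hypertension": [0.0]}
        )
        out = derive_comorbidity_flags(p)
        assert out.loc[0, "hypertension"] == 0.0

    def test_hypertension_truth_table(self):
        sbp_opts = [130.0, 145.0, None]
        dbp_opts = [85.0, 95.0, None]
        binary_opts = [0.0, 1.0, None]
        rows, expected = [], []
        for sbp, dbp, rep, med in itertools.product(
            sbp_opts, dbp_opts, binary_opts, binary_opts
        ):
            rows.append(
                {"sbp": sbp, "dbp": dbp, "self_reported_hypertension": rep,
                 "antihypertensive_use": med}
            )
            expected.append(
                brute_force_flag(
                    [
                        None if sbp is None else int(sbp >= 140),
                        None if dbp is None else int(dbp >= 90),
                        rep,
                        med,
                    ]
                )
            )
        p = pd.DataFrame(rows)
        p.insert(0, "participant_id", range(len(p)))
        got = derive_comorbidity_flags(p)["hypertension"].to_numpy()
        np.testing.assert_array_equal(got, np.array(expected, dtype=float))

    def test_dyslipidemia_truth_table(self):
        ldl_opts = [2.0, 3.37, None]
        hdl_opts = [1.03, 1.04, None]
        tg_opts = [1.5, 1.8, None]
        rows, expected = [], []
        for ldl, hdl, tg in itertools.product(ldl_opts, hdl_opts, tg_opts):
            rows.append({"ldl_c": ldl, "hdl_c": hdl, "tg": tg})
            expected.append(
                brute_force_flag(
                    [
                        None if ldl is None else int(ldl >= 3.37),
                        None if hdl is None else int(hdl < 1.04),
                        None if tg is None else int(tg >= 1.7),
                    ]
                )
            )
        p = pd.DataFrame(rows)
        p.insert(0, "participant_id", range(len(p)))
        got = derive_comorbidity_flags(p)["dyslipidemia"].to_numpy()
        np.testing.assert_array_equal(got, np.array(expected, dtype=float))


def small_cohort(spec):
    """Build a cohort from (n_visits, final_window, has_outcome) triples."""
    visits, participants = [], []
    for i, (nv, win, out) in enumerate(spec):
        pid = f"p{i}"
        for j in range(nv):
            visits.append(
                {"participant_id": pid, "visit_time_days": 400.0 * j,
                 "fbg_mmol_l": 5.5}
            )
        participants.append(
            {
                "participant_id": pid,
                "age": 50.0,
                "has_final_window_fbg": int(win),
                "dr_status": 0.0 if out else np.nan,
            }
        )
    return Cohort(pd.DataFrame(visits), pd.DataFrame(participants))


class TestEligibilityFilters:
    def test_enumeration_example(self):
        cohort = small_cohort(
            [(2, 1, 1), (3, 1, 1), (4, 0, 1), (5, 1, 0), (3, 1, 1)]
        )
        kept, log = apply_eligibility_filters(cohort)
        assert kept.n_participants() == 2
        assert set(kept.participants["participant_id"]) == {"p1", "p4"}
        frame = log.to_frame()
        assert frame["n_excluded"].tolist() == [1, 1, 1]
        assert set(kept.visits["participant_id"]) == {"p1", "p4"}

    def test_all_eligible_is_identity(self):
        cohort = small_cohort([(3, 1, 1), (5, 1, 1)])
        kept, log = apply_eligibility_filters(cohort)
        assert kept.n_participants() == 2
        assert log.to_frame()["n_excluded"].sum() == 0

    def test_three_visits_boundary_inclusive(self):
        cohort = small_cohort([(3, 1, 1)])
        kept, _ = apply_eligibility_filters(cohort)
        assert kept.n_participants() == 1

    def test_empty_cohort(self):
        cohort = small_cohort([])
        kept, log = apply_eligibility_filters(cohort)
        assert kept.n_participants() == 0
        assert log.to_frame().empty

    def test_idempotent(self):
        cohort = small_cohort(
            [(2, 1, 1), (3, 1, 1), (4, 0, 1), (5, 1, 0), (4, 1, 1)]
        )
        once, _ = apply_eligibility_filters(cohort)
        twice, log2 = apply_eligibility_filters(once)
        pd.testing.assert_frame_equal(
            once.participants.reset_index(drop=True),
            twice.participants.reset_index(drop=True),
        )
        assert log2.to_frame()["n_excluded"].sum() == 0


class TestImputation:
    def _cohort(self, **cols):
        n = len(next(iter(cols.values())))
        p = pd.DataFrame({"participant_id": [f"p{i}" for i in range(n)], **cols})
        return Cohort(pd.DataFrame(columns=["participant_id", "visit_time_days",
                                            "fbg_mmol_l"]), p)

    def test_continuous_mean(self):
        c = self._cohort(bmi=[20.0, 30.0, np.nan])
        out, report = impute_missing_covariates(c)
        assert out.participants["bmi"].tolist() == [20.0, 30.0, 25.0]
        assert report.iloc[0]["n_imputed"] == 1

    def test_categorical_median_of_coding(self):
        c = self._cohort(current_smoking=[0.0, 0.0, 0.0, 1.0, np.nan])
        out, _ = impute_missing_covariates(c)
        assert out.participants["current_smoking"].tolist()[-1] == 0.0

    def test_categorical_tie_rounds_down(self):
        c = self._cohort(current_smoking=[0.0, 0.0, 1.0, 1.0, np.nan])
        out, _ = impute_missing_covariates(c)
        assert out.participants["current_smoking"].iloc[-1] == 0.0

    def test_no_missing_is_identity_with_empty_report(self):
        c = self._cohort(bmi=[22.0, 25.0], current_smoking=[0.0, 1.0])
        out, report = impute_missing_covariates(c)
        pd.testing.assert_frame_equal(out.participants, c.participants)
        assert report.empty

    def test_observed_values_never_altered(self, rng):
        bmi = rng.uniform(18, 35, 50)
        bmi[rng.random(50) < 0.2] = np.nan
        c = self._cohort(bmi=bmi)
        out, _ = impute_missing_covariates(c)
        obs = ~np.isnan(bmi)
        np.testing.assert_array_equal(out.participants["bmi"].to_numpy()[obs],
                                      bmi[obs])
        assert out.participants["bmi"].notna().all()

    def test_all_missing_errors(self):
        c = self._cohort(bmi=[np.nan, np.nan])
        with pytest.raises(ValueError, match="missing for all"):
            impute_missing_covariates(c)
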