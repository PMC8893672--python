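import numpy as np
import pandas as pd
import pytest

import coclaims as cc
from coclaims.cohort_builder import EXCLUSION_ORDER

from conftest import make_dispensations, make_service_claims

ACCRUAL = ("2012-01-01", "2017-12-31")


def _mini_dataset(config, persons=None, dispensations=None,
                  service_claims=None, hospital_stays=None,
                  coverage=None, ed_visits=None):
    ds = cc.empty_dataset()
    if persons is not None:
        ds.persons = pd.DataFrame(persons)
    if dispensations is not None:
        ds.dispensations = dispensations
    if service_claims is not None:
        ds.service_claims = service_claims
    if hospital_stays is not None:
        ds.hospital_stays = pd.DataFrame(hospital_stays)
    if coverage is not None:
        ds.coverage = pd.DataFrame(coverage)
    if ed_visits is not None:
        ds.ed_visits = pd.DataFrame(ed_visits)
    return ds


def _person(pid, birth="1960-01-01", sex="M", quintile=3, ltc=()):
    return dict(person_id=pid, birth_date=pd.Timestamp(birth), sex=sex,
                residence="urban", income_quintile=quintile,
                ltc_admission_dates=[pd.Timestamp(d) for d in ltc])


def _full_coverage(pid, index="2015-06-01"):
    index = pd.Timestamp(index)
    return dict(person_id=pid, start=index - pd.Timedelta(days=2000),
                end=index + pd.Timedelta(days=400))


class TestFindNewUsers:
    def test_in_window_user_included_at_earliest_date(self, config):
        disp = make_dispensations([
            ("P1", "GP1", "STATIN01", "2015-06-01", 90),
            ("P1", "GP1", "STATIN02", "2015-09-01", 90)])
        ds = _mini_dataset(config, dispensations=disp)
        users = cc.find_new_users(ds, config, ACCRUAL)
        assert list(users["person_id"]) == ["P1"]
        assert users.loc[0, "index_date"] == pd.Timestamp("2015-06-01")

    def test_statin_four_years_prior_violates_clean_period(self, config):
        disp = make_dispensations([
            ("P1", "GP1", "STATIN01", "2011-06-01", 90),
            ("P1", "GP1", "STATIN01", "2015-06-01", 90)])
        ds = _mini_dataset(config, dispensations=disp)
        assert len(cc.find_new_users(ds, config, ACCRUAL)) == 0

    def test_statin_six_years_prior_is_outside_clean_period(self, config):
        disp = make_dispensations([
            ("P1", "GP1", "STATIN01", "2009-05-01", 90),
            ("P1", "GP1", "STATIN01", "2015-06-01", 90)])
        ds = _mini_dataset(config, dispensations=disp)
        users = cc.find_new_users(ds, config, ACCRUAL)
        assert users.loc[0, "index_date"] == pd.Timestamp("2015-06-01")

    def test_synthetic_generator_guarantees_clean_period(self, synth500,
                                                         config):
        params, dataset, _ = synth500
        assert len(cc.find_new_users(dataset, config,
                                     params.study_window)) == 500

    def test_empty_accrual_window_rejected(self, config):
        ds = _mini_dataset(config)
        with pytest.raises(ValueError):
            cc.find_new_users(ds, config, ("2015-01-01", "2014-01-01"))


class TestExclusions:
    def _base(self, config, **overrides):
        persons = [_person("P1")]
        disp = make_dispensations([
            ("P1", "GP1", "STATIN01", "2015-06-01", 90)])
        claims = make_service_claims([
            ("P1", "GP1", "GP", "2015-07-01")])
        coverage = [_full_coverage("P1")]
        kwargs = dict(persons=persons, dispensations=disp,
                      service_claims=claims, coverage=coverage)
        kwargs.update(overrides)
        return _mini_dataset(config, **kwargs)

    def _run(self, ds, config):
        candidates = cc.find_new_users(ds, config, ACCRUAL)
        return cc.apply_exclusions(candidates, ds, config)

    def test_clean_candidate_enters_cohort(self, config):
        cohort, flow = self._run(self._base(config), config)
        assert len(cohort) == 1
        assert cohort.loc[0, "age_at_index"] == 55
        assert (cohort.loc[0, "followup_end"]
                - cohort.loc[0, "followup_start"]).days == 365

    def test_under_18_excluded(self, config):
        ds = self._base(config, persons=[_person("P1", birth="1998-01-01")])
        cohort, flow = self._run(ds, config)
        assert len(cohort) == 0
        assert flow.removed["under_18"] == 1

    def test_first_failure_attribution(self, config):
        # fails both under-18 (2) and no-GP-visits (7): reported under 2 only
        ds = self._base(config, persons=[_person("P1", birth="1998-01-01")],
                        service_claims=cc.empty_dataset().service_claims)
        _, flow = self._run(ds, config)
        assert flow.removed["under_18"] == 1
        assert flow.removed["no_gp_visits"] == 0

    def test_missing_sex_excluded_first(self, config):
        ds = self._base(config, persons=[_person("P1", sex=None)])
        _, flow = self._run(ds, config)
        assert flow.removed["missing_demog"] == 1

    def test_coverage_gap_excluded(self, config):
        cov = [dict(person_id="P1",
                    start=pd.Timestamp("2013-01-01"),
                    end=pd.Timestamp("2016-12-31"))]
        _, flow = self._run(self._base(config, coverage=cov), config)
        assert flow.removed["coverage_gap"] == 1

    def test_single_day_coverage_gap_counts(self, config):
        # two intervals with exactly one uncovered day between them
        index = pd.Timestamp("2015-06-01")
        cov = [dict(person_id="P1", start=index - pd.Timedelta(days=2000),
                    end=index),
               dict(person_id="P1", start=index + pd.Timedelta(days=2),
                    end=index + pd.Timedelta(days=400))]
        _, flow = self._run(self._base(config, coverage=cov), config)
        assert flow.removed["coverage_gap"] == 1

    def test_ltc_admission_excluded(self, config):
        ds = self._base(config,
                        persons=[_person("P1", ltc=["2013-03-01"])])
        _, flow = self._run(ds, config)
        assert flow.removed["ltc"] == 1

    def test_pregnancy_code_in_followup_excluded(self, config):
        claims = make_service_claims([
            ("P1", "GP1", "GP", "2015-07-01"),
            ("P1", "GP1", "GP", "2015-08-01", {"diagnosis_code": "V272"})])
        _, flow = self._run(self._base(config, service_claims=claims),
                            config)
        assert flow.removed["pregnancy"] == 1

    def test_no_gp_visits_excluded(self, config):
        claims = make_service_claims([
            ("P1", "SP1", "specialist", "2015-07-01")])
        _, flow = self._run(self._base(config, service_claims=claims),
                            config)
        assert flow.removed["no_gp_visits"] == 1

    def test_flow_report_matches_injected_exclusions(self, synth500,
                                                     config):
        params, dataset, _ = synth500
        counts = {"under_18": 10, "pregnancy": 5, "missing_demog": 3,
                  "coverage_gap": 4, "ltc": 2, "out_province_hospital": 2,
                  "no_gp_visits": 6}
        perturbed, injected = cc.perturb_for_exclusions(dataset, params,
                                                        counts)
        candidates = cc.find_new_users(perturbed, config,
                                       params.study_window)
        cohort, flow = cc.apply_exclusions(candidates, perturbed, config)
        assert flow.removed == {k: counts.get(k, 0)
                                for k in EXCLUSION_ORDER}
        assert len(cohort) == 500
        # the injected ids are exactly the excluded ones
        excluded = set(candidates["person_id"]) - set(cohort["person_id"])
        assert excluded == {pid for ids in injected.values()
                            for pid in ids}

    def test_row_order_invariance(self, synth500, config):
        params, dataset, _ = synth500
        perturbed, _ = cc.perturb_for_exclusions(
            dataset, params, {"under_18": 4, "ltc": 3})
        rng = np.random.default_rng(0)
        shuffled = cc.ClaimsDataset(
            **{name: getattr(perturbed, name)
               .sample(frac=1, random_state=rng.integers(1 << 30))
               .reset_index(drop=True)
               for name in ["persons", "service_claims", "dispensations",
                            "hospital_stays", "ed_visits", "coverage"]})
        cand_a = cc.find_new_users(perturbed, config, params.study_window)
        cand_b = cc.find_new_users(shuffled, config, params.study_window)
        cohort_a, flow_a = cc.apply_exclusions(cand_a, perturbed, config)
        cohort_b, flow_b = cc.apply_exclusions(cand_b, shuffled, config)
        assert flow_a.removed == flow_b.removed
        pd.testing.assert_frame_equal(
            cohort_a.sort_values("person_id").reset_index(drop=True),
            cohort_b.sort_values("person_id").reset_index(drop=True))

    def test_flow_totals_balance(self, synth500, config):
        params, dataset, _ = synth500
        perturbed, _ = cc.perturb_for_exclusions(
            dataset, params, {"under_18": 7, "no_gp_visits": 3})
        candidates = cc.find_new_users(perturbed, config,
                                       params.study_window)
        cohort, flow = cc.apply_exclusions(candidates, perturbed, config)
        assert sum(flow.removed.values()) + len(cohort) == len(candidates)
        frame = flow.to_frame()
        assert frame.loc[frame["stage"] == "candidates", "n"].iloc[0] \
            == len(candidates)


class TestCovariates:
    def _cohort(self, index="2015-06-01"):
        index = pd.Timestamp(index)
        return pd.DataFrame([dict(
            person_id="P1", index_date=index, age_at_index=55,
            followup_start=index,
            followup_end=index + pd.Timedelta(days=365))])

    def test_no_prior_activity_gives_zeros(self, config):
        ds = _mini_dataset(config, persons=[_person("P1")])
        cov = cc.build_covariates(self._cohort(), ds, config)
        row = cov.iloc[0]
        for col in ["n_gp_visits_prior", "n_specialist_visits_prior",
                    "n_hospitalizations_prior", "n_ed_visits_prior",
                    "n_distinct_drugs_prior", "charlson_score"]:
            assert row[col] == 0
        assert row["govt_paid_pct"] == 0.0
        assert row["income_quintile"] == "3"

    def test_charlson_sums_distinct_condition_weights(self, config):
        # 4109 -> myocardial infarction (1), N189 -> renal disease (2)
        claims = make_service_claims([
            ("P1", "GP1", "GP", "2015-01-10", {"diagnosis_code": "4109"}),
            ("P1", "GP1", "GP", "2015-02-10", {"diagnosis_code": "N189"}),
            ("P1", "GP1", "GP", "2015-03-10", {"diagnosis_code": "4101"}),
        ])
        ds = _mini_dataset(config, persons=[_person("P1")],
                           service_claims=claims)
        cov = cc.build_covariates(self._cohort(), ds, config)
        assert cov.iloc[0]["charlson_score"] == 3  # 1 + 2, MI counted once

    def test_govt_paid_pct_is_cost_weighted(self, config):
        disp = make_dispensations([
            ("P1", "GP1", "RX01", "2015-01-15", 30),
            ("P1", "GP1", "RX02", "2015-02-15", 30)])
        disp.loc[0, ["total_cost", "govt_paid_fraction"]] = [100.0, 1.0]
        disp.loc[1, ["total_cost", "govt_paid_fraction"]] = [100.0, 0.5]
        ds = _mini_dataset(config, persons=[_person("P1")],
                           dispensations=disp)
        cov = cc.build_covariates(self._cohort(), ds, config)
        assert cov.iloc[0]["govt_paid_pct"] == pytest.approx(0.75)
        assert cov.iloc[0]["n_distinct_drugs_prior"] == 2

    def test_prior_visit_counts_deduplicate_same_day_claims(self, config):
        claims = make_service_claims([
            ("P1", "GP1", "GP", "2015-01-10"),
            ("P1", "GP1", "GP", "2015-01-10", {"fee_code": "OTHER"}),
            ("P1", "GP1", "GP", "2015-02-10"),
            ("P1", "SP1", "specialist", "2015-03-10"),
            ("P1", "GP1", "GP", "2015-06-10"),  # on index: not prior
        ])
        ds = _mini_dataset(config, persons=[_person("P1")],
                           service_claims=claims)
        cov = cc.build_covariates(self._cohort(), ds, config)
        assert cov.iloc[0]["n_gp_visits_prior"] == 2
        assert cov.iloc[0]["n_specialist_visits_prior"] == 1

    def test_condition_flag_from_din_history(self, config):
        disp = make_dispensations([
            ("P1", "GP1", "DMRX01", "2010-01-15", 30)])
        ds = _mini_dataset(config, persons=[_person("P1")],
                           dispensations=disp)
        cov = cc.build_covariates(self._cohort(), ds, config)
        assert cov.iloc[0]["cond_diabetes"]
        assert not cov.iloc[0]["cond_hypertension"]
        assert cov.iloc[0]["n_distinct_drugs_prior"] == 0  # outside year
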