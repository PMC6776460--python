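"""Landmark cohorts, Aalen–Johansen estimation, absolute-risk prediction."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import deltameld as dm
from deltameld.calibration import (LandmarkCohort, landmark_counting_rows,
                                   predict_absolute_risk)
from deltameld.cox import ModelSpec, fit_csh

from .conftest import make_records


def members_of(*triples):
    return pd.DataFrame(
        [dict(registrant_id=f"m{i}", landmark_date=0.0, time=float(t),
              status=s, jump=j) for i, (t, s, j) in enumerate(triples)])


class TestBuildLandmark:
    def test_retiming_from_first_attainment(self):
        feats = dm.compute_delta_meld(
            make_records([(0, 20), (40, 25), (70, 25, "died")]))
        cohort = dm.build_landmark(feats, 25)
        m = cohort.members.iloc[0]
        assert m.landmark_date == 40
        assert m.time == 30 and m.status == "dropout"

    def test_skipped_level_not_member_exact(self):
        feats = dm.compute_delta_meld(
            make_records([(0, 24), (30, 26), (60, 26, "transplanted")]))
        assert len(dm.build_landmark(feats, 25)) == 0
        assert len(dm.build_landmark(feats, 25, mode="crossing")) == 1

    def test_event_before_level_not_member(self):
        feats = dm.compute_delta_meld(
            make_records([(0, 20), (30, 22, "transplanted")]))
        assert len(dm.build_landmark(feats, 30)) == 0

    def test_jump_status_frozen_at_landmark(self):
        feats = dm.compute_delta_meld(
            make_records([(0, 14), (10, 25), (30, 25, "died")]))
        cohort = dm.build_landmark(feats, 25)
        assert cohort.members.jump.tolist() == [1]

    def test_at_most_one_membership(self, default_cohort_rows):
        feats, _ = default_cohort_rows
        cohort = dm.build_landmark(feats, 28)
        assert cohort.members.registrant_id.is_unique

    def test_empty_cohort_warns(self):
        feats = dm.compute_delta_meld(make_records([(0, 20), (30, 21)]))
        with pytest.warns(UserWarning, match="attain"):
            cohort = dm.build_landmark(feats, 40)
        assert len(cohort) == 0


class TestAalenJohansen:
    def test_hand_computed_three_subjects(self):
        mem = members_of((10, "dropout", 0), (20, "transplant", 0),
                         (30, "censored", 0))
        do = dm.aalen_johansen(mem, "dropout")
        tx = dm.aalen_johansen(mem, "transplant")
        assert do.at(10) == pytest.approx(1 / 3)
        assert do.at(25) == pytest.approx(1 / 3)
        assert tx.at(19.9) == 0.0
        assert tx.at(20) == pytest.approx((2 / 3) * (1 / 2))
        assert do.at(5) == 0.0

    def test_single_cause_reduces_to_one_minus_km(self):
        rng = np.random.default_rng(2)
        t = rng.integers(1, 40, 60).astype(float)
        status = np.where(rng.random(60) < 0.7, "dropout", "censored")
        mem = pd.DataFrame({"time": t, "status": status})
        cif = dm.aalen_johansen(mem, "dropout")
        from lifelines import KaplanMeierFitter
        km = KaplanMeierFitter().fit(t, status == "dropout")
        for tt in cif.times:
            assert cif.at(tt) == pytest.approx(
                1 - km.survival_function_at_times(tt).iloc[0], abs=1e-12)

    def test_cause_cifs_sum_below_one(self, default_cohort_rows):
        feats, _ = default_cohort_rows
        cohort = dm.build_landmark(feats, 30)
        do = dm.aalen_johansen(cohort, "dropout")
        tx = dm.aalen_johansen(cohort, "transplant")
        grid = np.union1d(do.times, tx.times)
        total = np.array([do.at(t) + tx.at(t) for t in grid])
        assert (total <= 1 + 1e-12).all()
        assert (np.diff([do.at(t) for t in grid]) >= 0).all()

    def test_bands_bracket_estimate(self):
        mem = members_of(*[(t, "dropout" if t % 2 else "censored", 0)
                           for t in range(1, 30)])
        c = dm.aalen_johansen(mem, "dropout")
        assert (c.ci_lower <= c.cif + 1e-12).all()
        assert (c.cif <= c.ci_upper + 1e-12).all()


class TestPredictAbsoluteRisk:
    @staticmethod
    def null_fits(mem):
        rows = landmark_counting_rows(LandmarkCohort(20, mem))
        fd = fit_csh(rows, ModelSpec(cause="dropout", terms=("meld",), max_iter=0))
        ft = fit_csh(rows, ModelSpec(cause="transplant", terms=("meld",), max_iter=0))
        return fd, ft

    def test_null_model_equals_aalen_johansen(self):
        rng = np.random.default_rng(3)
        mem = members_of(*[(int(t) + 1,
                            ["dropout", "transplant", "censored"][s], 0)
                           for t, s in zip(rng.exponential(60, 80),
                                           rng.integers(0, 3, 80))])
        fd, ft = self.null_fits(mem)
        aj = dm.aalen_johansen(mem, "dropout")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = predict_absolute_risk(fd, ft, {"meld": 20.0},
                                         horizons=(30.0, 90.0, 180.0))
        assert pred == pytest.approx([aj.at(30), aj.at(90), aj.at(180)],
                                     abs=1e-12)

    def test_constant_hazard_closed_form(self):
        # exponential competing risks: CIF_d(t) = hd/(hd+ht)(1-exp(-(hd+ht)t))
        hd, ht = 4e-3, 8e-3
        rng = np.random.default_rng(4)
        n = 4000
        te = rng.exponential(1 / (hd + ht), n)
        cause = np.where(rng.random(n) < hd / (hd + ht), "dropout", "transplant")
        mem = members_of(*[(t, c, 0) for t, c in zip(te, cause)])
        fd, ft = self.null_fits(mem)
        pred = predict_absolute_risk(fd, ft, {"meld": 20.0},
                                     horizons=(30.0, 90.0, 180.0))
        for p, t in zip(pred, (30, 90, 180)):
            closed = hd / (hd + ht) * (1 - math.exp(-(hd + ht) * t))
            assert p == pytest.approx(closed, rel=0.12)

    def test_monotone_in_dropout_linear_predictor(self, recovery_pipeline):
        _, feats, _ = recovery_pipeline
        cohort = dm.build_landmark(feats, 30)
        rows = landmark_counting_rows(cohort)
        rows["noise"] = np.tile([0.0, 1.0], len(rows))[: len(rows)]
        fd = fit_csh(rows, ModelSpec(cause="dropout", terms=("jump",)))
        ft = fit_csh(rows, ModelSpec(cause="transplant", terms=("jump",)))
        lo = predict_absolute_risk(fd, ft, {"jump": 0.0})
        hi = predict_absolute_risk(fd, ft, {"jump": 1.0})
        if fd.beta[0] > 0:
            assert (hi >= lo - 1e-12).all()

    def test_horizon_beyond_data_warns(self):
        mem = members_of((5, "dropout", 0), (8, "transplant", 0), (9, "censored", 0))
        fd, ft = self.null_fits(mem)
        with pytest.warns(UserWarning, match="beyond"):
            predict_absolute_risk(fd, ft, {"meld": 20.0}, horizons=(500.0,))
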