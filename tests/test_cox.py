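"""Cox engine vs enumeration oracles, R-verified fixtures, and invariances."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import deltameld as dm
from deltameld.cox import (ConvergenceError, ModelSpec, SingularInformationError,
                           fit_csh, harrell_cindex)


def cp_frame(subjects):
    """Plain survival rows from (time, event, covariate...) tuples."""
    rows = []
    for i, (t, e, *x) in enumerate(subjects):
        rows.append(dict(registrant_id=f"s{i}", start=0.0, stop=float(t),
                         event_dropout=int(e), event_transplant=0,
                         **{f"x{j}": float(v) for j, v in enumerate(x)}))
    return pd.DataFrame(rows)


def brute_partial_loglik(df, beta, ties="breslow"):
    """Enumerate every risk set explicitly; no shared code with the fitter."""
    start = df.start.to_numpy()
    stop = df.stop.to_numpy()
    event = df.event_dropout.to_numpy()
    x = df.x0.to_numpy()
    ll = 0.0
    for t in sorted(set(stop[event == 1])):
        dead = [i for i in range(len(df)) if event[i] and stop[i] == t]
        risk = [i for i in range(len(df)) if start[i] < t <= stop[i]]
        d = len(dead)
        tie_sum = sum(math.exp(beta * x[i]) for i in dead)
        for l, i in enumerate(dead):
            denom = sum(math.exp(beta * x[j]) for j in risk)
            if ties == "efron":
                denom -= (l / d) * tie_sum
            ll += beta * x[i] - math.log(denom)
    return ll


FOUR_SUBJECTS = [(2, 1, 1), (4, 1, 0), (6, 1, 1), (9, 0, 0)]


@pytest.mark.parametrize("ties", ["breslow", "efron"])
def test_beta_matches_grid_search_oracle(ties):
    """Fitted coefficient equals the maximiser of the explicitly enumerated
    partial likelihood, to 1e-6."""
    df = cp_frame(FOUR_SUBJECTS)
    fit = fit_csh(df, ModelSpec(cause="dropout", terms=("x0",),
                                ties_method=ties, tol=1e-12))
    res = minimize_scalar(lambda b: -brute_partial_loglik(df, b, ties),
                          bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    assert abs(fit.beta[0] - res.x) < 1e-6
    assert math.isclose(fit.loglik, -res.fun, rel_tol=1e-9)


def test_loglik_matches_enumeration_on_ties():
    subjects = [(3, 1, 1), (3, 1, 0), (3, 1, 1), (5, 1, 0), (7, 0, 1),
                (8, 1, 1), (8, 1, 0), (9, 0, 0)]
    df = cp_frame(subjects)
    for ties in ("breslow", "efron"):
        fit = fit_csh(df, ModelSpec(cause="dropout", terms=("x0",),
                                    ties_method=ties))
        assert math.isclose(fit.loglik,
                            brute_partial_loglik(df, fit.beta[0], ties),
                            rel_tol=1e-10)


def test_efron_equals_breslow_on_unique_event_times():
    rng = np.random.default_rng(0)
    subjects = [(t, e, x) for t, e, x in zip(
        rng.uniform(1, 100, 30), rng.integers(0, 2, 30), rng.normal(size=30))]
    df = cp_frame(subjects)
    fe = fit_csh(df, ModelSpec(cause="dropout", terms=("x0",), ties_method="efron"))
    fb = fit_csh(df, ModelSpec(cause="dropout", terms=("x0",), ties_method="breslow"))
    assert np.allclose(fe.beta, fb.beta, atol=1e-8)
    assert math.isclose(fe.loglik, fb.loglik, rel_tol=1e-10)


def test_matches_survival_coxph_frozen_fixture():
    """Deterministic simulated dataset whose fit was checked against R's
    survival::coxph (counting-process Surv(start, stop, event))."""
    cfg = dm.recovery_scenario(n=300, seed=5)
    kept, _ = dm.filter_cohort(dm.simulate_registry(cfg))
    rows = dm.cohort_counting_process(dm.compute_delta_meld(kept))
    expected = {  # from survival::coxph, both ties methods
        "efron": ([0.1664264, 0.7499073], [0.01180856, 0.2173022], -445.8698),
        "breslow": ([0.1662060, 0.7454130], [0.01180026, 0.2173506], -446.2874),
    }
    for ties, (beta, se, ll) in expected.items():
        fit = fit_csh(rows, ModelSpec(cause="dropout",
                                      terms=("meld_capped", "ind_ge10"),
                                      ties_method=ties))
        assert np.allclose(fit.beta, beta, atol=5e-7)
        assert np.allclose(fit.se, se, atol=5e-7)
        assert math.isclose(fit.loglik, ll, abs_tol=5e-4)


def test_constant_covariate_raises_singular():
    df = cp_frame([(2, 1, 1), (4, 1, 1), (6, 0, 1)])
    with pytest.raises(SingularInformationError, match="x0"):
        fit_csh(df, ModelSpec(cause="dropout", terms=("x0",)))


def test_separation_raises_convergence_error():
    # covariate perfectly orders event vs censored subjects
    df = cp_frame([(1, 1, 1), (2, 1, 1), (10, 0, 0), (11, 0, 0)])
    with pytest.raises((ConvergenceError, SingularInformationError)):
        fit_csh(df, ModelSpec(cause="dropout", terms=("x0",), max_iter=200))


def test_no_events_raises():
    df = cp_frame([(2, 0, 1), (4, 0, 0)])
    with pytest.raises(ValueError, match="transplant"):
        fit_csh(df, ModelSpec(cause="transplant", terms=("x0",)))


def test_centering_and_scaling_invariance():
    rng = np.random.default_rng(1)
    df = cp_frame([(t, e, x) for t, e, x in zip(
        rng.uniform(1, 50, 40), rng.integers(0, 2, 40), rng.normal(2, 1, 40))])
    base = fit_csh(df, ModelSpec(cause="dropout", terms=("x0",)))
    shifted = df.assign(x0=df.x0 + 7.5)
    scaled = df.assign(x0=df.x0 * 4.0)
    assert np.allclose(fit_csh(shifted, ModelSpec(cause="dropout", terms=("x0",))).beta,
                       base.beta, atol=1e-7)
    assert np.allclose(fit_csh(scaled, ModelSpec(cause="dropout", terms=("x0",))).beta,
                       base.beta / 4.0, atol=1e-7)


def test_json_round_trip(tmp_path):
    df = cp_frame(FOUR_SUBJECTS)
    fit = fit_csh(df, ModelSpec(cause="dropout", terms=("x0",)))
    p = tmp_path / "fit.json"
    fit.to_json(p)
    back = dm.CoxModelFit.from_json(p)
    assert np.array_equal(back.beta, fit.beta)
    assert np.array_equal(back.vcov, fit.vcov)
    assert np.array_equal(back.baseline_hazard, fit.baseline_hazard)
    assert back.loglik == fit.loglik


class TestStratifiedJumpModel:
    def test_null_strata_cover_one(self, recovery_pipeline):
        # on a null-jump simulation, stratum CIs should bracket HR = 1
        cfg = dm.recovery_scenario(n=2500, seed=13,
                                   beta_jump_dropout_by_stratum={},
                                   beta_jump_tx_by_stratum={})
        kept, _ = dm.filter_cohort(dm.simulate_registry(cfg))
        rows = dm.cohort_counting_process(dm.compute_delta_meld(kept))
        tab, _ = dm.fit_stratified_jump_model(rows, "dropout")
        ok = tab.dropna(subset=["hr"])
        covers = ((ok.hr_lo95 <= 1.0) & (1.0 <= ok.hr_hi95)).sum()
        assert covers >= len(ok) - 1  # nominal 95 % coverage

    def test_sparse_stratum_reported_na(self):
        cfg = dm.recovery_scenario(n=400, seed=3,
                                   jump_prob_by_meld={(6, 40): 0.0})
        kept, _ = dm.filter_cohort(dm.simulate_registry(cfg))
        rows = dm.cohort_counting_process(dm.compute_delta_meld(kept))
        with pytest.warns(UserWarning, match="NA"):
            tab, _ = dm.fit_stratified_jump_model(rows, "dropout")
        assert tab.hr.isna().all()


class TestCindex:
    def test_perfect_ordering(self):
        df = cp_frame([(1, 1, 0), (2, 1, 0), (3, 1, 0), (4, 1, 0)])
        c, _ = harrell_cindex(df, [4, 3, 2, 1], "dropout")
        assert c == 1.0

    def test_all_tied_scores(self):
        df = cp_frame([(1, 1, 0), (2, 1, 0), (3, 0, 0), (4, 1, 0)])
        c, _ = harrell_cindex(df, [5, 5, 5, 5], "dropout")
        assert c == 0.5

    def test_matches_pair_enumeration_with_censoring(self):
        subjects = [(2, 1, 0), (3, 0, 0), (5, 1, 0), (6, 1, 0), (7, 0, 0), (9, 1, 0)]
        scores = [3.0, 1.0, 2.5, 2.5, 0.5, 1.5]
        df = cp_frame(subjects)
        conc = ties = comp = 0
        for i, j in itertools.permutations(range(6), 2):
            ti, ei = subjects[i][0], subjects[i][1]
            tj = subjects[j][0]
            if not ei or not (ti <= tj) or (ti == tj and subjects[j][1]):
                continue
            comp += 1
            if scores[i] > scores[j]:
                conc += 1
            elif scores[i] == scores[j]:
                ties += 1
        expected = (conc + 0.5 * ties) / comp
        c, _ = harrell_cindex(df, scores, "dropout")
        assert math.isclose(c, expected, rel_tol=1e-12)

    def test_registrant_unit_mode(self, default_cohort_rows):
        _, rows = default_cohort_rows
        c_rec, _ = harrell_cindex(rows, rows.meld_capped, "dropout")
        c_reg, _ = harrell_cindex(rows, rows.meld_capped, "dropout",
                                  unit="registrant")
        assert 0.5 < c_rec <= 1.0 and 0.0 < c_reg <= 1.0

    def test_no_comparable_pairs(self):
        df = cp_frame([(5, 1, 0)])
        with pytest.raises(ValueError, match="comparable"):
            harrell_cindex(df, [1.0], "dropout")
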