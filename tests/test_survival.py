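import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from mircircuitnet.io_formats import SurvivalRecord
from mircircuitnet.survival import (
    bonferroni_adjust,
    bonferroni_alpha,
    cox_fit_univariate,
    cox_partial_loglik,
    dichotomize_by_median,
    km_curve,
    screen_mirnas,
)
from mircircuitnet.synthetic_data import CohortConfig, generate_survival


def records_from(times, events, x, name="x"):
    return [
        SurvivalRecord(f"p{i}", t, e, {name: xi})
        for i, (t, e, xi) in enumerate(zip(times, events, x))
    ]


def grid_search_beta(times, events, x, lo=-5.0, hi=5.0, ties="breslow"):
    """Two-stage grid maximizer of the explicit partial-likelihood product."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)
    best = 0.0
    for _ in range(4):  # refine to ~1e-6 resolution
        grid = np.linspace(lo, hi, 2001)
        lls = [cox_partial_loglik(b, times, events, x, ties) for b in grid]
        best = grid[int(np.argmax(lls))]
        span = (hi - lo) / 100
        lo, hi = best - span, best + span
    return best


class TestCoxFit:
    def test_exchangeable_tied_groups_give_zero_beta(self):
        # two deaths at the same time with x = 0 and 1: risk sets are symmetric
        recs = records_from([3.0, 3.0], [True, True], [0.0, 1.0])
        fit = cox_fit_univariate(recs, "x")
        assert fit.beta == pytest.approx(0.0, abs=1e-8)

    def test_four_record_fixture_matches_grid_search_oracle(self):
        times, events, x = [1, 2, 3, 4], [True] * 4, [1, 0, 1, 0]
        fit = cox_fit_univariate(records_from(times, events, x), "x")
        assert fit.beta == pytest.approx(grid_search_beta(times, events, x), abs=1e-4)

    def test_random_small_fixtures_match_grid_search_oracle(self):
        rng = np.random.default_rng(71)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            times = rng.exponential(10, n).round(2) + 0.5
            events = rng.random(n) < 0.8
            if events.sum() < 2:
                events[:2] = True
            x = rng.normal(0, 1, n).round(2)
            if np.ptp(x) == 0:
                continue
            fit = cox_fit_univariate(records_from(times, events, x), "x")
            if not fit.converged or abs(fit.beta) > 4.5:
                continue  # monotone likelihood: grid comparison meaningless
            assert fit.beta == pytest.approx(
                grid_search_beta(times, events, x), abs=1e-4
            )

    def test_matches_lifelines_on_untied_data(self):
        rng = np.random.default_rng(72)
        n = 60
        x = rng.normal(0, 1, n)
        times = rng.exponential(np.exp(-0.5 * x))
        events = rng.random(n) < 0.7
        events[:2] = True
        fit = cox_fit_univariate(records_from(times, events, x), "x")
        df = pd.DataFrame({"T": times, "E": events, "x": x})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_rescaling_covariate_rescales_beta_and_keeps_p(self):
        rng = np.random.default_rng(73)
        n = 50
        x = rng.normal(0, 1, n)
        times = rng.exponential(np.exp(-0.4 * x))
        events = np.ones(n, bool)
        f1 = cox_fit_univariate(records_from(times, events, x), "x")
        f2 = cox_fit_univariate(records_from(times, events, 10 * x), "x")
        assert f2.beta == pytest.approx(f1.beta / 10, rel=1e-5)
        assert f2.p == pytest.approx(f1.p, rel=1e-6)

    def test_all_censored_is_error(self):
        recs = records_from([1, 2, 3], [False] * 3, [0.1, 0.5, 0.9])
        with pytest.raises(ValueError, match="censored"):
            cox_fit_univariate(recs, "x")

    def test_constant_covariate_is_error(self):
        recs = records_from([1, 2, 3], [True] * 3, [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="constant"):
            cox_fit_univariate(recs, "x")

    def test_monotone_likelihood_flagged_unconverged(self):
        # perfect separation: the highest covariate values die first
        recs = records_from([1, 2, 3, 4, 5, 6], [True] * 6,
                            [5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        fit = cox_fit_univariate(recs, "x")
        assert not fit.converged

    def test_parameter_recovery_with_exponential_hazards(self):
        estimates = []
        coverage = 0
        n_reps = 50
        for rep in range(n_reps):
            cfg = CohortConfig(seed=900 + rep, n_survival_patients=200,
                               survival_betas={"miR-X": 0.4})
            truth = type("T", (), {"survival_betas": {"miR-X": 0.4}})()
            recs = generate_survival(truth, cfg, screen_mirnas=["miR-X"])
            fit = cox_fit_univariate(recs, "miR-X")
            estimates.append(fit.beta)
            if np.log(fit.ci_low) <= 0.4 <= np.log(fit.ci_high):
                coverage += 1
        assert abs(np.mean(estimates) - 0.4) < 0.05
        assert 0.86 <= coverage / n_reps <= 1.0


class TestBonferroni:
    def test_twenty_six_tests_round_to_two_thousandths(self):
        assert round(bonferroni_alpha(0.05, 26), 3) == 0.002

    def test_single_test_unchanged(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_adjusted_p_capped_at_one(self):
        np.testing.assert_allclose(bonferroni_adjust([0.1], m=26), [1.0])

    def test_adjustment_is_m_times_p(self):
        np.testing.assert_allclose(bonferroni_adjust([0.001, 0.01], m=10),
                                   [0.01, 0.1])


class TestKaplanMeier:
    def test_product_limit_hand_computation(self):
        recs = records_from([1, 2, 3, 4], [True] * 4, [0, 0, 0, 0])
        out = km_curve(recs)["all"]
        curve = out["curve"].set_index("time")["survival"]
        np.testing.assert_allclose(
            curve.loc[[1.0, 2.0, 3.0, 4.0]], [0.75, 0.5, 0.25, 0.0]
        )
        assert out["median"] == pytest.approx(2.0)

    def test_all_censored_flat_curve_and_undefined_median(self):
        recs = records_from([5, 6, 7], [False] * 3, [0, 0, 0])
        out = km_curve(recs)["all"]
        assert (out["curve"]["survival"] == 1.0).all()
        assert out["median"] is None

    def test_simultaneous_events_single_drop(self):
        recs = records_from([5, 5, 5], [True] * 3, [0, 0, 0])
        out = km_curve(recs)["all"]
        curve = out["curve"].set_index("time")["survival"]
        assert curve.loc[5.0] == pytest.approx(0.0)
        assert out["median"] == pytest.approx(5.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(74)
        times = rng.exponential(10, 40)
        recs = records_from(times, [True] * 40, np.zeros(40))
        curve = km_curve(recs)["all"]["curve"]
        for _, row in curve.iterrows():
            empirical = np.mean(times > row["time"])
            assert row["survival"] == pytest.approx(empirical, abs=1e-9)

    def test_dichotomize_assigns_median_ties_to_low(self):
        groups = dichotomize_by_median(pd.Series([1.0, 2.0, 2.0, 3.0],
                                                 index=list("abcd")))
        assert groups["b"] == "low" and groups["c"] == "low"
        assert groups["d"] == "high"

    def test_grouped_curves(self):
        recs = records_from([1, 2, 10, 12], [True] * 4, [0, 0, 1, 1])
        labels = {"p0": "low", "p1": "low", "p2": "high", "p3": "high"}
        out = km_curve(recs, labels)
        assert out["low"]["median"] < out["high"]["median"]


class TestScreen:
    def test_planted_effect_ranks_first_among_nulls(self):
        hits = 0
        n_reps = 20
        for rep in range(n_reps):
            cfg = CohortConfig(seed=700 + rep, n_survival_patients=200,
                               survival_betas={"miR-007": 0.4})
            truth = type("T", (), {"survival_betas": {"miR-007": 0.4}})()
            screen = [f"miR-{i:03d}" for i in range(1, 27)]
            recs = generate_survival(truth, cfg, screen_mirnas=screen)
            fits = screen_mirnas(recs, screen)
            if fits.iloc[0]["covariate_name"] == "miR-007":
                hits += 1
        assert hits / n_reps >= 0.9

    def test_null_screen_rarely_significant_at_bonferroni_level(self):
        cfg = CohortConfig(seed=75, n_survival_patients=200)
        truth = type("T", (), {"survival_betas": {}})()
        screen = [f"miR-{i:03d}" for i in range(1, 27)]
        recs = generate_survival(truth, cfg, screen_mirnas=screen)
        fits = screen_mirnas(recs, screen)
        alpha = fits["per_test_alpha"].iloc[0]
        assert alpha == pytest.approx(0.05 / 26)
        assert (fits["p"] < alpha).sum() <= 1

    def test_empty_list_gives_empty_output(self):
        assert screen_mirnas([], []).empty

    def test_sorted_by_adjusted_p(self):
        cfg = CohortConfig(seed=76, n_survival_patients=150,
                           survival_betas={"miR-002": 0.5})
        truth = type("T", (), {"survival_betas": {"miR-002": 0.5}})()
        screen = [f"miR-{i:03d}" for i in range(1, 6)]
        recs = generate_survival(truth, cfg, screen_mirnas=screen)
        fits = screen_mirnas(recs, screen)
        ps = fits["p_adjusted"].dropna().to_numpy()
        assert (np.diff(ps) >= -1e-12).all()
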