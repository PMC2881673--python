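"""Stratification, log-odds adjustment, stratum logits and composite scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from nhqi import (
    QIDefinition,
    RiskAdjustmentModel,
    RiskAdjustmentResults,
    StandardModel,
    StrataThresholds,
    StratumModel,
    adjust_log_odds,
    assign_stratum,
    assign_strata,
    compute_thresholds,
    expected_rate,
    fit_stratum_logit,
)

# ---------------------------------------------------------------------------
# thresholds and stratum assignment
# ---------------------------------------------------------------------------


class TestThresholds:
    def test_linear_interpolation_quantiles_1_to_100(self):
        values = np.random.default_rng(0).permutation(np.arange(1, 101))
        th = compute_thresholds(values)
        assert th.p20 == pytest.approx(20.8)
        assert th.p80 == pytest.approx(80.2)

    def test_degenerate_distribution(self):
        th = compute_thresholds([3.5] * 25)
        assert th.p20 == th.p80 == 3.5

    def test_gaussian_closed_form(self):
        values = np.random.default_rng(1).standard_normal(100_000)
        th = compute_thresholds(values)
        assert th.p20 == pytest.approx(-0.8416, abs=0.02)
        assert th.p80 == pytest.approx(0.8416, abs=0.02)

    def test_missing_dropped_and_all_missing_rejected(self):
        th = compute_thresholds([np.nan] * 5 + list(range(1, 101)))
        assert th.p20 == pytest.approx(20.8)
        with pytest.raises(ValueError):
            compute_thresholds([np.nan, np.nan])


class TestAssignStratum:
    th = StrataThresholds(p20=-1.0, p80=1.0)

    @pytest.mark.parametrize(
        "value, expected",
        [(-1.0, "middle"), (1.0, "middle"), (1.0 + 1e-9, "high"),
         (-1.5, "low"), (0.0, "middle"), (np.nan, "middle")],
    )
    def test_boundaries_and_missing(self, value, expected):
        assert assign_stratum(value, self.th) == expected

    def test_self_stratification_shares(self):
        values = np.random.default_rng(2).standard_normal(50_000)
        strata = assign_strata(values, compute_thresholds(values))
        shares = pd.Series(strata).value_counts(normalize=True)
        assert shares["low"] == pytest.approx(0.20, abs=0.005)
        assert shares["middle"] == pytest.approx(0.60, abs=0.005)
        assert shares["high"] == pytest.approx(0.20, abs=0.005)


# ---------------------------------------------------------------------------
# log-odds observed/expected adjustment
# ---------------------------------------------------------------------------


class TestAdjustLogOdds:
    def test_frozen_worked_example(self):
        # expit(logit .3 - logit .2 + logit .25), high-precision oracle
        assert adjust_log_odds(0.3, 0.2, 0.25) == pytest.approx(
            0.36363636363636365, abs=1e-15)

    def test_observed_equals_standard_and_expected(self):
        assert adjust_log_odds(0.25, 0.25, 0.25) == pytest.approx(0.25, abs=1e-15)

    def test_boundary_observed_requires_denominator(self):
        with pytest.raises(ValueError, match="denominator"):
            adjust_log_odds(0.0, 0.2, 0.25)
        a = adjust_log_odds(0.0, 0.2, 0.25, denominator=10)
        expected = expit(logit(0.5 / 11) - logit(0.2) + logit(0.25))
        assert a == pytest.approx(expected, abs=1e-15)

    def test_degenerate_standard_model_rejected(self):
        with pytest.raises(ValueError):
            adjust_log_odds(0.5, 0.0, 0.25)
        with pytest.raises(ValueError):
            adjust_log_odds(0.5, 0.2, 1.0)

    @given(e=st.floats(0.01, 0.99), p=st.floats(0.01, 0.99))
    @settings(max_examples=200, deadline=None)
    def test_anchor_identity_property(self, e, p):
        """O = E collapses the adjustment to the standard rate exactly."""
        assert adjust_log_odds(e, e, p) == pytest.approx(p, abs=1e-12)

    @given(o1=st.floats(0.05, 0.9), delta=st.floats(0.01, 0.09),
           e=st.floats(0.05, 0.95), p=st.floats(0.05, 0.95))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_observed(self, o1, delta, e, p):
        assert adjust_log_odds(o1 + delta, e, p) > adjust_log_odds(o1, e, p)


# ---------------------------------------------------------------------------
# stratum logistic models
# ---------------------------------------------------------------------------


def grid_search_logit(y, x, refinements=7, steps=41, span=8.0):
    """Independent ML oracle: iteratively refined grid over (intercept, slope)."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    center = np.zeros(2)
    width = span
    for _ in range(refinements):
        a = np.linspace(center[0] - width, center[0] + width, steps)
        b = np.linspace(center[1] - width, center[1] + width, steps)
        eta = a[:, None, None] + b[None, :, None] * x[None, None, :]
        ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        center = np.array([a[i], b[j]])
        width = 2 * width / (steps - 1) * 2  # keep the optimum interior
    return center


class TestFitStratumLogit:
    def test_matches_grid_search_oracle_on_tiny_instance(self):
        y = [0, 1, 0, 1, 1, 0, 1, 1]
        x = [-1.2, -0.5, -0.3, 0.1, 0.4, 0.8, 1.3, 2.0]
        model = fit_stratum_logit(y, pd.DataFrame({"x": x}), "middle")
        oracle = grid_search_logit(y, x)
        assert model.fit_status == "converged"
        assert model.intercept == pytest.approx(oracle[0], abs=1e-3)
        assert model.coefficients["x"] == pytest.approx(oracle[1], abs=1e-3)

    def test_null_covariates_give_zero_slopes_and_calibrated_rate(self):
        rng = np.random.default_rng(3)
        n = 50_000
        X = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        y = rng.uniform(size=n) < 0.3
        model = fit_stratum_logit(y, X, "middle")
        assert abs(model.coefficients["a"]) < 0.05
        assert abs(model.coefficients["b"]) < 0.05
        assert expit(model.intercept) == pytest.approx(y.mean(), abs=0.01)

    def test_constant_outcome_intercept_only_fallback(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        model = fit_stratum_logit([0, 0, 0, 0], X, "low")
        assert model.fit_status == "intercept_only"
        assert expit(model.intercept) == pytest.approx(0.5 / 5)

    def test_perfect_separation_falls_back_to_finite_fit(self):
        x = np.array([-2.0, -1.5, -1.0, -0.5, 0.5, 1.0, 1.5, 2.0])
        y = (x > 0).astype(float)
        model = fit_stratum_logit(y, pd.DataFrame({"x": x}), "high")
        assert model.fit_status in ("penalized_fallback", "intercept_only")
        assert np.isfinite(model.intercept)
        preds = model.predict(pd.DataFrame({"x": x}))
        assert np.all((preds > 0) & (preds < 1))


class TestExpectedRate:
    def test_intercept_only_constant(self):
        model = StratumModel("middle", float(logit(0.25)), {}, "converged")
        records = pd.DataFrame(index=range(7))
        assert expected_rate(records, model) == pytest.approx(0.25, abs=1e-12)

    def test_mean_of_inverse_logits(self):
        model = StratumModel("middle", 0.0, {"x": 1.0}, "converged")
        records = pd.DataFrame({"x": [-1.0, 0.0, 1.0]})
        # expit(-1) + expit(1) = 1, so the mean is exactly 1/2
        assert expected_rate(records, model) == pytest.approx(0.5, abs=1e-15)


# ---------------------------------------------------------------------------
# fitted artifact: weights, anchors, serialization
# ---------------------------------------------------------------------------


def _stratifier_block_panel():
    """Panel whose stratifier takes values -1 (x200), 0 (x600), 1 (x200)."""
    rng = np.random.default_rng(4)
    strat = np.repeat([-1.0, 0.0, 1.0], [200, 600, 200])
    return pd.DataFrame({
        "resident_id": [f"r{i}" for i in range(1000)],
        "facility_id": np.tile([f"F{j}" for j in range(10)], 100),
        "quarter": 1,
        "new_admission": False,
        "ev": (rng.uniform(size=1000) < 0.3).astype(int),
        "s": strat,
    })


SIMPLE_QI = QIDefinition(
    qi_id="EV", numerator_rule={"item": "ev", "op": "==", "value": 1},
    stratifier_name="s",
)


class TestStandardModelFit:
    def test_weights_are_denominator_shares(self):
        res = RiskAdjustmentModel(_stratifier_block_panel(), SIMPLE_QI).fit()
        assert res.weights["low"] == pytest.approx(0.2)
        assert res.weights["middle"] == pytest.approx(0.6)
        assert res.weights["high"] == pytest.approx(0.2)
        assert sum(res.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_standard_rate_is_overall_event_rate(self):
        panel = _stratifier_block_panel()
        res = RiskAdjustmentModel(panel, SIMPLE_QI).fit()
        assert res.standard_rate == pytest.approx(panel["ev"].mean())

    def test_json_round_trip(self, tmp_path, small_world, prevalence_qi):
        _, panel, _ = small_world
        res = RiskAdjustmentModel(panel, prevalence_qi).fit()
        path = tmp_path / "model.json"
        res.save(path)
        loaded = RiskAdjustmentResults.load(path, qi_def=prevalence_qi)
        pd.testing.assert_frame_equal(res.score(panel), loaded.score(panel))


# ---------------------------------------------------------------------------
# composite scoring
# ---------------------------------------------------------------------------


def _manual_artifact():
    """Hand-built artifact: intercept-only strata with known anchors."""
    return StandardModel(
        qi_id="EV",
        thresholds=StrataThresholds(-1.0, 1.0),
        stratum_models={
            "low": StratumModel("low", float(logit(0.2)), {}, "converged"),
            "middle": StratumModel("middle", float(logit(0.3)), {}, "converged"),
            "high": StratumModel("high", float(logit(0.5)), {}, "converged"),
            "unstratified": StratumModel("unstratified", float(logit(0.25)), {}, "converged"),
        },
        weights={"low": 0.5, "middle": 0.5, "high": 0.0},
        standard_rate_overall=0.25,
        standard_rate_by_stratum={"low": 0.15, "middle": 0.35, "high": 0.5},
        covariate_means={},
    )


def _two_stratum_facility():
    """One facility: 1/10 triggering in the low stratum, 4/10 in the middle."""
    rows = []
    for i in range(10):
        rows.append({"resident_id": f"lo{i}", "facility_id": "X", "quarter": 1,
                     "new_admission": False, "ev": int(i < 1), "s": -2.0})
    for i in range(10):
        rows.append({"resident_id": f"mid{i}", "facility_id": "X", "quarter": 1,
                     "new_admission": False, "ev": int(i < 4), "s": 0.0})
    return pd.DataFrame(rows)


class TestCompositeScores:
    def test_two_stratum_worked_example(self):
        """gen3 equals the weight-renormalized mean of the per-stratum
        adjusted rates, against a 40-digit-precision oracle."""
        res = RiskAdjustmentResults(None, _manual_artifact())
        res.qi_def = SIMPLE_QI
        scored = res.score(_two_stratum_facility())
        row = scored.iloc[0]
        # oracle values: A_low = expit(logit .1 - logit .2 + logit .15),
        # A_mid = expit(logit .4 - logit .3 + logit .35)
        assert row["adjusted_low"] == pytest.approx(0.07272727272727273, abs=1e-12)
        assert row["adjusted_middle"] == pytest.approx(0.4558139534883721, abs=1e-12)
        assert row["gen3_score"] == pytest.approx(0.2642706131078224, abs=1e-12)
        # O = 5/20 = 0.25 = E = P_std, so gen2 collapses to the anchor
        assert row["gen2_score"] == pytest.approx(0.25, abs=1e-12)
        assert row["relative_quality"] == pytest.approx(
            row["gen3_score"] - 0.25, abs=1e-15)
        assert row["n_strata_empty"] == 1

    def test_single_nonempty_stratum_gets_full_weight(self):
        res = RiskAdjustmentResults(None, _manual_artifact())
        res.qi_def = SIMPLE_QI
        panel = _two_stratum_facility()
        panel = panel[panel["s"] == 0.0]  # middle stratum only
        scored = res.score(panel)
        assert scored.iloc[0]["gen3_score"] == pytest.approx(
            scored.iloc[0]["adjusted_middle"], abs=1e-15)

    def test_case_mix_invariance_under_resident_replication(
            self, small_world, prevalence_qi):
        """Replicating every resident k times changes no facility score.

        Exact invariance holds wherever no observed rate needs the
        (n + 0.5)/(d + 1) boundary correction, whose perturbation shrinks
        with the denominator by design.
        """
        _, panel, _ = small_world
        res = RiskAdjustmentModel(panel, prevalence_qi).fit()
        replicated = pd.concat(
            [panel.assign(resident_id=panel["resident_id"] + f"_copy{k}")
             for k in range(3)],
            ignore_index=True,
        )
        a = res.score(panel)
        b = res.score(replicated)
        interior = np.ones(len(a), dtype=bool)
        for col in ("raw_rate", "observed_low", "observed_middle", "observed_high"):
            v = a[col].to_numpy()
            interior &= np.isnan(v) | ((v > 0) & (v < 1))
        assert interior.sum() >= 20  # the check must actually bite
        cols = ["facility_id", "quarter", "gen2_score", "gen3_score"]
        pd.testing.assert_frame_equal(
            a.loc[interior, cols].reset_index(drop=True),
            b.loc[interior, cols].reset_index(drop=True),
        )

    def test_reduction_no_covariates_single_stratum(self):
        """With no covariates and everyone in one stratum, gen3 = gen2 and
        both are strictly monotone in the raw rate."""
        art = StandardModel(
            qi_id="EV",
            thresholds=StrataThresholds(-10.0, 10.0),
            stratum_models={
                lab: StratumModel(lab, float(logit(0.3)), {}, "converged")
                for lab in ("low", "middle", "high", "unstratified")
            },
            weights={"low": 0.0, "middle": 1.0, "high": 0.0},
            standard_rate_overall=0.3,
            standard_rate_by_stratum={"low": 0.3, "middle": 0.3, "high": 0.3},
            covariate_means={},
        )
        res = RiskAdjustmentResults(None, art)
        res.qi_def = SIMPLE_QI
        rows = []
        for f, k in (("A", 2), ("B", 5), ("C", 8)):
            for i in range(10):
                rows.append({"resident_id": f"{f}{i}", "facility_id": f,
                             "quarter": 1, "new_admission": False,
                             "ev": int(i < k), "s": 0.0})
        scored = res.score(pd.DataFrame(rows)).sort_values("raw_rate")
        assert np.allclose(scored["gen2_score"], scored["gen3_score"], atol=1e-12)
        assert scored["gen2_score"].is_monotonic_increasing

    def test_summary_mentions_strata_and_anchor(self, small_world, prevalence_qi):
        _, panel, _ = small_world
        text = RiskAdjustmentModel(panel, prevalence_qi).fit().summary()
        assert "P_std" in text and "middle" in text and "cognition_scale" in text
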