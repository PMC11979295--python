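"""Change-rate estimation: dichotomization, logistic fits, period splits."""

import numpy as np
import pandas as pd
import pytest

from conftest import binomial_panel
from moraltides.norm_change import (
    JUSTIFIABILITY_10,
    ItemScaleSpec,
    aggregate_records,
    calibrate_issue_time,
    dichotomize,
    dichotomize_panel,
    fit_fixed_change,
    fit_interaction_model,
    fit_multilevel_change,
    split_by_period,
)


def two_wave_panel(p0=0.5, p1=0.6, n=1000, society="A", issue="x"):
    return pd.DataFrame(
        {
            "society": [society] * 2,
            "issue_id": [issue] * 2,
            "wave_year": [1990, 2000],
            "n_agree_w": [p0 * n, p1 * n],
            "n_total_w": [float(n)] * 2,
        }
    )


class TestDichotomization:
    @pytest.mark.parametrize("response, expected", [(8, 1), (7, 1), (10, 1), (3, 0), (1, 0), (4, 0),
                                                    (5, "excluded"), (6, "excluded")])
    def test_justifiability_scale_coding(self, response, expected):
        assert dichotomize(response, JUSTIFIABILITY_10("divorce")) == expected

    def test_outside_support_rejected(self):
        with pytest.raises(ValueError, match="outside the support"):
            dichotomize(11, JUSTIFIABILITY_10("divorce"))

    def test_binary_item_maps_identically(self):
        spec = ItemScaleSpec("x", "binary", ones=frozenset({1}), zeros=frozenset({0}))
        assert dichotomize(1, spec) == 1
        assert dichotomize(0, spec) == 0

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            ItemScaleSpec("x", "bad", ones=frozenset({1, 2}), zeros=frozenset({2}))

    def test_panel_dichotomization_drops_midpoints(self):
        panel = pd.DataFrame(
            {
                "society": ["A"] * 4,
                "issue_id": ["divorce"] * 4,
                "wave_year": [1990] * 4,
                "response": [8, 3, 5, 7],
                "weight": [1.0] * 4,
            }
        )
        out = dichotomize_panel(panel, {"divorce": JUSTIFIABILITY_10("divorce")})
        assert len(out) == 3
        assert out["mu"].tolist() == [1.0, 0.0, 1.0]


class TestFixedEffectsChange:
    def test_two_wave_closed_form(self):
        # saturated two-point logistic: slope = logit(0.6) - logit(0.5) = ln 1.5
        est = fit_fixed_change(two_wave_panel())
        assert est.rate == pytest.approx(np.log(1.5), abs=1e-6)
        assert est.ci_low < est.rate < est.ci_high

    def test_constant_share_means_zero_change(self):
        est = fit_fixed_change(two_wave_panel(p0=0.55, p1=0.55))
        assert est.rate == pytest.approx(0.0, abs=1e-9)

    def test_recovers_common_slope_across_societies(self, rng):
        intercepts = np.array([[0.5], [-0.5]])
        panel = binomial_panel(rng, slopes=np.array([0.3]), intercepts=intercepts, n=5000)
        est = fit_fixed_change(panel)
        assert est.rate == pytest.approx(0.3, abs=0.05)
        assert est.n_societies == 2

    def test_single_time_point_rejected(self):
        bad = two_wave_panel().iloc[:1]
        with pytest.raises(ValueError):
            fit_fixed_change(bad)

    def test_aggregate_equals_individual_level_fit(self):
        individual = pd.DataFrame(
            {
                "society": ["A"] * 8,
                "issue_id": ["x"] * 8,
                "wave_year": [1990] * 4 + [2000] * 4,
                "mu": [1, 0, 1, 0, 1, 1, 1, 0],
                "weight": [1.0, 2.0, 1.0, 1.0, 1.0, 1.0, 2.0, 1.0],
            }
        )
        agg = aggregate_records(individual)
        a = fit_fixed_change(individual)
        b = fit_fixed_change(agg)
        assert a.rate == pytest.approx(b.rate, abs=1e-10)
        assert a.se == pytest.approx(b.se, rel=1e-8)

    def test_reversed_coding_negates_rate(self):
        panel = two_wave_panel(p0=0.4, p1=0.7)
        flipped = panel.copy()
        flipped["n_agree_w"] = flipped["n_total_w"] - flipped["n_agree_w"]
        assert fit_fixed_change(flipped).rate == pytest.approx(-fit_fixed_change(panel).rate)

    def test_doubling_weights_leaves_point_estimate(self):
        panel = two_wave_panel(p0=0.45, p1=0.6)
        doubled = panel.copy()
        doubled[["n_agree_w", "n_total_w"]] *= 2.0
        assert fit_fixed_change(doubled).rate == pytest.approx(fit_fixed_change(panel).rate)

    def test_separation_flagged_not_raised(self):
        est = fit_fixed_change(two_wave_panel(p0=0.0, p1=1.0))
        assert "separation" in est.flags


class TestMultilevelChange:
    def test_recovers_per_issue_rates(self, rng):
        # generative process of the hierarchical model: global slope 0.2,
        # between-issue slope SD 0.2, random society levels
        g10, tau = 0.2, 0.2
        u = rng.normal(0.0, tau, 20)
        intercepts = rng.normal(0.0, 0.5, size=(20, 20))
        panel = binomial_panel(rng, slopes=g10 + u, intercepts=intercepts, n=500)
        ests = fit_multilevel_change(panel)
        rates = np.array([e.rate for e in ests])
        assert np.mean(np.abs(rates - (g10 + u))) < 0.05

    def test_degenerates_to_fixed_fit_without_slope_heterogeneity(self, rng):
        slopes = np.full(10, 0.25)
        intercepts = rng.normal(0.0, 0.4, size=(12, 10))
        panel = binomial_panel(rng, slopes=slopes, intercepts=intercepts, n=4000)
        ml = {e.issue_id: e.rate for e in fit_multilevel_change(panel)}
        for j in range(10):
            issue = f"I{j:02d}"
            fx = fit_fixed_change(panel[panel["issue_id"] == issue])
            assert ml[issue] == pytest.approx(fx.rate, abs=0.02)

    def test_single_issue_single_society_reduces_to_logistic_slope(self):
        panel = two_wave_panel(p0=0.5, p1=0.6)
        [est] = fit_multilevel_change(panel)
        assert est.rate == pytest.approx(np.log(1.5), abs=1e-6)
        assert est.estimator == "multilevel"


class TestPeriodSplit:
    def make(self, years, society="A", issue="x"):
        return pd.DataFrame(
            {
                "society": [society] * len(years),
                "issue_id": [issue] * len(years),
                "wave_year": years,
                "n_agree_w": [50.0] * len(years),
                "n_total_w": [100.0] * len(years),
            }
        )

    def test_pivot_nearest_midpoint_belongs_to_both(self):
        early, late = split_by_period(self.make([1990, 1998, 2010]))
        assert sorted(early["wave_year"]) == [1990, 1998]
        assert sorted(late["wave_year"]) == [1998, 2010]

    def test_symmetric_waves_split_at_middle(self):
        early, late = split_by_period(self.make([1990, 2000, 2010]))
        assert sorted(early["wave_year"]) == [1990, 2000]
        assert sorted(late["wave_year"]) == [2000, 2010]

    def test_midpoint_tie_resolves_to_earlier_wave(self):
        early, late = split_by_period(self.make([1990, 1995, 2005, 2010]))
        # midpoint 2000: 1995 and 2005 are equidistant; earlier wins
        assert sorted(early["wave_year"]) == [1990, 1995]
        assert sorted(late["wave_year"]) == [1995, 2005, 2010]

    def test_two_waves_not_eligible(self):
        assert split_by_period(self.make([1990, 2010])) is None

    def test_mixed_series_rejected(self):
        df = pd.concat([self.make([1990, 2000, 2010]), self.make([1990, 2000, 2010], society="B")])
        with pytest.raises(ValueError):
            split_by_period(df)


class TestInteractionModel:
    def test_time_zero_at_first_measurement_anywhere(self):
        agg = pd.DataFrame(
            {
                "society": ["A", "A", "B", "B"],
                "issue_id": ["x"] * 4,
                "wave_year": [1981, 1991, 1991, 2001],
                "n_agree_w": [50.0] * 4,
                "n_total_w": [100.0] * 4,
            }
        )
        out = calibrate_issue_time(agg)
        # society B's first wave is 1991, but the issue clock starts in 1981
        assert out.loc[out["wave_year"] == 1981, "time"].tolist() == [0.0]
        assert out.loc[out["society"] == "B", "time"].tolist() == [1.0, 2.0]

    def test_three_way_moderation_recovered(self, rng):
        # per-cell slope 0.1 + 0.5 * AA * LIB: the time:AA:LIB coefficient
        # should come back positive and near its generating value
        n_soc, n_iss = 20, 15
        aa = rng.uniform(-0.6, 0.6, n_iss)
        lib = rng.uniform(0.05, 0.35, n_soc)
        rows = []
        for j in range(n_iss):
            for c in range(n_soc):
                slope = 0.1 + 0.5 * aa[j] * lib[c]
                icept = rng.normal(0.0, 0.3)
                for k, y in enumerate([1990, 2000, 2010]):
                    p = 1.0 / (1.0 + np.exp(-(icept + slope * k)))
                    rows.append({"society": f"S{c:02d}", "issue_id": f"I{j:02d}",
                                 "wave_year": y, "n_agree_w": float(rng.binomial(500, p)),
                                 "n_total_w": 500.0})
        panel = pd.DataFrame(rows)
        aa_map = {f"I{j:02d}": aa[j] for j in range(n_iss)}
        lib_map = {f"S{c:02d}": lib[c] for c in range(n_soc)}
        fit = fit_interaction_model(panel, aa_map, lib_map)
        coef = fit.coefficients.loc["time:AA:LIB", "estimate"]
        assert coef > 0
        assert coef == pytest.approx(0.5, abs=0.35)
        assert set(fit.coefficients.index) == set(fit.FIXED_EFFECTS)
        assert all(sd >= 0 for sd in fit.random_sd.values())

    def test_missing_moderators_listed_not_dropped_silently(self, rng):
        panel = binomial_panel(rng, slopes=np.full(3, 0.2),
                               intercepts=np.zeros((6, 3)), n=300)
        aa_map = {"I00": 0.3, "I01": -0.2}                       # I02 missing
        lib_map = {f"S{c:02d}": 0.1 + 0.05 * c for c in range(5)}  # S05 missing
        fit = fit_interaction_model(panel, aa_map, lib_map)
        assert fit.excluded["issues_missing_aa"] == ["I02"]
        assert fit.excluded["societies_missing_lib"] == ["S05"]
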