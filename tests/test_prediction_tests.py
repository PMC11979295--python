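"""Profile mirroring, correlations, resampling and the assembled P1-P5 report."""

import numpy as np
import pandas as pd
import pytest

from moraltides.prediction_tests import (
    bootstrap_ci_over_issues,
    evaluate_predictions,
    mirror_profile,
    period_consistency,
    profile_correlation,
    split_half_consistency,
)


class TestMirroring:
    def test_single_issue_mirrors_to_signed_pair(self):
        prof = mirror_profile({"A": 0.5})
        assert prof.values == (0.5, -0.5)
        assert prof.mirrored

    def test_length_doubles_and_mean_is_zero(self, rng):
        vals = {f"I{i}": v for i, v in enumerate(rng.normal(size=9))}
        prof = mirror_profile(vals)
        assert len(prof.values) == 2 * len(vals)
        assert prof.as_array().mean() == pytest.approx(0.0, abs=1e-15)
        assert prof.n_issues == len(vals)


class TestProfileCorrelation:
    def test_proportional_profiles_correlate_perfectly(self):
        x = mirror_profile({"A": 0.5, "B": -0.2, "C": 0.1})
        y = mirror_profile({"A": 1.0, "B": -0.4, "C": 0.2})
        assert profile_correlation(x, y) == pytest.approx(1.0)

    def test_orthogonal_profiles_correlate_zero(self):
        x = mirror_profile({"A": 1.0, "B": 0.0})
        y = mirror_profile({"A": 0.0, "B": 1.0})
        assert profile_correlation(x, y) == pytest.approx(0.0, abs=1e-15)

    def test_mirrored_pearson_equals_uncentered_identity(self, rng):
        v = rng.normal(size=12)
        w = 0.6 * v + rng.normal(scale=0.5, size=12)
        x = mirror_profile(dict(zip(map(str, range(12)), v)))
        y = mirror_profile(dict(zip(map(str, range(12)), w)))
        uncentered = float(v @ w / np.sqrt((v @ v) * (w @ w)))
        assert profile_correlation(x, y) == pytest.approx(uncentered, abs=1e-12)

    def test_invariant_to_flipping_an_issue_in_both_profiles(self, rng):
        v = rng.normal(size=8)
        w = rng.normal(size=8)
        r1 = profile_correlation(
            mirror_profile(dict(zip(map(str, range(8)), v))),
            mirror_profile(dict(zip(map(str, range(8)), w))),
        )
        v2, w2 = v.copy(), w.copy()
        v2[3] *= -1  # flip the positive coding of one issue in both profiles
        w2[3] *= -1
        r2 = profile_correlation(
            mirror_profile(dict(zip(map(str, range(8)), v2))),
            mirror_profile(dict(zip(map(str, range(8)), w2))),
        )
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_mismatched_or_flat_profiles_rejected(self):
        x = mirror_profile({"A": 0.5, "B": 0.2})
        y = mirror_profile({"A": 0.5, "C": 0.2})
        with pytest.raises(ValueError):
            profile_correlation(x, y)
        flat = mirror_profile({"A": 0.0, "B": 0.0})
        with pytest.raises(ValueError):
            profile_correlation(flat, x)


class TestIssueBootstrap:
    def test_proportional_profiles_collapse_ci(self):
        x = mirror_profile({"A": 0.5, "B": -0.2, "C": 0.1})
        y = mirror_profile({"A": 1.0, "B": -0.4, "C": 0.2})
        out = bootstrap_ci_over_issues(x, y, B=300, seed=0)
        assert out["stat"] == pytest.approx(1.0)
        assert out["ci_low"] == pytest.approx(1.0)
        assert out["ci_high"] == pytest.approx(1.0)

    def test_resamples_keep_pairs_together(self, rng):
        # every resample must hold n_issues mirrored pairs: using a stat that
        # checks the pair structure of each resample it receives
        v = rng.normal(size=6)
        x = mirror_profile(dict(zip(map(str, range(6)), v)))

        def pair_checking_stat(xs, ys):
            n = len(xs) // 2
            assert len(xs) == 2 * n
            np.testing.assert_allclose(xs[:n], -xs[n:])
            np.testing.assert_allclose(ys[:n], -ys[n:])
            return float(np.corrcoef(xs, ys)[0, 1])

        out = bootstrap_ci_over_issues(x, x, B=150, seed=1, stat=pair_checking_stat)
        assert out["n_issues"] == 6

    def test_seed_reproducibility_and_small_b_rejected(self):
        x = mirror_profile({"A": 0.5, "B": -0.2, "C": 0.3})
        y = mirror_profile({"A": 0.4, "B": 0.1, "C": 0.2})
        a = bootstrap_ci_over_issues(x, y, B=200, seed=9)
        b = bootstrap_ci_over_issues(x, y, B=200, seed=9)
        assert a == b
        with pytest.raises(ValueError):
            bootstrap_ci_over_issues(x, y, B=50, seed=0)

    def test_ci_covers_known_profile_correlation(self, rng):
        # mirrored bivariate-normal profiles with population mirrored r = rho
        # 600 replications keep the Monte-Carlo error on the coverage
        # estimate near 1%, so the assertion reflects the true rate
        rho, n_issues, reps = 0.6, 30, 600
        cov = [[1.0, rho], [rho, 1.0]]
        hits = 0
        for _ in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n_issues)
            x = mirror_profile({str(i): xy[i, 0] for i in range(n_issues)})
            y = mirror_profile({str(i): xy[i, 1] for i in range(n_issues)})
            out = bootstrap_ci_over_issues(x, y, B=1000, seed=rng)
            hits += out["ci_low"] <= rho <= out["ci_high"]
        assert hits / reps >= 0.90


class TestSplitHalf:
    @staticmethod
    def society_table(values_by_society):
        rows = []
        for soc, values in values_by_society.items():
            for issue, rate in values.items():
                rows.append({"society": soc, "issue_id": issue, "rate": rate})
        return pd.DataFrame(rows)

    def test_identical_societies_always_correlate_perfectly(self):
        profile = {"A": 0.4, "B": -0.2, "C": 0.1}
        df = self.society_table({f"S{i}": profile for i in range(6)})
        res = split_half_consistency(df, n_partitions=50, seed=0)
        np.testing.assert_allclose(res.correlations, 1.0)

    def test_seeded_partitions_reproduce_and_serialize(self):
        profile = {"A": 0.4, "B": -0.2, "C": 0.1}
        df = self.society_table({f"S{i}": profile for i in range(5)})
        r1 = split_half_consistency(df, n_partitions=20, seed=3)
        r2 = split_half_consistency(df, n_partitions=20, seed=3)
        assert r1.partitions == r2.partitions
        # odd society count: group sizes differ by exactly one
        sizes = {len(g) for pair in r1.partitions for g in pair}
        assert sizes == {2, 3}

    def test_pure_noise_gives_mean_near_zero(self, rng):
        # correlations from partitions of one dataset are dependent, so the
        # null check averages over independent datasets
        issues = [f"I{i}" for i in range(20)]
        means = []
        for _ in range(12):
            df = self.society_table(
                {f"S{c}": dict(zip(issues, rng.normal(size=20))) for c in range(20)}
            )
            res = split_half_consistency(df, n_partitions=60,
                                         seed=int(rng.integers(1 << 30)))
            means.append(res.correlations.mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(np.mean(means)) <= 2 * se

    def test_shared_profile_dominating_noise_is_always_detected(self, rng):
        # shared issue profile with SD far above the noise of group means
        shared = rng.normal(scale=1.0, size=25)
        issues = [f"I{i}" for i in range(25)]
        df = self.society_table(
            {
                f"S{c}": dict(zip(issues, shared + rng.normal(scale=1.0, size=25)))
                for c in range(24)
            }
        )
        res = split_half_consistency(df, n_partitions=300, seed=6)
        assert (res.correlations > 0).all()

    def test_too_few_societies_rejected(self):
        df = self.society_table({"S1": {"A": 0.1}, "S2": {"A": 0.2}})
        with pytest.raises(ValueError):
            split_half_consistency(df)


class TestPeriodConsistency:
    def test_identical_periods_correlate_perfectly(self):
        rates = {"A": 0.4, "B": -0.1, "C": 0.2}
        assert period_consistency(rates, dict(rates)) == pytest.approx(1.0)

    def test_reversed_periods_correlate_negatively(self):
        rates = {"A": 0.4, "B": -0.1, "C": 0.2}
        flipped = {k: -v for k, v in rates.items()}
        assert period_consistency(rates, flipped) == pytest.approx(-1.0)

    def test_too_few_common_issues_rejected(self):
        with pytest.raises(ValueError):
            period_consistency({"A": 0.1, "B": 0.2}, {"A": 0.1, "B": 0.2})


class TestAssembledReport:
    def test_missing_ingredients_reported_explicitly(self):
        report = evaluate_predictions(seed=1)
        for key in ("P1", "P2", "P3", "P4", "P5"):
            assert report[key]["computed"] is False
            assert report[key]["reason"]

    def test_stable_rates_give_positive_p2_and_p3(self, rng):
        aa = {f"I{i}": v for i, v in enumerate(rng.uniform(-0.5, 0.5, 12))}
        rates = {k: 0.8 * v + rng.normal(scale=0.05) for k, v in aa.items()}
        report = evaluate_predictions(
            change_rates=rates,
            aa_by_issue=aa,
            early_rates=rates,
            late_rates={k: v + rng.normal(scale=0.02) for k, v in rates.items()},
            B=500,
            seed=2,
        )
        assert report["P2"]["computed"] and report["P2"]["r"] > 0.9
        assert report["P3"]["computed"] and report["P3"]["r"] > 0.5
        assert report["P3"]["ci_low"] <= report["P3"]["r"] <= report["P3"]["ci_high"]

    def test_binding_block_included_when_available(self, rng):
        aa = {f"I{i}": v for i, v in enumerate(rng.uniform(-0.5, 0.5, 10))}
        rates = {k: v + rng.normal(scale=0.05) for k, v in aa.items()}
        binding = {k: -v for k, v in aa.items()}
        report = evaluate_predictions(
            change_rates=rates, aa_by_issue=aa, aa_binding_by_issue=binding, B=500, seed=3
        )
        assert report["P3"]["binding"]["r"] < 0
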