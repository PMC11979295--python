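"""Estimation of per-issue norm-change rates from longitudinal opinion panels.

A norm is operationalized as the population share agreeing with a positively
coded opinion. Graded survey responses are first dichotomized (ambiguous
midpoints excluded), then the change rate of each issue is estimated as the
slope of a weighted logistic regression of agreement on calendar time in
decades — log odds per 10 years. Two estimators are provided:

* a *fixed-effects* logistic per issue, with society dummies absorbing level
  differences between societies (the design used for preregistered subsets
  where every society has data on every issue);
* a *multilevel* estimator for the full unbalanced panel, targeting the model

      logit Pr(mu_icj = 1) = (g00 + u0j + v0cj) + (g10 + u1j) time_cj

  with random intercepts by issue and society-issue and a random slope by
  issue; the per-issue global rate is g10 + u1j. The realization is a
  two-stage empirical-Bayes fit: per-issue fixed-effects slopes, then
  DerSimonian-Laird shrinkage of slopes toward their precision-weighted
  mean. Any consistent approximation satisfies the estimator contract; this
  one is fast, deterministic and accurate when per-issue information is
  rich, and degrades gracefully to the fixed-effects estimate when the
  between-issue slope variance dominates sampling error.

A three-way interaction model extends this with per-issue argument
advantage (AA) and per-society moral liberalness (LIB) moderators, testing
whether norms sit further in, and move faster toward, the argument-advantaged
direction in more liberal societies.

Input panels are pandas DataFrames, either individual-level rows
(``society, issue_id, wave_year, response, weight``) or weighted binomial
aggregates (``society, issue_id, wave_year, n_agree_w, n_total_w``);
individual rows are reduced to aggregates internally, which leaves the
weighted likelihood unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "ItemScaleSpec",
    "ChangeEstimate",
    "InteractionFit",
    "JUSTIFIABILITY_10",
    "dichotomize",
    "dichotomize_panel",
    "aggregate_records",
    "fit_fixed_change",
    "fit_multilevel_change",
    "split_by_period",
    "calibrate_issue_time",
    "fit_interaction_model",
]

AGG_COLS = ("society", "issue_id", "wave_year", "n_agree_w", "n_total_w")
EXCLUDED = "excluded"


@dataclass(frozen=True)
class ItemScaleSpec:
    """Dichotomization rule for one item's response scale.

    ``ones``, ``zeros`` and ``excluded`` partition the scale's support;
    excluded values (ambiguous midpoints) are dropped from analysis.
    """

    issue_id: str
    kind: str
    ones: frozenset
    zeros: frozenset
    excluded: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.ones or not self.zeros:
            raise ValueError("ones and zeros sets must be non-empty")
        sets = [set(self.ones), set(self.zeros), set(self.excluded)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("ones/zeros/excluded must be disjoint")

    @property
    def support(self) -> frozenset:
        return frozenset(self.ones | self.zeros | self.excluded)


def JUSTIFIABILITY_10(issue_id: str) -> ItemScaleSpec:
    """The 10-step justifiability scale: 7-10 agree, 1-4 disagree, 5-6 excluded."""
    return ItemScaleSpec(
        issue_id=issue_id,
        kind="justifiability-10",
        ones=frozenset(range(7, 11)),
        zeros=frozenset(range(1, 5)),
        excluded=frozenset({5, 6}),
    )


def dichotomize(response, spec: ItemScaleSpec):
    """Map one raw response to 1, 0 or the string ``"excluded"``."""
    if response in spec.ones:
        return 1
    if response in spec.zeros:
        return 0
    if response in spec.excluded:
        return EXCLUDED
    raise ValueError(
        f"response {response!r} outside the support of scale {spec.kind!r} "
        f"for issue {spec.issue_id!r}"
    )


def dichotomize_panel(records: pd.DataFrame, specs: Mapping[str, ItemScaleSpec]) -> pd.DataFrame:
    """Dichotomize an individual-level panel, dropping excluded responses."""
    out = records.copy()
    coded = np.empty(len(out), dtype=object)
    for i, (issue, resp) in enumerate(zip(out["issue_id"], out["response"])):
        if issue not in specs:
            raise KeyError(f"no scale spec for issue {issue!r}")
        coded[i] = dichotomize(resp, specs[issue])
    out["mu"] = coded
    out = out[out["mu"] != EXCLUDED].copy()
    out["mu"] = out["mu"].astype(float)
    return out


def aggregate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Reduce records to weighted binomial aggregates per society-issue-wave.

    Accepts either individual rows carrying a dichotomized ``mu`` column and
    ``weight``, or data already in aggregate form (returned unchanged apart
    from column order). Weighted aggregation is likelihood-preserving for
    the binomial models used downstream.
    """
    if {"n_agree_w", "n_total_w"}.issubset(records.columns):
        return records.loc[:, list(AGG_COLS)].reset_index(drop=True)
    df = records.copy()
    if "mu" not in df.columns:
        raise ValueError("individual-level input needs a dichotomized 'mu' column")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    if (df["weight"] <= 0).any():
        raise ValueError("survey weights must be positive")
    df["_wy"] = df["weight"] * df["mu"]
    g = df.groupby(["society", "issue_id", "wave_year"], sort=True)
    out = g.agg(n_agree_w=("_wy", "sum"), n_total_w=("weight", "sum")).reset_index()
    return out.loc[:, list(AGG_COLS)]


@dataclass(frozen=True)
class ChangeEstimate:
    """Estimated change rate for one issue, in log odds per decade."""

    issue_id: str
    rate: float
    ci_low: float
    ci_high: float
    estimator: Literal["fixed", "multilevel"]
    n_societies: int
    se: float = float("nan")
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if math.isfinite(self.ci_low) and math.isfinite(self.ci_high):
            if not (self.ci_low <= self.rate <= self.ci_high):
                raise ValueError("CI must bracket the rate")


def _fit_binomial_glm(agg: pd.DataFrame):
    """Weighted binomial GLM of agreement share on decade time + society dummies."""
    agg = agg.sort_values(["society", "wave_year"]).reset_index(drop=True)
    t0 = agg["wave_year"].min()
    time_dec = (agg["wave_year"] - t0) / 10.0
    societies = sorted(agg["society"].unique())
    X = pd.DataFrame({"const": 1.0, "time": time_dec})
    for s in societies[1:]:
        X[f"soc[{s}]"] = (agg["society"] == s).astype(float)
    y = agg["n_agree_w"] / agg["n_total_w"]
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=agg["n_total_w"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    return res, societies


def fit_fixed_change(records: pd.DataFrame, alpha: float = 0.05) -> ChangeEstimate:
    """Fixed-effects logistic change rate for one issue.

    Weighted logistic regression of dichotomized agreement on time in
    decades, with society dummies absorbing between-society level
    differences. Returns the time coefficient with its Wald CI. A
    near-separated fit (degenerate observed shares or an exploding slope
    standard error) is returned with a ``"separation"`` flag rather than
    raised.
    """
    agg = aggregate_records(records)
    issues = agg["issue_id"].unique()
    if len(issues) != 1:
        raise ValueError(f"fit_fixed_change expects one issue, got {sorted(issues)}")
    if agg["wave_year"].nunique() < 2:
        raise ValueError("need at least two distinct wave years to estimate change")
    res, societies = _fit_binomial_glm(agg)
    b = float(res.params["time"])
    se = float(res.bse["time"])
    flags: tuple[str, ...] = ()
    shares = agg["n_agree_w"] / agg["n_total_w"]
    if not np.isfinite(se) or se > 50 or (shares % 1 == 0).all():
        flags = ("separation",)
    z = float(norm.ppf(1 - alpha / 2))
    return ChangeEstimate(
        issue_id=str(issues[0]),
        rate=b,
        ci_low=b - z * se,
        ci_high=b + z * se,
        estimator="fixed",
        n_societies=len(societies),
        se=se,
        flags=flags,
    )


def fit_multilevel_change(records: pd.DataFrame, alpha: float = 0.05) -> list[ChangeEstimate]:
    """Per-issue global change rates from the random-slope multilevel model.

    Two-stage empirical-Bayes realization: per-issue fixed-effects slopes
    ``b_j`` with standard errors ``se_j`` (society dummies play the role of
    the society-issue random intercepts), then a normal-normal hierarchical
    model ``b_j ~ N(g10 + u1j, se_j^2)`` with ``u1j ~ N(0, tau^2)``.
    ``tau^2`` is the DerSimonian-Laird moment estimate and each issue's rate
    is the posterior mean ``(b_j / se_j^2 + g10 / tau^2) / (1/se_j^2 +
    1/tau^2)``, i.e. precision-weighted shrinkage toward the global mean
    slope. A single issue is returned unshrunk (the shrinkage target is
    degenerate). Degenerate per-issue designs propagate their diagnostic
    flags instead of silently disappearing.
    """
    agg = aggregate_records(records)
    issues = sorted(agg["issue_id"].unique())
    stage1: dict[str, ChangeEstimate] = {}
    for issue in issues:
        stage1[issue] = fit_fixed_change(agg[agg["issue_id"] == issue], alpha=alpha)
    if len(issues) == 1:
        est = stage1[issues[0]]
        return [ChangeEstimate(est.issue_id, est.rate, est.ci_low, est.ci_high,
                               "multilevel", est.n_societies, est.se, est.flags)]
    b = np.array([stage1[j].rate for j in issues])
    se = np.array([stage1[j].se for j in issues])
    usable = np.isfinite(b) & np.isfinite(se) & (se > 0)
    if usable.sum() < 2:
        raise ValueError("too few issues with usable slope estimates")
    w = 1.0 / se[usable] ** 2
    g10 = float(np.sum(w * b[usable]) / np.sum(w))
    # DerSimonian-Laird between-issue slope variance
    Q = float(np.sum(w * (b[usable] - g10) ** 2))
    k = int(usable.sum())
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    z = float(norm.ppf(1 - alpha / 2))
    out = []
    for j, issue in enumerate(issues):
        s1 = stage1[issue]
        if not usable[j]:
            out.append(ChangeEstimate(issue, s1.rate, s1.ci_low, s1.ci_high, "multilevel",
                                      s1.n_societies, s1.se, s1.flags + ("unusable-stage1",)))
            continue
        if tau2 == 0.0:
            post_mean, post_var = g10, 1.0 / np.sum(w)
        else:
            prec = 1.0 / se[j] ** 2 + 1.0 / tau2
            post_mean = (b[j] / se[j] ** 2 + g10 / tau2) / prec
            post_var = 1.0 / prec
        ps = math.sqrt(post_var)
        out.append(ChangeEstimate(issue, float(post_mean), float(post_mean - z * ps),
                                  float(post_mean + z * ps), "multilevel",
                                  s1.n_societies, ps, s1.flags))
    return out


def split_by_period(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame] | None:
    """Split one society-item series into early/late halves around its midpoint.

    Eligible only when measured at least three times. The pivot is the
    observed wave closest to the calendar midpoint (first + last) / 2, ties
    resolved toward the earlier wave; the pivot wave belongs to both halves.
    Returns ``None`` when not eligible.
    """
    keys = records[["society", "issue_id"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("split_by_period expects a single society-item series")
    years = np.sort(records["wave_year"].unique())
    if len(years) < 3:
        return None
    mid = (years[0] + years[-1]) / 2.0
    # ties toward the earlier wave: stable argmin on (distance, year)
    pivot = min(years, key=lambda y: (abs(y - mid), y))
    early = records[records["wave_year"] <= pivot].copy()
    late = records[records["wave_year"] >= pivot].copy()
    return early, late


@dataclass
class InteractionFit:
    """Result of the three-way time x AA x LIB interaction model.

    ``coefficients`` indexes the eight fixed effects (intercept, time, AA,
    LIB, AA:LIB, time:AA, time:LIB, time:AA:LIB) with columns estimate,
    ci_low, ci_high, p. ``random_sd`` holds the random-effect standard
    deviations; ``excluded`` lists issues/societies dropped for missing
    moderators.
    """

    coefficients: pd.DataFrame
    random_sd: dict[str, float]
    n_obs: int
    n_issues: int
    n_society_issues: int
    excluded: dict[str, list] = field(default_factory=dict)

    FIXED_EFFECTS = ("intercept", "time", "AA", "LIB", "AA:LIB", "time:AA", "time:LIB", "time:AA:LIB")

    def __post_init__(self) -> None:
        missing = [t for t in self.FIXED_EFFECTS if t not in self.coefficients.index]
        if missing:
            raise ValueError(f"missing fixed-effect rows: {missing}")
        if any(v < 0 for v in self.random_sd.values()):
            raise ValueError("random-effect SDs must be non-negative")


def calibrate_issue_time(agg: pd.DataFrame) -> pd.DataFrame:
    """Add a per-issue calibrated ``time`` column in decades.

    Time is zero in the first year an issue was measured in *any* society,
    so an issue first fielded anywhere in 1981 assigns time 0 to its 1981
    rows in every society.
    """
    out = agg.copy()
    first_year = out.groupby("issue_id")["wave_year"].transform("min")
    out["time"] = (out["wave_year"] - first_year) / 10.0
    return out


def _cell_logistic(agg: pd.DataFrame, time: np.ndarray) -> tuple[float, float] | None:
    """Intercept and slope of a two-parameter weighted logistic on one cell.

    ``agg`` holds one society-issue's aggregated waves. Boundary shares get
    a Haldane-style 0.5 pseudo-count correction so the MLE stays finite.
    Returns None when fewer than two waves are present.
    """
    if len(agg) < 2 or len(np.unique(time)) < 2:
        return None
    n = agg["n_total_w"].to_numpy(dtype=float)
    k = agg["n_agree_w"].to_numpy(dtype=float)
    at_edge = (k <= 0) | (k >= n)
    if at_edge.any():
        k = k + 0.5 * at_edge
        n = n + 1.0 * at_edge
    X = np.column_stack([np.ones_like(time), time])
    model = sm.GLM(k / n, X, family=sm.families.Binomial(), var_weights=n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    return float(res.params[0]), float(res.params[1])


def fit_interaction_model(
    records: pd.DataFrame,
    aa_by_issue: Mapping[str, float],
    lib_by_society: Mapping[str, float],
    alpha: float = 0.05,
) -> InteractionFit:
    """Three-way interaction of time, argument advantage and liberalness.

    Fits the weighted multilevel logistic model with fixed effects
    {intercept, time, AA, LIB, AA:LIB, time:AA, time:LIB, time:AA:LIB} and
    random intercepts by issue and society-issue plus random time, LIB and
    time:LIB effects by issue. Time is calibrated per issue: 0 in the first
    year the issue was measured in *any* society, in decades.

    Realization (same estimator contract as :func:`fit_multilevel_change`):
    stage one fits a two-parameter logistic (intercept, decade slope) to
    each society-issue cell; stage two regresses the cell slopes and
    intercepts on AA, LIB and AA x LIB with linear mixed models grouped by
    issue. The slope regression yields the four time-interaction
    coefficients, the intercept regression the four level coefficients, and
    their variance components the random-effect SDs.

    Societies without a LIB value and issues without an AA value are
    excluded and listed in the result metadata.
    """
    agg = aggregate_records(records)
    excluded = {
        "issues_missing_aa": sorted(set(agg["issue_id"]) - set(aa_by_issue)),
        "societies_missing_lib": sorted(set(agg["society"]) - set(lib_by_society)),
    }
    agg = agg[agg["issue_id"].isin(aa_by_issue) & agg["society"].isin(lib_by_society)].copy()
    if agg.empty:
        raise ValueError("no records remain after AA/LIB matching")

    agg = calibrate_issue_time(agg)

    rows = []
    for (soc, issue), cell in agg.groupby(["society", "issue_id"], sort=True):
        fit = _cell_logistic(cell, cell["time"].to_numpy(dtype=float))
        if fit is None:
            continue
        rows.append({"society": soc, "issue_id": issue, "alpha_cj": fit[0], "beta_cj": fit[1],
                     "aa": aa_by_issue[issue], "lib": lib_by_society[soc]})
    cells = pd.DataFrame(rows)
    if cells["issue_id"].nunique() < 2 or len(cells) < 8:
        raise ValueError("interaction model needs several issues and society-issue cells")

    z = float(norm.ppf(1 - alpha / 2))

    def _stage2(y: str, names: tuple[str, str, str, str]):
        X = pd.DataFrame({
            "const": 1.0,
            "aa": cells["aa"],
            "lib": cells["lib"],
            "aa_lib": cells["aa"] * cells["lib"],
        })
        exog_re = pd.DataFrame({"const": 1.0, "lib": cells["lib"]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = sm.MixedLM(cells[y], X, groups=cells["issue_id"], exog_re=exog_re)
                res = md.fit(reml=True, method="lbfgs")
                re_sd = (math.sqrt(max(res.cov_re.iloc[0, 0], 0.0)),
                         math.sqrt(max(res.cov_re.iloc[1, 1], 0.0)))
            except Exception:
                try:
                    md = sm.MixedLM(cells[y], X, groups=cells["issue_id"])
                    res = md.fit(reml=True, method="lbfgs")
                except Exception as e:
                    raise ValueError(
                        "interaction stage-2 design is degenerate (constant or "
                        f"collinear AA/LIB moderators?): {type(e).__name__}: {e}"
                    ) from e
                re_sd = (math.sqrt(max(float(np.asarray(res.cov_re).ravel()[0]), 0.0)), float("nan"))
        tab = []
        for raw, name in zip(("const", "aa", "lib", "aa_lib"), names):
            est = float(res.params[raw])
            se = float(res.bse[raw])
            p = float(res.pvalues[raw])
            tab.append({"term": name, "estimate": est, "ci_low": est - z * se,
                        "ci_high": est + z * se, "p": p})
        resid_sd = math.sqrt(max(float(res.scale), 0.0))
        return pd.DataFrame(tab).set_index("term"), re_sd, resid_sd

    level_tab, (sd_issue, sd_lib_by_issue), sd_soc_issue = _stage2(
        "alpha_cj", ("intercept", "AA", "LIB", "AA:LIB"))
    slope_tab, (sd_time_by_issue, sd_time_lib_by_issue), _ = _stage2(
        "beta_cj", ("time", "time:AA", "time:LIB", "time:AA:LIB"))

    coefficients = pd.concat([level_tab, slope_tab]).loc[list(InteractionFit.FIXED_EFFECTS)]
    random_sd = {
        "society:issue intercept": sd_soc_issue,
        "issue intercept": sd_issue,
        "time by issue": sd_time_by_issue,
        "LIB by issue": 0.0 if math.isnan(sd_lib_by_issue) else sd_lib_by_issue,
        "time:LIB by issue": 0.0 if math.isnan(sd_time_lib_by_issue) else sd_time_lib_by_issue,
    }
    return InteractionFit(
        coefficients=coefficients,
        random_sd=random_sd,
        n_obs=int(len(agg)),
        n_issues=int(cells["issue_id"].nunique()),
        n_society_issues=int(len(cells)),
        excluded=excluded,
    )
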