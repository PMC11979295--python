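"""The five preregistered prediction tests on profiles of norm change.

All profile statistics treat an issue's two opinions symmetrically: each
per-issue value ``v`` is *mirrored* into the pair ``(v, -v)`` before any
correlation is computed, so the arbitrary choice of which opinion is
positively coded cannot influence the result. On mirrored profiles both
series have mean zero by construction and the Pearson correlation equals
the uncentered form ``sum(xy) / sqrt(sum(x^2) sum(y^2))``. Bootstrap
resampling draws whole issues, so a pair's two values always travel
together.

The five predictions:

1. different societies share a common profile of norm change — tested by
   repeatedly partitioning societies into two random halves and correlating
   the half-profiles;
2. the global change profile is stable over time — early-period vs
   late-period profile correlation;
3. the global change profile correlates with per-issue argument advantage —
   mirrored Pearson r with an issue-level bootstrap CI;
4. norms sit further in the advantaged direction in more liberal societies
   (positive AA x LIB coefficient in the interaction model);
5. norms move faster in the advantaged direction in more liberal societies
   (positive time x AA x LIB coefficient).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .argument_advantage import concordance_correlation  # noqa: F401  (re-export convenience)

__all__ = [
    "IssueProfile",
    "SplitHalfResult",
    "mirror_profile",
    "profile_correlation",
    "bootstrap_ci_over_issues",
    "split_half_consistency",
    "period_consistency",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class IssueProfile:
    """An ordered per-issue value profile, optionally mirrored.

    A mirrored profile lists each issue's value for the positively coded
    opinion followed, in the same issue order, by the sign-flipped values
    for the opposite opinions; its length is even and its mean is zero.
    """

    issue_ids: tuple[str, ...]
    values: tuple[float, ...]
    mirrored: bool = False

    def __post_init__(self) -> None:
        if len(self.issue_ids) != len(self.values):
            raise ValueError("issue_ids and values must align")
        if self.mirrored:
            n = len(self.values)
            if n % 2:
                raise ValueError("mirrored profile must have even length")
            half = n // 2
            for v, w in zip(self.values[:half], self.values[half:]):
                if v != -w:
                    raise ValueError("mirrored profile must consist of (v, -v) pairs")

    @property
    def n_issues(self) -> int:
        return len(self.values) // 2 if self.mirrored else len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def mirror_profile(values: Mapping[str, float]) -> IssueProfile:
    """Mirror per-issue values into (v, -v) pairs, keeping issue pairing."""
    ids = list(values)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate issue ids")
    vals = [float(values[i]) for i in ids]
    return IssueProfile(
        issue_ids=tuple(ids) + tuple(f"{i}(opp)" for i in ids),
        values=tuple(vals) + tuple(-v for v in vals),
        mirrored=True,
    )


def profile_correlation(x: IssueProfile, y: IssueProfile) -> float:
    """Pearson correlation between two aligned profiles."""
    if x.mirrored != y.mirrored:
        raise ValueError("profiles must both be mirrored or both unmirrored")
    if x.issue_ids != y.issue_ids:
        raise ValueError("profiles must cover the same issues in the same order")
    xv, yv = x.as_array(), y.as_array()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined for a zero-variance profile")
    return float(np.corrcoef(xv, yv)[0, 1])


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r over resample matrices (B x n)."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def bootstrap_ci_over_issues(
    x: IssueProfile,
    y: IssueProfile,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
    stat: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> dict:
    """Percentile bootstrap CI for a profile statistic, resampling issues.

    Each bootstrap draw samples ``n_issues`` issues with replacement and
    carries both members of each mirrored pair into the resample (2 x
    n_issues values). ``stat=None`` uses Pearson r with a fast vectorized
    path; any callable on two value arrays may be supplied instead.
    Resamples on which the statistic is undefined (zero variance) are
    redrawn and counted in the result metadata.
    """
    if not (x.mirrored and y.mirrored):
        raise ValueError("issue-level bootstrap requires mirrored profiles")
    if x.issue_ids != y.issue_ids:
        raise ValueError("profiles must cover the same issues in the same order")
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = x.n_issues
    xv, yv = x.as_array(), y.as_array()
    point = profile_correlation(x, y) if stat is None else float(stat(xv, yv))

    def draw(count: int) -> np.ndarray:
        pair_idx = rng.integers(0, n, size=(count, n))
        return np.concatenate([pair_idx, pair_idx + n], axis=1)

    idx = draw(B)
    if stat is None:
        stats = _pearson_rows(xv[idx], yv[idx])
    else:
        stats = np.array([stat(xv[i], yv[i]) for i in idx])
    bad = ~np.isfinite(stats)
    n_redrawn = 0
    while bad.any():
        n_redrawn += int(bad.sum())
        idx_b = draw(int(bad.sum()))
        if stat is None:
            stats[bad] = _pearson_rows(xv[idx_b], yv[idx_b])
        else:
            stats[bad] = [stat(xv[i], yv[i]) for i in idx_b]
        bad = ~np.isfinite(stats)
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return {
        "stat": point,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "B": B,
        "level": level,
        "n_issues": n,
        "n_redrawn": n_redrawn,
    }


@dataclass
class SplitHalfResult:
    """Correlations from repeated random half-partitions of societies."""

    correlations: np.ndarray
    seed: int | None
    partitions: list[tuple[tuple[str, ...], tuple[str, ...]]] = field(default_factory=list)
    dropped_issues: list[list[str]] = field(default_factory=list)

    def summary(self) -> dict:
        r = self.correlations
        return {
            "n_partitions": int(r.size),
            "min": float(r.min()),
            "max": float(r.max()),
            "mean": float(r.mean()),
            "share_positive": float((r > 0).mean()),
        }


def split_half_consistency(
    change_by_society_issue: pd.DataFrame,
    n_partitions: int = 300,
    seed: int | np.random.Generator = 0,
) -> SplitHalfResult:
    """Correlation between change profiles of two random society halves.

    ``change_by_society_issue`` has columns ``society, issue_id, rate``;
    missing society-issue combinations are simply absent rows. For each
    partition the societies are split randomly into halves (sizes differing
    by one when their number is odd), each group's profile is the unweighted
    per-issue mean over its societies with data, and the mirrored Pearson
    correlation over issues present in *both* group profiles is recorded.
    Issues present in neither or only one group are dropped from that
    partition and logged.
    """
    df = change_by_society_issue
    societies = sorted(df["society"].unique())
    if len(societies) < 4:
        raise ValueError("need at least four societies to split")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wide = df.pivot_table(index="issue_id", columns="society", values="rate", aggfunc="mean")
    rs = np.empty(n_partitions)
    partitions = []
    dropped_all = []
    soc_arr = np.array(societies)
    half = len(societies) // 2
    for b in range(n_partitions):
        perm = rng.permutation(len(soc_arr))
        g1 = soc_arr[perm[:half]]
        g2 = soc_arr[perm[half:]]
        p1 = wide[g1].mean(axis=1)
        p2 = wide[g2].mean(axis=1)
        ok = p1.notna() & p2.notna()
        dropped = sorted(wide.index[~ok])
        x = mirror_profile(dict(zip(wide.index[ok], p1[ok])))
        y = mirror_profile(dict(zip(wide.index[ok], p2[ok])))
        rs[b] = profile_correlation(x, y)
        partitions.append((tuple(sorted(g1)), tuple(sorted(g2))))
        dropped_all.append(dropped)
    return SplitHalfResult(
        correlations=rs,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
        partitions=partitions,
        dropped_issues=dropped_all,
    )


def period_consistency(early: Mapping[str, float], late: Mapping[str, float]) -> float:
    """Mirrored Pearson correlation between early- and late-period profiles."""
    common = [i for i in early if i in late]
    if len(common) < 3:
        raise ValueError("need at least three issues with both-period estimates")
    x = mirror_profile({i: early[i] for i in common})
    y = mirror_profile({i: late[i] for i in common})
    return profile_correlation(x, y)


def evaluate_predictions(
    change_rates: Mapping[str, float] | None = None,
    aa_by_issue: Mapping[str, float] | None = None,
    aa_binding_by_issue: Mapping[str, float] | None = None,
    change_by_society_issue: pd.DataFrame | None = None,
    early_rates: Mapping[str, float] | None = None,
    late_rates: Mapping[str, float] | None = None,
    interaction_fit=None,
    B: int = 10_000,
    n_partitions: int = 300,
    seed: int = 0,
) -> dict:
    """Assemble the P1-P5 report from whatever ingredients are available.

    Missing ingredients yield explicit ``{"computed": False, "reason": ...}``
    blocks rather than silent gaps. The report is JSON-serializable.
    """
    rng = np.random.default_rng(seed)
    report: dict = {"seed": seed}

    if change_by_society_issue is not None and change_by_society_issue["society"].nunique() >= 4:
        sh = split_half_consistency(change_by_society_issue, n_partitions=n_partitions, seed=rng)
        report["P1"] = {"computed": True, **sh.summary()}
    else:
        report["P1"] = {"computed": False, "reason": "per-society change estimates unavailable"}

    if early_rates and late_rates:
        try:
            r2 = period_consistency(early_rates, late_rates)
            report["P2"] = {"computed": True, "r": r2,
                            "n_issues": len([i for i in early_rates if i in late_rates])}
        except ValueError as e:
            report["P2"] = {"computed": False, "reason": str(e)}
    else:
        report["P2"] = {"computed": False, "reason": "period-split estimates unavailable"}

    if change_rates and aa_by_issue:
        common = [i for i in aa_by_issue if i in change_rates]
        x = mirror_profile({i: aa_by_issue[i] for i in common})
        y = mirror_profile({i: change_rates[i] for i in common})
        boot = bootstrap_ci_over_issues(x, y, B=B, seed=rng)
        report["P3"] = {"computed": True, "r": boot["stat"], "ci_low": boot["ci_low"],
                        "ci_high": boot["ci_high"], "n_issues": len(common), "B": B}
        if aa_binding_by_issue:
            common_b = [i for i in aa_binding_by_issue if i in change_rates]
            xb = mirror_profile({i: aa_binding_by_issue[i] for i in common_b})
            yb = mirror_profile({i: change_rates[i] for i in common_b})
            boot_b = bootstrap_ci_over_issues(xb, yb, B=B, seed=rng)
            report["P3"]["binding"] = {"r": boot_b["stat"], "ci_low": boot_b["ci_low"],
                                       "ci_high": boot_b["ci_high"], "n_issues": len(common_b)}
    else:
        report["P3"] = {"computed": False, "reason": "change rates or AA scores unavailable"}

    for key, term in (("P4", "AA:LIB"), ("P5", "time:AA:LIB")):
        if interaction_fit is not None:
            row = interaction_fit.coefficients.loc[term]
            report[key] = {
                "computed": True,
                "term": term,
                "estimate": float(row["estimate"]),
                "ci_low": float(row["ci_low"]),
                "ci_high": float(row["ci_high"]),
                "p": float(row["p"]),
                "positive": bool(row["estimate"] > 0),
            }
        else:
            report[key] = {"computed": False, "reason": "interaction model not fitted"}
    return report


def report_to_json(report: dict, path) -> None:
    """Write an evaluate_predictions report as indented JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
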