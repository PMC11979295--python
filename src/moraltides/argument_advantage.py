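"""Scoring of per-issue argument advantages from applicability-rating surveys.

Raters state their position on a moral issue (dichotomous) and then rate how
applicable one argument of each of seven kinds — Harm, Violence (a harm
sub-kind), Fairness, Liberty, Authority, Loyalty, Purity — is to their own
position and to the opposite position, on a five-point scale coded
equidistantly 0, 0.25, 0.5, 0.75, 1.

A participant's argument-advantage score for the positively coded opinion is
the mean applicability of the individualizing arguments for that opinion
minus the mean applicability of the same arguments for the opposite opinion;
per-issue scores are the mean over raters. Three kind-sets are supported:
``standard`` (Harm, Fairness, Liberty), ``prereg`` (adds Violence) and
``binding`` (Authority, Loyalty, Purity). Cross-group agreement between
issue profiles is quantified with Lin's concordance correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ARGUMENT_KINDS",
    "KIND_SETS",
    "ArgumentRating",
    "ParticipantScreen",
    "IssueAdvantage",
    "filter_participants",
    "participant_advantage",
    "issue_advantage",
    "concordance_correlation",
    "ccc_with_ci",
]

ARGUMENT_KINDS = ("Harm", "Violence", "Fairness", "Liberty", "Authority", "Loyalty", "Purity")
RATING_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)

KIND_SETS: dict[str, frozenset[str]] = {
    "standard": frozenset({"Harm", "Fairness", "Liberty"}),
    "prereg": frozenset({"Harm", "Violence", "Fairness", "Liberty"}),
    "binding": frozenset({"Authority", "Loyalty", "Purity"}),
}


@dataclass(frozen=True)
class ParticipantScreen:
    """Vocabulary-test screening record for one participant (0-10 correct)."""

    participant_id: str
    vocab_correct: int

    def __post_init__(self) -> None:
        if not 0 <= self.vocab_correct <= 10:
            raise ValueError(f"vocab_correct must be 0-10, got {self.vocab_correct!r}")


@dataclass(frozen=True)
class ArgumentRating:
    """One participant's position and 14-cell applicability grid on one issue.

    ``applicability`` maps ``(kind, side)`` with ``side`` in {"own",
    "opposite"} to a value on the five-point grid; all 14 cells must be
    present. ``position_held`` is True when the rater holds the positively
    coded opinion.
    """

    participant_id: str
    society: str
    issue_id: str
    position_held: bool
    applicability: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        expected = {(k, s) for k in ARGUMENT_KINDS for s in ("own", "opposite")}
        got = set(self.applicability)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValueError(f"applicability grid mismatch; missing={missing} extra={extra}")
        for cell, v in self.applicability.items():
            if not any(abs(v - g) < 1e-9 for g in RATING_GRID):
                raise ValueError(f"rating {v!r} at {cell} is not on the five-point grid")


@dataclass(frozen=True)
class IssueAdvantage:
    """Aggregated signed advantage score for one issue."""

    issue_id: str
    aa: float
    variant: str
    n_raters: int

    def __post_init__(self) -> None:
        if abs(self.aa) > 1.0 + 1e-12:
            raise ValueError(f"|aa| must not exceed 1, got {self.aa!r}")
        if self.n_raters < 1:
            raise ValueError("n_raters must be at least 1")


def filter_participants(
    screens: Iterable[ParticipantScreen], min_correct: int = 6
) -> list[str]:
    """Ids of participants passing the vocabulary screen, input order kept.

    The default threshold keeps participants with at least six of ten
    vocabulary items correct.
    """
    return [s.participant_id for s in screens if s.vocab_correct >= min_correct]


def participant_advantage(rating: ArgumentRating, kinds: Iterable[str] = KIND_SETS["standard"]) -> float:
    """Signed advantage score this rater assigns to the positively coded opinion.

    Mean applicability of ``kinds`` arguments for the positively coded
    opinion minus the mean for the opposite opinion. Since raters rate their
    *own* and the *opposite* side, the difference is orientation-flipped when
    the rater holds the negatively coded opinion.
    """
    kinds = list(kinds)
    unknown = set(kinds) - set(ARGUMENT_KINDS)
    if unknown:
        raise ValueError(f"unknown argument kinds: {sorted(unknown)}")
    if not kinds:
        raise ValueError("kinds must be non-empty")
    own = float(np.mean([rating.applicability[(k, "own")] for k in kinds]))
    opp = float(np.mean([rating.applicability[(k, "opposite")] for k in kinds]))
    return own - opp if rating.position_held else opp - own


def issue_advantage(ratings: Sequence[ArgumentRating], variant: str = "standard") -> IssueAdvantage:
    """Per-issue advantage: mean of participant scores over all raters."""
    if variant not in KIND_SETS:
        raise ValueError(f"variant must be one of {sorted(KIND_SETS)}, got {variant!r}")
    if not ratings:
        raise ValueError("at least one rating is required")
    issues = {r.issue_id for r in ratings}
    if len(issues) != 1:
        raise ValueError(f"ratings mix issues: {sorted(issues)}")
    kinds = KIND_SETS[variant]
    scores = [participant_advantage(r, kinds) for r in ratings]
    return IssueAdvantage(
        issue_id=ratings[0].issue_id,
        aa=float(np.mean(scores)),
        variant=variant,
        n_raters=len(ratings),
    )


def concordance_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient between two profiles.

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2), with
    population (n-denominator) moments and no small-sample bias correction.
    Unlike Pearson's r it penalizes location and scale differences, so
    |CCC| <= |r| with equality only under perfect calibration.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < 2:
        raise ValueError("need at least two paired values")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population denominators
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: both profiles constant and equal")
    return float(2.0 * cov / denom)


def _ccc_vectorized(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise CCC for resample matrices (shape B x n)."""
    mx = x.mean(axis=1)
    my = y.mean(axis=1)
    vx = x.var(axis=1)
    vy = y.var(axis=1)
    cov = (x * y).mean(axis=1) - mx * my
    denom = vx + vy + (mx - my) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        return 2.0 * cov / denom


def ccc_with_ci(
    x: Sequence[float],
    y: Sequence[float],
    n_issues: int | None = None,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> dict:
    """CCC with a percentile bootstrap CI resampling issues, not values.

    ``x`` and ``y`` are mirrored profiles laid out as ``n_issues`` positive
    values followed by their sign-negated twins (the layout produced by
    :func:`moraltides.prediction_tests.mirror_profile`); each bootstrap draw
    resamples whole issues with replacement so a pair's two values always
    travel together. With ``n_issues=None`` the profiles are treated as
    unmirrored and plain rows are the resampling unit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ccc = concordance_correlation(x, y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meta: dict = {}
    if B < 100:
        meta["warning"] = f"B={B} is below 100; percentile CI will be unstable"
    if n_issues is not None:
        if 2 * n_issues != x.size:
            raise ValueError("mirrored profile length must be 2 * n_issues")
        pair_idx = rng.integers(0, n_issues, size=(B, n_issues))
        idx = np.concatenate([pair_idx, pair_idx + n_issues], axis=1)
    else:
        idx = rng.integers(0, x.size, size=(B, x.size))
    stats = _ccc_vectorized(x[idx], y[idx])
    bad = ~np.isfinite(stats)
    n_redrawn = 0
    while bad.any():
        n_redrawn += int(bad.sum())
        if n_issues is not None:
            pair_idx = rng.integers(0, n_issues, size=(int(bad.sum()), n_issues))
            idx_b = np.concatenate([pair_idx, pair_idx + n_issues], axis=1)
        else:
            idx_b = rng.integers(0, x.size, size=(int(bad.sum()), x.size))
        stats[bad] = _ccc_vectorized(x[idx_b], y[idx_b])
        bad = ~np.isfinite(stats)
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    meta["n_redrawn"] = n_redrawn
    return {"ccc": ccc, "ci_low": float(lo), "ci_high": float(hi), "B": B, "level": level, "meta": meta}
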