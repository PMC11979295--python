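"""Synthetic worlds with known ground truth for end-to-end pipeline testing.

A *world* consists of societies with a latent moral liberalness (LIB, which
maps monotonically to the model's liberal proportion q), issues with a
shared signed argument advantage, and per-society-issue latent popularity
trajectories produced by the opinion-dynamics model. From a world the
generators emit the three observable data layers the analysis consumes:

* longitudinal opinion panels — binomial agree counts per society, issue
  and wave, drawn around the latent popularity;
* argument-applicability rating surveys — per-rater five-point grids whose
  individualizing own-minus-opposite gap equals the issue's true advantage
  in expectation;
* MFQ-style response tables in three study formats (6-, 7- and 5-point
  scales) whose individualizing-minus-binding gap equals the society's true
  LIB in expectation.

The generator emulates the statistical structure of cross-national survey
archives — societies x issues x waves with unbalanced coverage and binomial
sampling noise — not questionnaire wording, interviewer effects or realistic
weight construction. Every generator is seed-deterministic and stamps a
config hash into its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .argument_advantage import ARGUMENT_KINDS, ArgumentRating
from .liberalness import MFQResponse
from .model import ModelParams, PopulationState, simulate_mean_field

__all__ = [
    "WorldConfig",
    "WorldTruth",
    "generate_world",
    "generate_opinion_panel",
    "generate_argument_ratings",
    "generate_mfq_responses",
    "lib_to_q",
]

#: MFQ study formats: study id -> (scale_min, scale_max).
MFQ_FORMATS = {"klein6": (1, 6), "pagliaro7": (1, 7), "saucier5": (1, 5)}
_MFQ_ITEMS = {
    "harm": ("harm1", "harm2"),
    "fairness": ("fair1", "fair2"),
    "authority": ("auth1", "auth2"),
    "loyalty": ("loy1", "loy2"),
    "purity": ("pur1", "pur2"),
}


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions for a synthetic world.

    Defaults mirror the scale of the real analysis inputs: tens of
    societies with LIB spread over a moderate positive range, issues with
    advantages spanning both signs, three survey waves over two decades and
    national samples in the low thousands.
    """

    n_societies: int = 30
    n_issues: int = 20
    lib_low: float = 0.05
    lib_high: float = 0.35
    adv_low: float = -0.6
    adv_high: float = 0.6
    d: float = 0.1
    s: float = 0.5
    wave_years: tuple[int, ...] = (1990, 2000, 2010)
    steps_per_year: int = 1
    n_per_wave: int = 2000
    missingness: float = 0.0
    init_popularity: float = 0.5
    #: model years simulated before the first survey wave; with a burn-in,
    #: norms at first measurement already reflect accumulated prior change,
    #: further along in more liberal societies.
    burn_in_years: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_societies < 1 or self.n_issues < 1 or self.n_per_wave < 1:
            raise ValueError("counts must be at least 1")
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError("missingness must lie in [0, 1]")
        if not 0.0 < self.init_popularity < 1.0:
            raise ValueError("init_popularity must lie in (0, 1)")
        if self.burn_in_years < 0:
            raise ValueError("burn_in_years must be non-negative")
        if len(self.wave_years) < 1 or list(self.wave_years) != sorted(set(self.wave_years)):
            raise ValueError("wave_years must be strictly increasing")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def lib_to_q(lib: float) -> float:
    """Monotone link from observable LIB to the model's liberal proportion q.

    Any strictly increasing link is admissible; the default shifts LIB up by
    0.3 and clips into [0.05, 0.95], placing the default LIB range
    [0.05, 0.35] onto q in [0.35, 0.65].
    """
    return float(np.clip(lib + 0.3, 0.05, 0.95))


@dataclass
class WorldTruth:
    """Ground truth of a generated world."""

    config: WorldConfig
    societies: tuple[str, ...]
    issues: tuple[str, ...]
    lib: dict[str, float]
    q: dict[str, float]
    advantage: dict[str, float]
    #: latent popularity of the positively coded opinion, keyed by
    #: (society, issue) -> {wave_year: p}
    popularity: dict[tuple[str, str], dict[int, float]]
    observed: set[tuple[str, str]] = field(default_factory=set)

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "config_hash": self.config.hash(),
            "societies": list(self.societies),
            "issues": list(self.issues),
            "lib": self.lib,
            "q": self.q,
            "advantage": self.advantage,
            "popularity": {f"{s}|{j}": v for (s, j), v in self.popularity.items()},
            "observed": sorted(f"{s}|{j}" for s, j in self.observed),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "WorldTruth":
        d = json.loads(text)
        cfg = d["config"]
        cfg["wave_years"] = tuple(cfg["wave_years"])
        config = WorldConfig(**cfg)
        pop = {}
        for key, v in d["popularity"].items():
            s, j = key.split("|")
            pop[(s, j)] = {int(y): p for y, p in v.items()}
        return cls(
            config=config,
            societies=tuple(d["societies"]),
            issues=tuple(d["issues"]),
            lib=d["lib"],
            q=d["q"],
            advantage=d["advantage"],
            popularity=pop,
            observed={tuple(k.split("|")) for k in d["observed"]},
        )


def generate_world(config: WorldConfig) -> WorldTruth:
    """Draw a world and simulate its latent popularity trajectories.

    Societies get LIB ~ Uniform(lib_low, lib_high) and q = lib_to_q(LIB);
    issues get a *shared* signed advantage ~ Uniform(adv_low, adv_high),
    identical across societies. For each society-issue the mean-field model
    is run with magnitude |a| from the symmetric start l = c =
    init_popularity, and popularity at each wave year is read off the
    trajectory (mirrored around the start for negatively advantaged issues,
    where the positively coded opinion is the disadvantaged one).
    """
    rng = np.random.default_rng(config.seed)
    societies = tuple(f"S{i:03d}" for i in range(config.n_societies))
    issues = tuple(f"I{i:03d}" for i in range(config.n_issues))
    lib = {s: float(rng.uniform(config.lib_low, config.lib_high)) for s in societies}
    q = {s: lib_to_q(v) for s, v in lib.items()}
    advantage = {j: float(rng.uniform(config.adv_low, config.adv_high)) for j in issues}

    year0 = config.wave_years[0]
    burn = config.burn_in_years * config.steps_per_year
    T = burn + (config.wave_years[-1] - year0) * config.steps_per_year
    popularity: dict[tuple[str, str], dict[int, float]] = {}
    for s in societies:
        for j in issues:
            a = advantage[j]
            params = ModelParams(q=q[s], a=abs(a), d=config.d, s=config.s)
            traj = simulate_mean_field(
                params, PopulationState(config.init_popularity, config.init_popularity), T
            )
            p = traj.p
            waves = {}
            for y in config.wave_years:
                t = burn + (y - year0) * config.steps_per_year
                val = float(p[t])
                if a < 0:
                    # positively coded opinion is the disadvantaged one
                    val = 2.0 * config.init_popularity - val
                waves[y] = min(max(val, 0.0), 1.0)
            popularity[(s, j)] = waves

    observed = {
        (s, j)
        for s in societies
        for j in issues
        if config.missingness == 0.0 or rng.random() >= config.missingness
    }
    return WorldTruth(
        config=config,
        societies=societies,
        issues=issues,
        lib=lib,
        q=q,
        advantage=advantage,
        popularity=popularity,
        observed=observed,
    )


def true_change_per_decade(world: WorldTruth, society: str, issue: str) -> float:
    """Latent log-odds change per decade between first and last wave."""
    waves = world.popularity[(society, issue)]
    years = sorted(waves)
    p0, p1 = waves[years[0]], waves[years[-1]]
    span_dec = (years[-1] - years[0]) / 10.0
    logit = lambda p: np.log(p / (1.0 - p))
    return float((logit(p1) - logit(p0)) / span_dec)


def generate_opinion_panel(world: WorldTruth, seed: int | None = None) -> pd.DataFrame:
    """Binomial opinion aggregates for every observed society-issue-wave.

    At each wave ``n_agree_w ~ Binomial(n_per_wave, latent popularity)``
    with unit survey weights, so ``n_total_w = n_per_wave``. Columns follow
    the aggregate panel convention of :mod:`moraltides.norm_change`; a
    ``config_hash`` column stamps provenance.
    """
    cfg = world.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    rows = []
    for (s, j) in sorted(world.observed):
        for y in cfg.wave_years:
            p = world.popularity[(s, j)][y]
            k = int(rng.binomial(cfg.n_per_wave, p))
            rows.append({"society": s, "issue_id": j, "wave_year": y,
                         "n_agree_w": float(k), "n_total_w": float(cfg.n_per_wave)})
    df = pd.DataFrame(rows, columns=["society", "issue_id", "wave_year", "n_agree_w", "n_total_w"])
    df["config_hash"] = cfg.hash()
    return df


def _stochastic_grid(values: np.ndarray, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Clip to [0, 1] and round stochastically onto a uniform grid.

    Values are rounded to one of the two adjacent grid points with
    probabilities proportional to proximity, so the expected discretized
    value equals the (clipped) input — discretization adds variance but no
    bias to recovered scores.
    """
    scaled = np.clip(values, 0.0, 1.0) * n_steps
    lower = np.floor(scaled)
    frac = scaled - lower
    up = rng.random(scaled.shape) < frac
    return np.clip(lower + up, 0, n_steps) / n_steps


def generate_argument_ratings(
    world: WorldTruth,
    n_raters_per_issue: int = 215,
    noise_sd: float = 0.15,
    seed: int | None = None,
    base_applicability: float = 0.5,
) -> tuple[list[ArgumentRating], pd.DataFrame]:
    """Applicability-rating survey whose scores recover the true advantages.

    For each issue the latent individualizing applicability of the
    positively coded opinion is ``base + a/2`` and of the opposite opinion
    ``base - a/2``, so the own-minus-opposite gap equals the issue's true
    advantage ``a``. Binding-argument applicability mirrors this with the
    opposite sign, so binding advantages are ``-a`` in expectation. Each
    rater's cells are the latent side means plus Gaussian noise, clipped to
    [0, 1] and stochastically rounded onto the five-point grid (unbiased in
    expectation); rater positions are Bernoulli draws on
    the issue's latest latent global popularity. Returns the rating objects
    and a tidy DataFrame mirror.
    """
    cfg = world.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    individualizing = {"Harm", "Violence", "Fairness", "Liberty"}
    ratings: list[ArgumentRating] = []
    rows = []
    last_wave = cfg.wave_years[-1]
    for j in world.issues:
        a = world.advantage[j]
        # global popularity of the positively coded opinion at the last wave
        p_global = float(np.mean([world.popularity[(s, j)][last_wave] for s in world.societies]))
        for r in range(n_raters_per_issue):
            pid = f"{j}-R{r:04d}"
            society = "SyntheticA" if r % 2 == 0 else "SyntheticB"
            holds_positive = bool(rng.random() < p_global)
            cells = {}
            for kind in ARGUMENT_KINDS:
                sign = 0.5 if kind in individualizing else -0.5
                pos_mean = base_applicability + sign * a
                neg_mean = base_applicability - sign * a
                own_mean = pos_mean if holds_positive else neg_mean
                opp_mean = neg_mean if holds_positive else pos_mean
                cells[(kind, "own")] = own_mean + rng.normal(0.0, noise_sd)
                cells[(kind, "opposite")] = opp_mean + rng.normal(0.0, noise_sd)
            snapped_vals = _stochastic_grid(np.array(list(cells.values())), 4, rng)
            snapped = {k: float(v) for k, v in zip(cells, snapped_vals)}
            ratings.append(
                ArgumentRating(
                    participant_id=pid,
                    society=society,
                    issue_id=j,
                    position_held=holds_positive,
                    applicability=snapped,
                )
            )
            row = {"participant_id": pid, "society": society, "issue_id": j,
                   "position_held": holds_positive}
            for (kind, side), v in snapped.items():
                row[f"{kind}_{side}"] = v
            rows.append(row)
    df = pd.DataFrame(rows)
    df["config_hash"] = cfg.hash()
    return ratings, df


def generate_mfq_responses(
    world: WorldTruth,
    n_per_country: int = 200,
    noise_sd: float = 0.15,
    seed: int | None = None,
    studies: Sequence[str] = ("klein6", "pagliaro7", "saucier5"),
    base_reliance: float = 0.6,
) -> list[MFQResponse]:
    """MFQ-style responses whose LIB estimate recovers each society's truth.

    Latent standardized reliance is ``base + LIB/2`` for individualizing
    items and ``base - LIB/2`` for binding items; per-response noise is
    Gaussian on the standardized scale before discretization onto each
    study's response grid by unbiased stochastic rounding, so the
    individualizing-minus-binding gap stays centred on the true LIB in
    every format.
    """
    cfg = world.config
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    out: list[MFQResponse] = []
    for study in studies:
        lo, hi = MFQ_FORMATS[study]
        for country in world.societies:
            lib = world.lib[country]
            for i in range(n_per_country):
                pid = f"{study}-{country}-P{i:04d}"
                for foundation, items in _MFQ_ITEMS.items():
                    latent = (
                        base_reliance + lib / 2.0
                        if foundation in ("harm", "fairness")
                        else base_reliance - lib / 2.0
                    )
                    for item in items:
                        std = latent + rng.normal(0.0, noise_sd)
                        grid = _stochastic_grid(np.array([std]), hi - lo, rng)[0]
                        resp = float(lo + grid * (hi - lo))
                        out.append(
                            MFQResponse(
                                participant_id=pid,
                                country=country,
                                study_id=study,
                                item_id=f"{study}:{item}",
                                foundation=foundation,
                                response=resp,
                                scale_min=lo,
                                scale_max=hi,
                            )
                        )
    return out
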