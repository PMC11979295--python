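"""Two-type opinion dynamics of argument-driven moral norm change.

A well-mixed population contains a proportion ``q`` of moral liberals and
``1 - q`` of moral conservatives. On a given issue one of the two opinions
holds an *argument advantage* of size ``a``: it is better justified by
individualizing arguments (harm, fairness, liberty), which resonate with
everyone, while binding arguments (authority, loyalty, purity) resonate only
with conservatives. Each time step every agent is, with probability ``d``,
exposed to the opinion of a uniformly random other agent; on hearing a
different opinion, conservatives switch with probability ``s`` in either
direction, whereas liberals switch with probability ``s`` *toward* the
advantaged opinion but only ``(1 - a) s`` *away* from it.

Writing ``l_t`` and ``c_t`` for the popularity of the advantaged opinion
among liberals and conservatives, the expected (mean-field) dynamics are

    l_{t+1} - l_t = d s [ a (1 - l_t) p_t  -  (1 - a)(1 - q)(l_t - c_t) ]
    c_{t+1} - c_t = d s q (l_t - c_t)

with overall popularity ``p_t = q l_t + (1 - q) c_t``. Both the
deterministic recursion and a stochastic agent-based twin with the same
micro-rules are provided, together with accumulated-change profiles across
issues with signed advantages (a negative sign meaning the *opposite*,
negatively coded, opinion holds the advantage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "PopulationState",
    "Trajectory",
    "mean_field_step",
    "simulate_mean_field",
    "simulate_agents",
    "accumulated_change_profile",
]

#: Floating-point slack allowed when clamping state variables back into [0, 1].
CLAMP_TOL = 1e-12


def _check_unit(name: str, value: float, lo: float = 0.0, hi: float = 1.0) -> float:
    value = float(value)
    if math.isnan(value) or not (lo <= value <= hi):
        raise ValueError(f"{name} must lie in [{lo}, {hi}], got {value!r}")
    return value


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the opinion-dynamics model.

    Parameters
    ----------
    q : float
        Proportion of moral liberals in the population, in [0, 1].
    a : float
        Signed argument advantage in [-1, 1]. The magnitude ``|a|`` enters
        the dynamics; the sign records which opinion is advantaged (negative
        means the negatively coded opinion) and is resolved by
        :func:`accumulated_change_profile`.
    d : float
        Per-step probability that an agent is exposed to another agent's
        opinion, in [0, 1].
    s : float
        Switching probability on exposure to a resonating argument, in (0, 1].
    """

    q: float
    a: float
    d: float
    s: float

    def __post_init__(self) -> None:
        _check_unit("q", self.q)
        a = float(self.a)
        if math.isnan(a) or abs(a) > 1.0:
            raise ValueError(f"a must lie in [-1, 1], got {a!r}")
        _check_unit("d", self.d)
        s = _check_unit("s", self.s)
        if s == 0.0:
            raise ValueError("s must be positive")


@dataclass(frozen=True)
class PopulationState:
    """Popularity of the argument-advantaged opinion at one time step.

    ``l`` and ``c`` are the proportions holding the advantaged opinion among
    liberals and conservatives respectively; ``t`` is the time step.
    """

    l: float
    c: float
    t: int = 0

    def __post_init__(self) -> None:
        _check_unit("l", self.l)
        _check_unit("c", self.c)
        if int(self.t) != self.t or self.t < 0:
            raise ValueError(f"t must be a non-negative integer, got {self.t!r}")

    def popularity(self, q: float) -> float:
        """Overall popularity p = q*l + (1-q)*c of the advantaged opinion."""
        return q * self.l + (1.0 - q) * self.c


@dataclass
class Trajectory:
    """An ordered sequence of population states with its provenance."""

    states: list[PopulationState]
    params: ModelParams
    provenance: Literal["mean-field", "agent-based"] = "mean-field"
    seed: int | None = None
    n_agents: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = [s.t for s in self.states]
        if ts != list(range(len(ts))):
            raise ValueError("trajectory time steps must increase from 0 by 1")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def l(self) -> np.ndarray:
        return np.array([s.l for s in self.states])

    @property
    def c(self) -> np.ndarray:
        return np.array([s.c for s in self.states])

    @property
    def p(self) -> np.ndarray:
        """Overall popularity of the advantaged opinion at each step."""
        return self.params.q * self.l + (1.0 - self.params.q) * self.c

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": np.arange(len(self)), "l": self.l, "c": self.c, "p": self.p})


def _clamp(value: float, what: str) -> float:
    if value < 0.0:
        if value < -CLAMP_TOL:
            raise FloatingPointError(f"{what} left [0, 1] by more than {CLAMP_TOL}: {value!r}")
        return 0.0
    if value > 1.0:
        if value > 1.0 + CLAMP_TOL:
            raise FloatingPointError(f"{what} left [0, 1] by more than {CLAMP_TOL}: {value!r}")
        return 1.0
    return value


def mean_field_step(state: PopulationState, params: ModelParams) -> PopulationState:
    """One synchronous step of the deterministic mean-field recursion.

    Uses the unsigned advantage ``|a|``; both updates evaluate the right-hand
    side at time-``t`` values. States are clamped back into [0, 1] only to
    absorb floating error below ``CLAMP_TOL``.
    """
    a = abs(params.a)
    q, d, s = params.q, params.d, params.s
    l, c = state.l, state.c
    p = q * l + (1.0 - q) * c
    l_next = l + d * s * (a * (1.0 - l) * p - (1.0 - a) * (1.0 - q) * (l - c))
    c_next = c + d * s * q * (l - c)
    return PopulationState(_clamp(l_next, "l"), _clamp(c_next, "c"), state.t + 1)


def simulate_mean_field(params: ModelParams, init: PopulationState, T: int) -> Trajectory:
    """Iterate :func:`mean_field_step` for ``T`` steps starting from ``init``.

    The initial state is re-timed to ``t = 0``; the result holds ``T + 1``
    states. ``T = 0`` returns the initial state alone.
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    states = [PopulationState(init.l, init.c, 0)]
    for _ in range(T):
        states.append(mean_field_step(states[-1], params))
    return Trajectory(states, params, provenance="mean-field")


def simulate_agents(
    n_agents: int,
    params: ModelParams,
    init: PopulationState,
    T: int,
    seed: int | np.random.Generator,
    deterministic_init: bool = False,
) -> Trajectory:
    """Stochastic agent-based simulation with the model's micro-rules.

    ``floor(q * n_agents)`` agents are liberal, the rest conservative.
    Initial opinions are i.i.d. Bernoulli(``init.l``) / Bernoulli(``init.c``)
    by type, or assigned by deterministic rounding of the expected counts when
    ``deterministic_init`` is set. Each step, every agent independently with
    probability ``d`` observes a uniformly random *other* agent's time-``t``
    opinion; if it differs from their own, conservatives switch with
    probability ``s`` in either direction while liberals switch with
    probability ``s`` toward the advantaged opinion and ``(1 - |a|) s`` away
    from it. The same seed reproduces the trajectory exactly.
    """
    if n_agents < 2:
        raise ValueError("n_agents must be at least 2")
    if T < 0:
        raise ValueError("T must be non-negative")
    if isinstance(seed, np.random.Generator):
        rng = seed
    elif isinstance(seed, (int, np.integer)) and not isinstance(seed, bool):
        rng = np.random.default_rng(int(seed))
    else:
        raise TypeError(f"seed must be an integer or Generator, got {type(seed).__name__}")

    a = abs(params.a)
    q, d, s = params.q, params.d, params.s
    n_lib = int(math.floor(q * n_agents))
    is_lib = np.zeros(n_agents, dtype=bool)
    is_lib[:n_lib] = True

    # opinion True = holds the argument-advantaged opinion
    opinion = np.empty(n_agents, dtype=bool)
    if deterministic_init:
        k_l = int(round(init.l * n_lib))
        k_c = int(round(init.c * (n_agents - n_lib)))
        opinion[:n_lib] = np.arange(n_lib) < k_l
        opinion[n_lib:] = np.arange(n_agents - n_lib) < k_c
    else:
        opinion[:n_lib] = rng.random(n_lib) < init.l
        opinion[n_lib:] = rng.random(n_agents - n_lib) < init.c

    def observe() -> PopulationState:
        l = float(opinion[:n_lib].mean()) if n_lib else 0.0
        c = float(opinion[n_lib:].mean()) if n_lib < n_agents else 0.0
        return PopulationState(l, c, 0)

    states = []
    st = observe()
    states.append(st)
    for t in range(T):
        exposed = rng.random(n_agents) < d
        idx = np.nonzero(exposed)[0]
        if idx.size:
            # partner drawn uniformly among the *other* n-1 agents
            partner = rng.integers(0, n_agents - 1, size=idx.size)
            partner = np.where(partner >= idx, partner + 1, partner)
            other = opinion[partner]
            mine = opinion[idx]
            differs = other != mine
            # switching toward the advantaged opinion: currently holding the
            # disadvantaged one (mine False) and hearing the advantaged one
            toward = ~mine
            p_switch = np.where(
                is_lib[idx],
                np.where(toward, s, (1.0 - a) * s),
                s,
            )
            do_switch = differs & (rng.random(idx.size) < p_switch)
            new_op = opinion.copy()
            new_op[idx[do_switch]] = other[do_switch]
            opinion = new_op
        l = float(opinion[:n_lib].mean()) if n_lib else 0.0
        c = float(opinion[n_lib:].mean()) if n_lib < n_agents else 0.0
        states.append(PopulationState(l, c, t + 1))
    return Trajectory(
        states,
        params,
        provenance="agent-based",
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
        n_agents=n_agents,
    )


def accumulated_change_profile(
    advantages: Sequence[float],
    q: float,
    d: float,
    s: float,
    T: int,
    init_popularity: float = 0.5,
):
    """Accumulated change in popularity over ``T`` steps for each issue.

    For each signed advantage ``a`` the model is run from the symmetric start
    ``l = c = init_popularity`` with magnitude ``|a|``; the change in overall
    popularity ``p_T - p_0`` and in log odds ``logit(p_T) - logit(p_0)`` are
    reported, sign-flipped for ``a < 0`` (there the positively coded opinion
    is the *disadvantaged* one, so its popularity falls by symmetry).

    Returns a DataFrame with columns ``a``, ``delta_p``, ``delta_logodds``.
    """
    import pandas as pd

    if not (0.0 < init_popularity < 1.0):
        raise ValueError("init_popularity must be strictly inside (0, 1)")
    rows = []
    for a in advantages:
        a = float(a)
        if abs(a) > 1.0:
            raise ValueError(f"advantage magnitude must not exceed 1, got {a!r}")
        params = ModelParams(q=q, a=abs(a), d=d, s=s)
        traj = simulate_mean_field(params, PopulationState(init_popularity, init_popularity), T)
        p0, pT = traj.p[0], traj.p[-1]
        delta_p = pT - p0
        delta_lo = math.log(pT / (1.0 - pT)) - math.log(p0 / (1.0 - p0))
        sign = -1.0 if a < 0 else 1.0
        rows.append({"a": a, "delta_p": sign * delta_p, "delta_logodds": sign * delta_lo})
    return pd.DataFrame(rows)
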