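import numpy as np
import pandas as pd
import pytest

from moraltides.argument_advantage import ARGUMENT_KINDS, ArgumentRating


def make_rating(
    own=0.5,
    opposite=0.5,
    position_held=True,
    issue_id="issue",
    participant_id="p1",
    society="US",
    **cell_overrides,
):
    """Build an ArgumentRating with uniform side values plus overrides.

    Overrides use keys like ``Harm_own=1.0``.
    """
    cells = {}
    for kind in ARGUMENT_KINDS:
        cells[(kind, "own")] = own
        cells[(kind, "opposite")] = opposite
    for key, value in cell_overrides.items():
        kind, side = key.rsplit("_", 1)
        cells[(kind, side)] = value
    return ArgumentRating(
        participant_id=participant_id,
        society=society,
        issue_id=issue_id,
        position_held=position_held,
        applicability=cells,
    )


def binomial_panel(rng, slopes, intercepts, wave_years=(1990, 2000, 2010), n=500):
    """Aggregate opinion panel drawn from per-society-issue logistic trends.

    ``slopes[j]`` is issue j's log-odds change per decade; ``intercepts`` is
    a (society, issue) array of logit levels at the first wave.
    """
    n_soc, n_iss = intercepts.shape
    rows = []
    for j in range(n_iss):
        for c in range(n_soc):
            for k, y in enumerate(wave_years):
                dec = (y - wave_years[0]) / 10.0
                p = 1.0 / (1.0 + np.exp(-(intercepts[c, j] + slopes[j] * dec)))
                rows.append(
                    {
                        "society": f"S{c:02d}",
                        "issue_id": f"I{j:02d}",
                        "wave_year": y,
                        "n_agree_w": float(rng.binomial(n, p)),
                        "n_total_w": float(n),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic world shared across read-only tests."""
    from moraltides.synthetic_data import WorldConfig, generate_world

    return generate_world(WorldConfig(n_societies=8, n_issues=6, seed=11))
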