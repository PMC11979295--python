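"""Society-level moral liberalness (LIB) from moral-foundations questionnaires.

LIB measures how much more strongly a society relies on the individualizing
moral foundations (harm, fairness) than on the binding ones (authority,
in-group loyalty, purity). Cross-cultural MFQ studies use different response
scales (5-, 6- and 7-point formats), so every response is first rescaled to
[0, 1]; within each country-by-study cell the standardized responses are
averaged per item, items are averaged within each foundation group, and LIB
is the individualizing mean minus the binding mean. Countries appearing in
several studies get the unweighted average of their per-study values.

LIB serves as an observable proxy for the proportion of moral liberals in
the opinion-dynamics model: binding arguments resonate only with moral
conservatives, so a larger individualizing-minus-binding gap indicates a
more liberal society.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "INDIVIDUALIZING",
    "BINDING",
    "MFQResponse",
    "SocietyLiberalness",
    "standardize_response",
    "society_liberalness_one_study",
    "combine_studies",
    "liberalness_table",
]

INDIVIDUALIZING = frozenset({"harm", "fairness"})
BINDING = frozenset({"authority", "loyalty", "purity"})
#: Accepted but excluded from both sides of the LIB difference.
NEUTRAL = frozenset({"liberty"})


@dataclass(frozen=True)
class MFQResponse:
    """One participant's response to one MFQ item on a declared scale."""

    participant_id: str
    country: str
    study_id: str
    item_id: str
    foundation: str
    response: float
    scale_min: float
    scale_max: float

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be below scale_max")
        if not (self.scale_min <= self.response <= self.scale_max):
            raise ValueError(
                f"response {self.response!r} outside scale "
                f"[{self.scale_min}, {self.scale_max}]"
            )
        f = self.foundation.lower()
        if f not in INDIVIDUALIZING | BINDING | NEUTRAL:
            raise ValueError(f"unknown foundation {self.foundation!r}")


@dataclass(frozen=True)
class SocietyLiberalness:
    """Per-society LIB score and the number of studies it averages."""

    country: str
    lib: float
    studies_used: int

    def __post_init__(self) -> None:
        if abs(self.lib) > 1.0 + 1e-12:
            raise ValueError(f"|lib| must not exceed 1, got {self.lib!r}")
        if self.studies_used < 1:
            raise ValueError("studies_used must be at least 1")


def standardize_response(value: float, scale_min: float, scale_max: float) -> float:
    """Rescale a response linearly so the scale's range becomes [0, 1]."""
    if scale_min >= scale_max:
        raise ValueError("scale_min must be below scale_max")
    if not (scale_min <= value <= scale_max):
        raise ValueError(f"value {value!r} outside scale [{scale_min}, {scale_max}]")
    return (value - scale_min) / (scale_max - scale_min)


def society_liberalness_one_study(responses: Sequence[MFQResponse]) -> float:
    """LIB for one country-by-study cell.

    Standardized responses are averaged per item across participants, item
    means are averaged within each foundation group, and the result is
    mean(individualizing) - mean(binding). Items labelled ``liberty`` are
    accepted but enter neither side.
    """
    if not responses:
        raise ValueError("no responses")
    cells = {(r.country, r.study_id) for r in responses}
    if len(cells) != 1:
        raise ValueError(f"responses mix country/study cells: {sorted(cells)}")
    by_item: dict[str, list[float]] = {}
    item_side: dict[str, str] = {}
    for r in responses:
        f = r.foundation.lower()
        side = "ind" if f in INDIVIDUALIZING else "bind" if f in BINDING else "skip"
        if side == "skip":
            continue
        std = standardize_response(r.response, r.scale_min, r.scale_max)
        by_item.setdefault(r.item_id, []).append(std)
        item_side[r.item_id] = side
    ind = [np.mean(v) for item, v in by_item.items() if item_side[item] == "ind"]
    bind = [np.mean(v) for item, v in by_item.items() if item_side[item] == "bind"]
    if not ind or not bind:
        raise ValueError("need at least one individualizing and one binding item")
    return float(np.mean(ind) - np.mean(bind))


def combine_studies(country: str, study_values: Sequence[float]) -> SocietyLiberalness:
    """Average a country's per-study LIB values without weighting."""
    if not len(study_values):
        raise ValueError("no study values to combine")
    return SocietyLiberalness(
        country=country,
        lib=float(np.mean(study_values)),
        studies_used=len(study_values),
    )


def liberalness_table(responses: Iterable[MFQResponse]) -> list[SocietyLiberalness]:
    """Full pipeline: per country-study LIB, then per-country study averages."""
    by_cell: dict[tuple[str, str], list[MFQResponse]] = {}
    for r in responses:
        by_cell.setdefault((r.country, r.study_id), []).append(r)
    per_country: dict[str, list[float]] = {}
    for (country, _study), rs in sorted(by_cell.items()):
        per_country.setdefault(country, []).append(society_liberalness_one_study(rs))
    return [combine_studies(c, vals) for c, vals in sorted(per_country.items())]
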