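"""Pipeline orchestration: configuration, I/O conventions and the replication run.

File conventions: UTF-8 comma-separated CSV with a header row and "."
decimals; issue and society identifiers are opaque strings. Every written
artifact embeds the run's config hash and seeds. The packaged fixture
``fixtures/table3.csv`` carries the published per-issue argument advantages
and change-rate estimates (with CIs) for the 33 moral issues, enabling a
fixture-only run that reproduces the profile-correlation test without any
external data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import norm_change, prediction_tests
from .argument_advantage import (
    ArgumentRating,
    KIND_SETS,
    ParticipantScreen,
    filter_participants,
    issue_advantage,
)
from .liberalness import MFQResponse, liberalness_table
from .norm_change import ItemScaleSpec

__all__ = [
    "RunConfig",
    "load_table3",
    "table3_profile_correlation",
    "read_ratings_csv",
    "read_screens_csv",
    "read_mfq_csv",
    "load_scale_specs",
    "score_aa_table",
    "run_replication",
]

log = logging.getLogger("moraltides")


def load_table3() -> pd.DataFrame:
    """The packaged table of published per-issue scores and change rates."""
    with resources.files("moraltides.fixtures").joinpath("table3.csv").open() as fh:
        return pd.read_csv(fh)


def table3_profile_correlation(which: str = "alter", B: int = 10_000, seed: int = 0) -> dict:
    """Mirrored r between published argument advantages and change rates.

    ``which`` selects the change column: ``"alter"`` (all available data,
    33 issues) or ``"prereg"`` (preregistered subsets, 25 issues). Returns
    the correlation with an issue-level bootstrap CI.
    """
    t3 = load_table3()
    col = {"alter": "change_alter", "prereg": "change_prereg"}[which]
    sub = t3.dropna(subset=[col])
    x = prediction_tests.mirror_profile(dict(zip(sub["issue_id"], sub["arg_adv"])))
    y = prediction_tests.mirror_profile(dict(zip(sub["issue_id"], sub[col])))
    out = prediction_tests.bootstrap_ci_over_issues(x, y, B=B, seed=seed)
    out["change_column"] = col
    return out


@dataclass
class RunConfig:
    """Configuration of a replication run.

    Paths may be None when a stage's input is unavailable; downstream
    stages then degrade gracefully (reported as not computed). An empty
    ``societies`` list means no inclusion filter.
    """

    opinions_csv: str | None = None
    scales_yaml: str | None = None
    ratings_csv: str | None = None
    screens_csv: str | None = None
    mfq_csv: str | None = None
    societies: list[str] = field(default_factory=list)
    estimator: str = "multilevel"
    aa_variant: str = "standard"
    bootstrap_B: int = 10_000
    n_partitions: int = 300
    seed: int = 0
    out_dir: str = "moraltides_out"

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def read_ratings_csv(path) -> list[ArgumentRating]:
    """Parse a ratings CSV with 14 ``<Kind>_<side>`` applicability columns."""
    df = pd.read_csv(path)
    out = []
    from .argument_advantage import ARGUMENT_KINDS

    for _, row in df.iterrows():
        cells = {
            (k, side): float(row[f"{k}_{side}"])
            for k in ARGUMENT_KINDS
            for side in ("own", "opposite")
        }
        out.append(
            ArgumentRating(
                participant_id=str(row["participant_id"]),
                society=str(row["society"]),
                issue_id=str(row["issue_id"]),
                position_held=bool(row["position_held"]),
                applicability=cells,
            )
        )
    return out


def read_screens_csv(path) -> list[ParticipantScreen]:
    df = pd.read_csv(path)
    return [
        ParticipantScreen(str(r["participant_id"]), int(r["vocab_correct"]))
        for _, r in df.iterrows()
    ]


def read_mfq_csv(path) -> list[MFQResponse]:
    df = pd.read_csv(path)
    return [
        MFQResponse(
            participant_id=str(r["participant_id"]),
            country=str(r["country"]),
            study_id=str(r["study_id"]),
            item_id=str(r["item_id"]),
            foundation=str(r["foundation"]),
            response=float(r["response"]),
            scale_min=float(r["scale_min"]),
            scale_max=float(r["scale_max"]),
        )
        for _, r in df.iterrows()
    ]


def load_scale_specs(path) -> dict[str, ItemScaleSpec]:
    """Read dichotomization specs from YAML keyed by issue id.

    Each entry holds ``kind``, ``ones``, ``zeros`` and optional
    ``excluded`` lists; the shorthand ``kind: justifiability-10`` may be
    given alone.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = {}
    for issue, entry in raw.items():
        if isinstance(entry, str) or (isinstance(entry, dict) and "ones" not in entry):
            kind = entry if isinstance(entry, str) else entry.get("kind")
            if kind != "justifiability-10":
                raise ValueError(f"unknown scale shorthand {kind!r} for issue {issue!r}")
            specs[issue] = norm_change.JUSTIFIABILITY_10(issue)
        else:
            specs[issue] = ItemScaleSpec(
                issue_id=issue,
                kind=entry.get("kind", "custom"),
                ones=frozenset(entry["ones"]),
                zeros=frozenset(entry["zeros"]),
                excluded=frozenset(entry.get("excluded", ())),
            )
    return specs


def score_aa_table(
    ratings: list[ArgumentRating],
    screens: list[ParticipantScreen] | None = None,
    variant: str = "standard",
    min_correct: int = 6,
) -> pd.DataFrame:
    """Per-issue advantage scores after the vocabulary screen.

    Societies are pooled by default, matching the published per-issue
    scores that aggregate both survey samples.
    """
    if screens is not None:
        keep = set(filter_participants(screens, min_correct=min_correct))
        ratings = [r for r in ratings if r.participant_id in keep]
    by_issue: dict[str, list[ArgumentRating]] = {}
    for r in ratings:
        by_issue.setdefault(r.issue_id, []).append(r)
    rows = [
        {"issue_id": issue, "aa": ia.aa, "variant": ia.variant, "n_raters": ia.n_raters}
        for issue, rs in sorted(by_issue.items())
        for ia in [issue_advantage(rs, variant=variant)]
    ]
    return pd.DataFrame(rows)


def _stage(report: dict, name: str):
    """Context manager recording a stage's success or structured failure."""
    import contextlib

    @contextlib.contextmanager
    def cm():
        try:
            yield
            report["stages"][name] = "ok"
        except Exception as e:  # noqa: BLE001 - structured per-stage reporting
            log.exception("stage %s failed", name)
            report["stages"][name] = f"failed: {type(e).__name__}: {e}"

    return cm()


def run_replication(config: RunConfig) -> dict:
    """Execute the full pipeline and write a report bundle to ``out_dir``.

    Stages: argument-advantage scoring, liberalness scoring, change-rate
    estimation (with period splits where eligible) and the prediction
    tests. Stages whose inputs are missing are skipped and the report marks
    the affected predictions as not computed. A run without any inputs
    still produces the profile-correlation block from the packaged table of
    published values.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": {}}

    aa_map = aa_binding = None
    with _stage(report, "score-aa"):
        if config.ratings_csv:
            ratings = read_ratings_csv(config.ratings_csv)
            screens = read_screens_csv(config.screens_csv) if config.screens_csv else None
            aa_df = score_aa_table(ratings, screens, variant=config.aa_variant)
            aa_bind_df = score_aa_table(ratings, screens, variant="binding")
            aa_df["config_hash"] = config.hash()
            aa_df.to_csv(out_dir / "aa.csv", index=False)
            aa_map = dict(zip(aa_df["issue_id"], aa_df["aa"]))
            aa_binding = dict(zip(aa_bind_df["issue_id"], aa_bind_df["aa"]))

    lib_map = None
    with _stage(report, "liberalness"):
        if config.mfq_csv:
            libs = liberalness_table(read_mfq_csv(config.mfq_csv))
            lib_df = pd.DataFrame(
                [{"country": x.country, "lib": x.lib, "studies_used": x.studies_used} for x in libs]
            )
            lib_df["config_hash"] = config.hash()
            lib_df.to_csv(out_dir / "lib.csv", index=False)
            lib_map = dict(zip(lib_df["country"], lib_df["lib"]))

    rates = per_society = early = late = None
    with _stage(report, "estimate-change"):
        if config.opinions_csv:
            panel = pd.read_csv(config.opinions_csv)
            if config.societies:
                panel = panel[panel["society"].isin(config.societies)]
            if "response" in panel.columns and config.scales_yaml:
                specs = load_scale_specs(config.scales_yaml)
                panel = norm_change.dichotomize_panel(panel, specs)
            agg = norm_change.aggregate_records(panel)
            if config.estimator == "fixed":
                ests = [
                    norm_change.fit_fixed_change(agg[agg["issue_id"] == j])
                    for j in sorted(agg["issue_id"].unique())
                ]
            else:
                ests = norm_change.fit_multilevel_change(agg)
            rates_df = pd.DataFrame(
                [
                    {"issue_id": e.issue_id, "rate": e.rate, "ci_low": e.ci_low,
                     "ci_high": e.ci_high, "estimator": e.estimator,
                     "n_societies": e.n_societies, "ci_method": "wald"}
                    for e in ests
                ]
            )
            rates_df["config_hash"] = config.hash()
            rates_df.to_csv(out_dir / "rates.csv", index=False)
            rates = dict(zip(rates_df["issue_id"], rates_df["rate"]))

            rows = []
            for (soc, issue), cell in agg.groupby(["society", "issue_id"]):
                if cell["wave_year"].nunique() < 2:
                    continue
                est = norm_change.fit_fixed_change(cell)
                rows.append({"society": soc, "issue_id": issue, "rate": est.rate})
            per_society = pd.DataFrame(rows)

            early_parts, late_parts = [], []
            for (_soc, _issue), cell in agg.groupby(["society", "issue_id"]):
                split = norm_change.split_by_period(cell)
                if split is not None:
                    early_parts.append(split[0])
                    late_parts.append(split[1])
            if early_parts:
                early_agg = pd.concat(early_parts)
                late_agg = pd.concat(late_parts)
                early = {e.issue_id: e.rate for e in norm_change.fit_multilevel_change(early_agg)}
                late = {e.issue_id: e.rate for e in norm_change.fit_multilevel_change(late_agg)}

    interaction = None
    with _stage(report, "interaction-model"):
        if config.opinions_csv and aa_map and lib_map:
            interaction = norm_change.fit_interaction_model(agg, aa_map, lib_map)

    with _stage(report, "test-predictions"):
        if rates and aa_map:
            pred = prediction_tests.evaluate_predictions(
                change_rates=rates,
                aa_by_issue=aa_map,
                aa_binding_by_issue=aa_binding,
                change_by_society_issue=per_society,
                early_rates=early,
                late_rates=late,
                interaction_fit=interaction,
                B=config.bootstrap_B,
                n_partitions=config.n_partitions,
                seed=config.seed,
            )
        else:
            pred = {"note": "pipeline inputs unavailable; see published-values block"}
        report["predictions"] = pred

    with _stage(report, "published-values"):
        report["published_profile_correlation"] = table3_profile_correlation(
            "alter", B=config.bootstrap_B, seed=config.seed
        )

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
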