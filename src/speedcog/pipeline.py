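"""End-to-end study pipeline: simulate, validate, score, filter, analyze, norms.

``run_study`` orchestrates the full flow and writes every intermediate and
final table plus a run manifest (stage counts, seed, config hash, file
checksums).  Identical config and seed reproduce byte-identical outputs.

The primary device comparison uses each respondent's first completed
session only; the within-person comparison over both-device owners is an
optional extra stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .figid import score_figid_log
from .records import AGE_GROUP_EDGES, ScoringLimits, SpeedcogError, Test
from .sgst import filter_scored, score_sgst_log
from .simulate import SimConfig, simulate_cohort
from .stats import (
    device_effect_table,
    distraction_regression_table,
    weighted_group_norms,
    within_person_device_comparison,
)

logger = logging.getLogger(__name__)

SGST_SCORE_COLS = [
    "median_normal_s",
    "median_reverse_s",
    "median_nonswitch_s",
    "median_switch_s",
]
FIGID_SCORE_COLS = ["score", "pct_incorrect", "median_rt_correct_s"]
ENV_COLS = [
    "interrupted",
    "at_home",
    "watching_tv",
    "listening_music",
    "talking",
    "texting_email",
    "internet_content",
    "playing_game",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one reproducible study run."""

    sim: SimConfig = field(default_factory=SimConfig)
    limits: ScoringLimits = field(default_factory=ScoringLimits)
    include_incorrect_trials: bool = False
    age_edges: tuple[int, ...] = AGE_GROUP_EDGES
    alpha: float = 0.05
    within_person: bool = False

    def __post_init__(self) -> None:
        if list(self.age_edges) != sorted(set(self.age_edges)):
            raise SpeedcogError("age-group edges must be strictly increasing")
        if self.age_edges[0] != 18:
            raise SpeedcogError("age groups must start at 18")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(data.pop("sim", {}))
        limits = ScoringLimits(**data.pop("limits", {}))
        if "age_edges" in data:
            data["age_edges"] = tuple(data["age_edges"])
        return cls(sim=sim, limits=limits, **data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "sim": config.sim.to_dict(),
            "limits": config.limits.__dict__,
            "include_incorrect_trials": config.include_incorrect_trials,
            "age_edges": list(config.age_edges),
            "alpha": config.alpha,
            "within_person": config.within_person,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _first_sessions(scores: pd.DataFrame) -> pd.DataFrame:
    """Keep each respondent's first session (primary between-person analysis)."""
    return (
        scores.sort_values(["respondent_id", "session_index"])
        .groupby("respondent_id", as_index=False)
        .first()
    )


def analyze_scores(
    scores: pd.DataFrame,
    respondents: pd.DataFrame,
    environment: pd.DataFrame,
    score_cols: list[str],
) -> dict[str, pd.DataFrame]:
    """Run the full analysis block for one test's retained first-session scores.

    ``environment`` must already be restricted to the matching test.
    Returns the device-effect table, the distraction regression table, and
    the weighted age-group norms (one block per score).
    """
    effects = device_effect_table(scores, respondents, score_cols)
    regression = distraction_regression_table(
        scores, respondents, environment.drop(columns=["test"]), score_cols, ENV_COLS
    )
    merged = scores.merge(
        respondents[["respondent_id", "age", "weight"]], on="respondent_id"
    )
    norm_blocks = []
    for col in score_cols:
        block = weighted_group_norms(merged[col], merged["weight"], merged["age"])
        block.insert(0, "score_name", col)
        norm_blocks.append(block)
    return {
        "effects": effects,
        "regression": regression,
        "norms": pd.concat(norm_blocks, ignore_index=True),
    }


def run_study(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute simulate -> validate -> score -> filter -> analyze -> norms.

    Writes all stage outputs under ``out_dir`` and returns the manifest
    (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    logger.info("stage simulate: n_respondents=%d", config.sim.n_respondents)
    respondents, trials, environment = simulate_cohort(config.sim)
    io.write_respondents(respondents, out / "respondents.csv")
    io.write_trial_log(trials, out / "trials.csv", validate_counts=False)
    io.write_environment(environment, out / "environment.csv")
    counts["respondents"] = len(respondents)
    counts["trials"] = len(trials)

    logger.info("stage validate")
    invalid = []
    for key, group in trials.groupby(
        ["respondent_id", "test", "session_index"], sort=False
    ):
        report = io.validate_session(group)
        if not report.valid:
            invalid.append(key)
    if invalid:
        raise SpeedcogError(f"stage validate: {len(invalid)} invalid sessions")
    counts["sessions"] = int(
        trials.groupby(["respondent_id", "test", "session_index"]).ngroups
    )

    logger.info("stage score")
    sgst_all = score_sgst_log(trials, config.include_incorrect_trials)
    figid_all = score_figid_log(trials, config.limits)
    sgst_all.to_csv(out / "sgst_scores.csv", index=False)
    figid_all.to_csv(out / "figid_scores.csv", index=False)

    manifest_tables: dict[str, str] = {}
    for test, scores_all, score_cols in (
        (Test.SGST, sgst_all, SGST_SCORE_COLS),
        (Test.FIGID, figid_all, FIGID_SCORE_COLS),
    ):
        if scores_all.empty:
            continue
        name = test.value.lower()
        first = _first_sessions(scores_all)
        retained, excluded = filter_scored(first)
        counts[f"{name}_completed"] = len(first)
        counts[f"{name}_scored"] = len(retained)
        counts[f"{name}_excluded"] = len(excluded)
        env_test = environment.loc[environment["test"] == test.value]
        results = analyze_scores(retained, respondents, env_test, score_cols)
        results["effects"].to_csv(out / f"{name}_device_effects.csv", index=False)
        results["regression"].to_csv(
            out / f"{name}_distraction_regression.csv", index=False
        )
        results["norms"].to_csv(out / f"{name}_norms.csv", index=False)
        for kind in ("device_effects", "distraction_regression", "norms"):
            manifest_tables[f"{name}_{kind}"] = f"{name}_{kind}.csv"
        if config.within_person:
            paired_rows = []
            both, _ = filter_scored(scores_all)
            eligible = both.groupby("respondent_id").filter(
                lambda g: set(g["device_type"]) == {"keyboard", "touchscreen"}
            )
            if eligible["respondent_id"].nunique() >= 3:
                for col in score_cols:
                    cmp = within_person_device_comparison(
                        eligible[["respondent_id", "device_type", col]],
                        score_name=col,
                    )
                    paired_rows.append(cmp.__dict__)
                pd.DataFrame(paired_rows).to_csv(
                    out / f"{name}_within_person.csv", index=False
                )

    files = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
    }
    manifest = {
        "seed": config.sim.seed,
        "config_sha256": _config_hash(config),
        "counts": counts,
        "files": files,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %s", counts)
    return manifest
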