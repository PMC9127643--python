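"""Synthetic cohort generator for the two speeded web tests.

The study's panel microdata are not public, so every downstream stage is
exercised on synthetic cohorts drawn from an explicit generative model:

* Trial latencies are lognormal.  For respondent *i* on trial *t*,

  ``log RT_it = baseline(condition/item) + beta_age * (age_i - 50)
                + delta_device * 1[touchscreen] + delta_interrupt * 1[interrupted]
                + u_i + e_it``

  with person effect ``u_i ~ N(0, sigma_person^2)`` and trial noise
  ``e_it ~ N(0, sigma_trial^2)``.  Additive effects on the log scale give
  right-skewed latencies with multiplicative age/device effects, and sample
  medians track ``exp(baseline)``.
* Correctness is Bernoulli: 0.97 per trial for attentive respondents and
  0.55 for a small careless subpopulation (default 5%), whose latencies are
  also shrunk to 0.6x (rushing).  The careless group is what the 70%
  accuracy filter is designed to catch.
* A per-session interruption indicator and seven other binary environment
  fields are drawn at study-like prevalences (about 12.5% interrupted,
  about 90% at home, ...).
* Rare figure-test latencies above 30 s (walk-aways) occur with probability
  ``p_outlier`` per trial.
* Sampling weights are two-way inverse-inclusion weights over age band x
  education, normalized to mean 1: the cohort over-samples older and
  college-educated bands relative to the nominal population shares, so
  weighted and unweighted norms genuinely differ.

Reproducibility: one global seed drives a named substream per respondent
(``SeedSequence(seed, spawn_key=(i,))``), so enlarging the cohort never
perturbs earlier respondents.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import (
    AGE_GROUP_EDGES,
    FIGID_N_BLOCKS,
    FIGID_N_ITEMS,
    SGST_TRIAL_INVENTORY,
    ConfigurationError,
    ItemStats,
    TrialType,
    age_group_label,
)

_MS_PER_S = 1000.0

# Fixed SGST administration order: two baseline blocks then the 29-trial
# mixed block, with the 6 rule switches at fixed positions.
_SGST_SEQUENCE: tuple[str, ...] = (
    (TrialType.NORMAL.value,) * 10
    + (TrialType.REVERSE.value,) * 10
    + tuple(
        TrialType.SWITCH.value if k in (0, 5, 10, 15, 20, 25) else TrialType.NONSWITCH.value
        for k in range(29)
    )
)
assert len(_SGST_SEQUENCE) == 49

# Nominal population shares vs. panel sampling rates over the six age bands
# and three education levels; weights are their ratios.  Older and
# college-educated strata are over-sampled relative to the population.
_POP_AGE_SHARE = np.array([0.30, 0.16, 0.16, 0.16, 0.12, 0.10])
_SAMPLE_AGE_RATE = np.array([0.205, 0.21, 0.19, 0.19, 0.155, 0.05])
_EDUCATION_LEVELS = ("hs_or_less", "some_college", "bachelor_plus")
_POP_EDU_SHARE = np.array([0.40, 0.30, 0.30])
_SAMPLE_EDU_RATE = np.array([0.20, 0.35, 0.45])

_DEVICE_MIX = {"both": 0.52, "keyboard": 0.16, "touchscreen": 0.32}

_DEFAULT_ENV_PREVALENCE = {
    "interrupted": 0.125,
    "at_home": 0.896,
    "watching_tv": 0.15,
    "listening_music": 0.085,
    "talking": 0.07,
    "texting_email": 0.007,
    "internet_content": 0.007,
    "playing_game": 0.0015,
}


def _default_trial_type_baselines() -> dict[str, float]:
    # log-seconds chosen so median RTs at age 50 on a keyboard sit near
    # 1.0 / 1.1 / 0.95 / 1.5 s for normal / reverse / nonswitch / switch
    return {
        "normal": math.log(1.0),
        "reverse": math.log(1.1),
        "nonswitch": math.log(0.95),
        "switch": math.log(1.5),
    }


def _default_figid_item_baselines() -> tuple[float, ...]:
    # 60 item difficulties spanning roughly 3-7 s median latency
    return tuple(np.linspace(math.log(3.0), math.log(7.0), FIGID_N_ITEMS))


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the synthetic cohort.

    Latency effects are additive on log seconds: ``beta_age`` per year of
    age (centered at 50), ``delta_device`` for touch-screen sessions,
    ``delta_interrupt`` for interrupted sessions.
    """

    n_respondents: int = 1000
    seed: int = 0
    age_range: tuple[int, int] = (18, 101)
    beta_age: float = 0.006
    delta_device: float = 0.05
    delta_interrupt: float = 0.08
    trial_type_baselines: dict[str, float] = field(
        default_factory=_default_trial_type_baselines
    )
    figid_item_baselines: tuple[float, ...] = field(
        default_factory=_default_figid_item_baselines
    )
    sigma_person: float = 0.25
    sigma_trial: float = 0.20
    p_correct_attentive: float = 0.97
    p_correct_careless: float = 0.55
    careless_fraction: float = 0.05
    careless_latency_factor: float = 0.6
    p_outlier: float = 0.002
    outlier_range_s: tuple[float, float] = (30.0, 60.0)
    env_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ENV_PREVALENCE)
    )
    tests: tuple[str, ...] = ("SGST", "FIGID")
    second_session_for_both_owners: bool = True
    #: assign devices deterministically by alternation (exactly half the
    #: cohort per device, one session each) for controlled two-group designs
    balanced_device_assignment: bool = False

    def __post_init__(self) -> None:
        if self.n_respondents <= 0:
            raise ConfigurationError("n_respondents must be positive")
        if self.sigma_person <= 0 or self.sigma_trial <= 0:
            raise ConfigurationError("sigma_person and sigma_trial must be > 0")
        probs = [
            self.p_correct_attentive,
            self.p_correct_careless,
            self.careless_fraction,
            self.p_outlier,
            *self.env_prevalence.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if len(self.figid_item_baselines) != FIGID_N_ITEMS:
            raise ConfigurationError("figid_item_baselines must have 60 entries")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        for key in ("age_range", "figid_item_baselines", "tests", "outlier_range_s"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _respondent_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _draw_demographics(rng: np.random.Generator, config: SimConfig):
    band = int(rng.choice(6, p=_SAMPLE_AGE_RATE / _SAMPLE_AGE_RATE.sum()))
    edges = [*AGE_GROUP_EDGES, config.age_range[1] + 1]
    lo, hi = edges[band], min(edges[band + 1], config.age_range[1] + 1)
    age = int(rng.integers(lo, hi))
    edu = int(rng.choice(3, p=_SAMPLE_EDU_RATE / _SAMPLE_EDU_RATE.sum()))
    raw_weight = (_POP_AGE_SHARE[band] / (_SAMPLE_AGE_RATE[band] / _SAMPLE_AGE_RATE.sum())) * (
        _POP_EDU_SHARE[edu] / (_SAMPLE_EDU_RATE[edu] / _SAMPLE_EDU_RATE.sum())
    )
    sex = "female" if rng.random() < 0.59 else "male"
    race = str(rng.choice(["white", "black", "hispanic", "other"], p=[0.65, 0.07, 0.16, 0.12]))
    income = str(rng.choice(["lt25k", "25-50k", "50-100k", "ge100k"], p=[0.17, 0.21, 0.33, 0.29]))
    return age, _EDUCATION_LEVELS[edu], sex, race, income, raw_weight


def _session_devices(rng: np.random.Generator, config: SimConfig) -> list[str]:
    """Devices for session 1 (and 2 for both-device owners), in order."""
    owned = str(
        rng.choice(list(_DEVICE_MIX), p=np.array(list(_DEVICE_MIX.values())))
    )
    if owned == "both":
        first = "keyboard" if rng.random() < 0.5 else "touchscreen"
        second = "touchscreen" if first == "keyboard" else "keyboard"
        if config.second_session_for_both_owners:
            return [first, second]
        return [first]
    return [owned]


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a full synthetic cohort.

    Returns ``(respondents, trials, environment)`` DataFrames matching the
    interchange schemas of :mod:`speedcog.io`.  Both-device owners complete
    each test twice (sessions 1 and 2, one per device, random order);
    single-device owners complete one session.  Fully reproducible from
    ``config.seed``.
    """
    resp_rows: list[dict] = []
    env_rows: list[dict] = []
    trial_cols: dict[str, list] = {
        "respondent_id": [],
        "test": [],
        "session_index": [],
        "device_type": [],
        "trial_index": [],
        "trial_type": [],
        "item_id": [],
        "block_id": [],
        "latency_ms": [],
        "correct": [],
    }
    baselines = np.array(
        [config.trial_type_baselines[t] for t in _SGST_SEQUENCE]
    )
    item_base = np.asarray(config.figid_item_baselines)
    # default item->block layout: items are ordered by difficulty, so a
    # modulo assignment puts one item of each rank group in every block
    item_block = np.arange(FIGID_N_ITEMS) % FIGID_N_BLOCKS + 1

    for i in range(config.n_respondents):
        rng = _respondent_rng(config.seed, i)
        rid = f"R{i + 1:06d}"
        age, edu, sex, race, income, raw_w = _draw_demographics(rng, config)
        if config.balanced_device_assignment:
            devices = ["keyboard" if i % 2 == 0 else "touchscreen"]
        else:
            devices = _session_devices(rng, config)
        careless = rng.random() < config.careless_fraction
        u_i = rng.normal(0.0, config.sigma_person)
        p_correct = (
            config.p_correct_careless if careless else config.p_correct_attentive
        )
        person_shift = (
            u_i
            + config.beta_age * (age - 50)
            + (math.log(config.careless_latency_factor) if careless else 0.0)
        )
        resp_rows.append(
            {
                "respondent_id": rid,
                "age": age,
                "sex": sex,
                "race": race,
                "education": edu,
                "income": income,
                "weight": raw_w,
                "devices_owned": "+".join(sorted(set(devices))),
            }
        )
        for test in config.tests:
            for s_idx, device in enumerate(devices, start=1):
                env = {
                    name: int(rng.random() < p)
                    for name, p in config.env_prevalence.items()
                }
                env_rows.append(
                    {
                        "respondent_id": rid,
                        "test": test,
                        "session_index": s_idx,
                        **env,
                    }
                )
                shift = (
                    person_shift
                    + (config.delta_device if device == "touchscreen" else 0.0)
                    + (config.delta_interrupt if env["interrupted"] else 0.0)
                )
                if test == "SGST":
                    n = len(_SGST_SEQUENCE)
                    log_lat = baselines + shift + rng.normal(0, config.sigma_trial, n)
                    latency_ms = np.exp(log_lat) * _MS_PER_S
                    trial_cols["trial_type"].append(np.array(_SGST_SEQUENCE))
                    trial_cols["item_id"].append(np.full(n, "", dtype=object))
                    trial_cols["block_id"].append(np.full(n, "", dtype=object))
                else:
                    block_order = rng.permutation(FIGID_N_BLOCKS) + 1
                    order = np.concatenate(
                        [np.where(item_block == b)[0] for b in block_order]
                    )
                    n = FIGID_N_ITEMS
                    log_lat = (
                        item_base[order] + shift + rng.normal(0, config.sigma_trial, n)
                    )
                    latency_ms = np.exp(log_lat) * _MS_PER_S
                    is_out = rng.random(n) < config.p_outlier
                    if is_out.any():
                        latency_ms[is_out] = (
                            rng.uniform(*config.outlier_range_s, is_out.sum())
                            * _MS_PER_S
                        )
                    trial_cols["trial_type"].append(np.full(n, "", dtype=object))
                    trial_cols["item_id"].append(order + 1)
                    trial_cols["block_id"].append(item_block[order])
                correct = rng.random(n) < p_correct
                trial_cols["respondent_id"].append(np.full(n, rid))
                trial_cols["test"].append(np.full(n, test))
                trial_cols["session_index"].append(np.full(n, s_idx))
                trial_cols["device_type"].append(np.full(n, device))
                trial_cols["trial_index"].append(np.arange(1, n + 1))
                trial_cols["latency_ms"].append(np.round(latency_ms, 1))
                trial_cols["correct"].append(correct.astype(int))

    respondents = pd.DataFrame(resp_rows)
    respondents["weight"] = (
        respondents["weight"] / respondents["weight"].mean()
    )
    trials = pd.DataFrame(
        {name: np.concatenate(parts) for name, parts in trial_cols.items()}
    )
    environment = pd.DataFrame(env_rows)
    return respondents, trials, environment


def generate_item_bank(
    config: SimConfig, seed: int | None = None, n_pilot: int = 900
) -> list[ItemStats]:
    """Derive per-item median/IQR statistics from a simulated pilot study.

    ``n_pilot`` attentive respondents each answer all 60 items under the
    cohort's generative law; the returned median and IQR (seconds) per item
    are the difficulty/discrimination proxies consumed by the block
    balancing randomization.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, n_pilot)
    u = rng.normal(0.0, config.sigma_person, n_pilot)
    shift = (u + config.beta_age * (ages - 50))[:, None]
    log_lat = (
        np.asarray(config.figid_item_baselines)[None, :]
        + shift
        + rng.normal(0.0, config.sigma_trial, (n_pilot, FIGID_N_ITEMS))
    )
    lat = np.exp(log_lat)
    med = np.median(lat, axis=0)
    iqr = np.percentile(lat, 75, axis=0) - np.percentile(lat, 25, axis=0)
    return [
        ItemStats(item_id=i + 1, median_rt=float(med[i]), iqr_rt=float(iqr[i]))
        for i in range(FIGID_N_ITEMS)
    ]


def expected_exclusion_probability(config: SimConfig, n_trials: int) -> float:
    """Analytic probability that a random respondent fails the 70% filter.

    Mixture of binomial tails: careless respondents answer each of
    ``n_trials`` items correctly with probability ``p_correct_careless``,
    attentive ones with ``p_correct_attentive``; a session is excluded when
    the correct count falls below ``ceil(0.7 * n_trials)``.
    """
    from scipy.stats import binom

    threshold = math.ceil(0.70 * n_trials)  # minimum correct count to pass
    p_fail_careless = binom.cdf(threshold - 1, n_trials, config.p_correct_careless)
    p_fail_attentive = binom.cdf(threshold - 1, n_trials, config.p_correct_attentive)
    cf = config.careless_fraction
    return float(cf * p_fail_careless + (1 - cf) * p_fail_attentive)


def age_band_of(age: int) -> str:
    """Age-band label used for weighting, identical to the norm groups."""
    return age_group_label(age)
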