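"""Core domain types for trial-level response logs and derived scores.

Two web-administered speeded tests are modelled:

* **SGST** (Stop and Go Switching Task): an executive-functioning task with
  10 normal-baseline, 10 reverse-baseline, 23 nonswitch, and 6 switch trials
  per session (49 scorable trials).
* **FIGID** (Figure Identification): a perceptual-speed matching test with
  60 items administered in 6 blocks of 10.

A *trial* is one stimulus-response event with a latency in milliseconds and
a correctness flag.  A *session* is one complete administration of one test
by one respondent on one device.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Test(str, enum.Enum):
    """Which cognitive test a record belongs to."""

    SGST = "SGST"
    FIGID = "FIGID"


class DeviceType(str, enum.Enum):
    """Device class used for a session: physical keyboard+mouse or touch screen."""

    KEYBOARD = "keyboard"
    TOUCHSCREEN = "touchscreen"


class TrialType(str, enum.Enum):
    """SGST trial conditions.

    ``normal``/``reverse`` are single-rule baseline blocks; ``switch`` and
    ``nonswitch`` are trials of the mixed block, split by whether the rule
    changed on the immediately preceding trial.
    """

    NORMAL = "normal"
    REVERSE = "reverse"
    NONSWITCH = "nonswitch"
    SWITCH = "switch"


#: Required per-session trial counts for an SGST session, by trial type.
SGST_TRIAL_INVENTORY: dict[TrialType, int] = {
    TrialType.NORMAL: 10,
    TrialType.REVERSE: 10,
    TrialType.NONSWITCH: 23,
    TrialType.SWITCH: 6,
}

#: Total scorable SGST trials per session.
SGST_N_TRIALS: int = sum(SGST_TRIAL_INVENTORY.values())  # 49

#: Figure-identification inventory: 60 items, 6 blocks, 10 items per block.
FIGID_N_ITEMS: int = 60
FIGID_N_BLOCKS: int = 6
FIGID_ITEMS_PER_BLOCK: int = 10

#: Accuracy threshold below which a session is not scored (careless filter).
ACCURACY_THRESHOLD: float = 0.70

#: Lower edges of the six age groups used for norms: 18-34, 35-44, 45-54,
#: 55-64, 65-74, >=75.
AGE_GROUP_EDGES: tuple[int, ...] = (18, 35, 45, 55, 65, 75)


def age_group_label(age: float, edges: tuple[int, ...] = AGE_GROUP_EDGES) -> str:
    """Map an age in years to its norm age-group label, e.g. ``'45-54'``."""
    if age < edges[0]:
        raise ValueError(f"age {age} below the youngest group ({edges[0]})")
    for lo, hi in zip(edges[:-1], edges[1:]):
        if age < hi:
            return f"{lo}-{hi - 1}"
    return f">={edges[-1]}"


class SpeedcogError(Exception):
    """Base class for all package errors."""


class IntegrityError(SpeedcogError):
    """Input data violate a structural invariant (duplicates, mixed sessions...)."""


class FormatError(SpeedcogError):
    """A file does not match the documented schema."""


class ConfigurationError(SpeedcogError):
    """A configuration value is out of its admissible range."""


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus-response event.

    Exactly one of ``trial_type`` (SGST) / ``item_id`` (FIGID) is set,
    matching ``test``.  ``trial_index`` is 1-based administration order
    within the session.
    """

    respondent_id: str
    test: Test
    session_index: int
    device_type: DeviceType
    trial_index: int
    latency_ms: float
    correct: bool
    trial_type: TrialType | None = None
    item_id: int | None = None
    block_id: int | None = None

    def __post_init__(self) -> None:
        if self.latency_ms <= 0:
            raise IntegrityError(
                f"latency_ms must be positive, got {self.latency_ms!r} "
                f"(respondent {self.respondent_id}, trial {self.trial_index})"
            )
        if self.session_index < 1 or self.trial_index < 1:
            raise IntegrityError("session_index and trial_index are 1-based")
        if self.test is Test.SGST:
            if self.trial_type is None or self.item_id is not None:
                raise IntegrityError("SGST trials carry trial_type and no item_id")
        else:
            if self.item_id is None or self.trial_type is not None:
                raise IntegrityError("FIGID trials carry item_id and no trial_type")
            if not 1 <= self.item_id <= FIGID_N_ITEMS:
                raise IntegrityError(f"item_id out of range 1-60: {self.item_id}")
            if self.block_id is not None and not 1 <= self.block_id <= FIGID_N_BLOCKS:
                raise IntegrityError(f"block_id out of range 1-6: {self.block_id}")


@dataclass(frozen=True)
class RespondentProfile:
    """Demographics and survey weight for one panel member."""

    respondent_id: str
    age: int
    sex: str
    race: str
    education: str
    income: str
    weight: float
    devices_owned: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise IntegrityError(f"negative sampling weight: {self.weight}")
        if not 18 <= self.age <= 102:
            raise IntegrityError(f"age out of declared bounds 18-102: {self.age}")


#: Binary distraction fields collected right after each test session.
ENVIRONMENT_FIELDS: tuple[str, ...] = (
    "interrupted",
    "at_home",
    "watching_tv",
    "listening_music",
    "talking",
    "texting_email",
    "internet_content",
    "playing_game",
)


@dataclass(frozen=True)
class EnvironmentReport:
    """Post-session self-report of location and momentary distractions (0/1 each)."""

    respondent_id: str
    test: Test
    session_index: int
    interrupted: int
    at_home: int
    watching_tv: int
    listening_music: int
    talking: int
    texting_email: int
    internet_content: int
    playing_game: int

    def __post_init__(self) -> None:
        for name in ENVIRONMENT_FIELDS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise IntegrityError(f"environment field {name} must be 0/1, got {v!r}")


@dataclass(frozen=True)
class SGSTScore:
    """Person-level SGST outcome: four median latencies (seconds) plus validity.

    ``scored`` is True iff accuracy over all 49 trials is >= 0.70; medians are
    None for unscored sessions.
    """

    respondent_id: str
    session_index: int
    device_type: DeviceType
    accuracy: float
    scored: bool
    median_normal_s: float | None = None
    median_reverse_s: float | None = None
    median_nonswitch_s: float | None = None
    median_switch_s: float | None = None


@dataclass(frozen=True)
class FigIDScore:
    """Person-level figure-identification outcome.

    ``score`` is the number of figures answered correctly within the
    posterior time limit (0-60).  Secondary measures ignore the limit:
    ``pct_incorrect`` and ``median_rt_correct_s`` are computed over all
    non-outlier figures.
    """

    respondent_id: str
    session_index: int
    device_type: DeviceType
    score: int
    accuracy: float
    pct_incorrect: float
    median_rt_correct_s: float | None
    n_outliers_removed: int
    scored: bool


@dataclass(frozen=True)
class ScoringLimits:
    """Constants of the figure-identification scoring rule."""

    set_limit_s: float = 90.0
    n_sets: int = 2
    outlier_cut_s: float = 30.0

    def __post_init__(self) -> None:
        if self.set_limit_s <= 0 or self.n_sets <= 0 or self.outlier_cut_s <= 0:
            raise ConfigurationError("scoring limits must be positive")


@dataclass(frozen=True)
class ItemStats:
    """Pilot-derived difficulty proxies for one figure item."""

    item_id: int
    median_rt: float
    iqr_rt: float

    def __post_init__(self) -> None:
        if self.median_rt <= 0 or self.iqr_rt < 0:
            raise IntegrityError("median_rt must be > 0 and iqr_rt >= 0")


@dataclass(frozen=True)
class BlockAssignment:
    """A balanced mapping of the 60 items onto 6 blocks.

    ``mapping`` sends item_id -> block_id; each consecutive rank-group of six
    items (ranked by pilot median) contributes exactly one item per block.
    """

    mapping: dict[int, int]
    objective_value: float
    chosen_iteration: int


@dataclass(frozen=True)
class SessionValidation:
    """Result of structural validation of a single session."""

    respondent_id: str
    test: Test
    session_index: int
    valid: bool
    problems: tuple[str, ...] = field(default_factory=tuple)
    n_trials: int = 0
    n_long_latency: int = 0  # latencies > 30 s, flagged but never removed here
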