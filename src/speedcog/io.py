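"""Reading, writing, and validating trial logs and respondent tables.

Interchange formats are deliberately plain: UTF-8 delimited text (CSV) or
JSON-Lines, one row per trial, dot decimal separator.  Latencies are stored
in milliseconds; conversion to seconds happens exactly once, inside scoring.

Column schemas
--------------
trial log    : respondent_id,test,session_index,device_type,trial_index,
               trial_type,item_id,block_id,latency_ms,correct
respondents  : respondent_id,age,sex,race,education,income,weight,devices_owned
environment  : respondent_id,test,session_index,interrupted,at_home,
               watching_tv,listening_music,talking,texting_email,
               internet_content,playing_game

Row order in a trial log is administration order and must agree with the
1-based ``trial_index`` within each session.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd

from .records import (
    ENVIRONMENT_FIELDS,
    FIGID_ITEMS_PER_BLOCK,
    FIGID_N_BLOCKS,
    FIGID_N_ITEMS,
    SGST_TRIAL_INVENTORY,
    DeviceType,
    FormatError,
    IntegrityError,
    SessionValidation,
    Test,
    TrialRecord,
    TrialType,
)

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "respondent_id",
    "test",
    "session_index",
    "device_type",
    "trial_index",
    "trial_type",
    "item_id",
    "block_id",
    "latency_ms",
    "correct",
]

RESPONDENT_COLUMNS = [
    "respondent_id",
    "age",
    "sex",
    "race",
    "education",
    "income",
    "weight",
    "devices_owned",
]

ENVIRONMENT_COLUMNS = ["respondent_id", "test", "session_index", *ENVIRONMENT_FIELDS]

#: Latencies above this are flagged by validation (never removed there).
LONG_LATENCY_FLAG_MS = 30_000.0

_SESSION_KEY = ["respondent_id", "test", "session_index"]


def trials_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Convert TrialRecord objects to a DataFrame in the canonical column order."""
    rows = [
        {
            "respondent_id": r.respondent_id,
            "test": r.test.value,
            "session_index": r.session_index,
            "device_type": r.device_type.value,
            "trial_index": r.trial_index,
            "trial_type": r.trial_type.value if r.trial_type else "",
            "item_id": r.item_id if r.item_id is not None else "",
            "block_id": r.block_id if r.block_id is not None else "",
            "latency_ms": r.latency_ms,
            "correct": int(r.correct),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    """Convert a trial-log DataFrame to validated TrialRecord objects.

    Raises IntegrityError if any row violates a record invariant and
    FormatError on missing columns.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"trial log missing columns: {missing}")
    records = []
    for row in frame.itertuples(index=False):
        trial_type = getattr(row, "trial_type", "")
        item_id = getattr(row, "item_id", "")
        block_id = getattr(row, "block_id", "")
        records.append(
            TrialRecord(
                respondent_id=str(row.respondent_id),
                test=Test(row.test),
                session_index=int(row.session_index),
                device_type=DeviceType(row.device_type),
                trial_index=int(row.trial_index),
                trial_type=TrialType(trial_type) if _present(trial_type) else None,
                item_id=int(item_id) if _present(item_id) else None,
                block_id=int(block_id) if _present(block_id) else None,
                latency_ms=float(row.latency_ms),
                correct=_parse_bool(row.correct),
            )
        )
    return records


def _present(value) -> bool:
    return value is not None and value == value and str(value) != ""


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("1", "true"):
        return True
    if s in ("0", "false"):
        return False
    raise IntegrityError(f"correct field is not boolean: {value!r}")


def _check_no_duplicates(frame: pd.DataFrame) -> None:
    dup = frame.duplicated(subset=[*_SESSION_KEY, "trial_index"])
    if dup.any():
        first = frame.loc[dup].iloc[0]
        raise IntegrityError(
            "duplicate trial_index within session: respondent "
            f"{first['respondent_id']}, test {first['test']}, "
            f"session {first['session_index']}, trial {first['trial_index']}"
        )


def read_trial_log(path: str | Path, test: Test | None = None) -> list[TrialRecord]:
    """Read a trial log (CSV or JSON-Lines by extension) into TrialRecord objects.

    Parameters
    ----------
    path
        Input file; ``.jsonl`` selects JSON-Lines, anything else is read as CSV.
    test
        If given, restrict to rows of this test and error on any other.

    Administration order (row order) is preserved.  Malformed rows raise
    FormatError naming the line; duplicate trial indices within a session and
    invariant violations raise IntegrityError.
    """
    path = Path(path)
    if path.suffix == ".jsonl":
        frame = _read_jsonl(path)
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        header = list(frame.columns)
        if header != TRIAL_COLUMNS:
            raise FormatError(
                f"unexpected trial-log header {header}; expected {TRIAL_COLUMNS}"
            )
    if frame.empty:
        return []
    if test is not None:
        bad = frame.loc[frame["test"] != test.value]
        if len(bad):
            raise IntegrityError(
                f"trial log contains {len(bad)} rows for other tests than {test.value}"
            )
    try:
        records = frame_to_trials(frame)
    except (ValueError, KeyError) as exc:
        raise FormatError(f"malformed trial log {path}: {exc}") from exc
    _check_no_duplicates(trials_to_frame(records))
    logger.info("read %d trials from %s", len(records), path)
    return records


def _read_jsonl(path: Path) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
    frame = pd.DataFrame(rows)
    if rows and list(frame.columns) != TRIAL_COLUMNS:
        missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"{path}: JSONL rows missing keys {missing}")
        frame = frame[TRIAL_COLUMNS]
    elif not rows:
        frame = pd.DataFrame(columns=TRIAL_COLUMNS)
    return frame


def write_trial_log(
    records: Sequence[TrialRecord] | pd.DataFrame,
    path: str | Path,
    validate_counts: bool = True,
) -> Path:
    """Write trials to ``path`` (CSV or ``.jsonl``), sorted by session key.

    Rows are ordered deterministically by (respondent_id, test, session_index,
    trial_index).  With ``validate_counts`` (default), every complete session
    must match its test's trial inventory; violations raise IntegrityError
    before anything is written.
    """
    frame = records if isinstance(records, pd.DataFrame) else trials_to_frame(records)
    frame = frame.reindex(columns=TRIAL_COLUMNS)
    _check_no_duplicates(frame)
    frame = frame.sort_values([*_SESSION_KEY, "trial_index"], kind="mergesort")
    if validate_counts:
        for key, group in frame.groupby(_SESSION_KEY, sort=False):
            report = validate_session(group)
            if not report.valid:
                raise IntegrityError(
                    f"session {key} fails validation: {'; '.join(report.problems)}"
                )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for row in frame.to_dict(orient="records"):
                fh.write(json.dumps(row) + "\n")
    else:
        frame.to_csv(path, index=False)
    logger.info("wrote %d trials to %s", len(frame), path)
    return path


def validate_session(
    session: pd.DataFrame | Sequence[TrialRecord],
) -> SessionValidation:
    """Structurally validate the trials of one (respondent, test, session).

    Checks the fixed trial inventory (10/10/23/6 for SGST; 60 items, 10 per
    block for the figure test), duplicate or non-contiguous trial indices,
    and flags — without removing — latencies above 30 s.  Mixing tests or
    respondents in one session raises IntegrityError.
    """
    frame = (
        session
        if isinstance(session, pd.DataFrame)
        else trials_to_frame(list(session))
    )
    if frame.empty:
        raise IntegrityError("cannot validate an empty session")
    for col in _SESSION_KEY:
        if frame[col].nunique() != 1:
            raise IntegrityError(f"session mixes multiple values of {col}")
    test = Test(frame["test"].iloc[0])
    problems: list[str] = []

    idx = frame["trial_index"].astype(int).to_numpy()
    if len(set(idx)) != len(idx):
        problems.append("duplicate trial_index values")
    elif list(idx) != list(range(1, len(idx) + 1)):
        problems.append("trial_index not contiguous 1..n in administration order")

    if test is Test.SGST:
        counts = frame["trial_type"].astype(str).value_counts()
        for ttype, expected in SGST_TRIAL_INVENTORY.items():
            got = int(counts.get(ttype.value, 0))
            if got != expected:
                problems.append(f"{ttype.value}: {got} trials, expected {expected}")
    else:
        items = pd.to_numeric(frame["item_id"], errors="coerce")
        if items.isna().any():
            problems.append("FIGID trials with missing item_id")
        else:
            if len(frame) != FIGID_N_ITEMS:
                problems.append(f"{len(frame)} item trials, expected {FIGID_N_ITEMS}")
            if items.nunique() != len(items):
                problems.append("repeated item_id within session")
            missing = set(range(1, FIGID_N_ITEMS + 1)) - set(items.astype(int))
            if missing and len(frame) != FIGID_N_ITEMS:
                problems.append(f"missing items: {sorted(missing)[:5]}...")
            elif missing:
                problems.append(f"missing items: {sorted(missing)}")
        blocks = pd.to_numeric(frame["block_id"], errors="coerce")
        if not blocks.isna().any():
            bc = blocks.astype(int).value_counts()
            if len(bc) != FIGID_N_BLOCKS or (bc != FIGID_ITEMS_PER_BLOCK).any():
                problems.append("block sizes differ from 10 items x 6 blocks")

    lat = pd.to_numeric(frame["latency_ms"], errors="coerce")
    if (lat <= 0).any() or lat.isna().any():
        problems.append("non-positive or missing latency_ms")
    n_long = int((lat > LONG_LATENCY_FLAG_MS).sum())

    return SessionValidation(
        respondent_id=str(frame["respondent_id"].iloc[0]),
        test=test,
        session_index=int(frame["session_index"].iloc[0]),
        valid=not problems,
        problems=tuple(problems),
        n_trials=len(frame),
        n_long_latency=n_long,
    )


def read_respondents(path: str | Path) -> pd.DataFrame:
    """Read the respondent table; age and weight are coerced to numbers."""
    frame = pd.read_csv(path, dtype={"respondent_id": str})
    missing = [c for c in RESPONDENT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"respondent table missing columns: {missing}")
    frame["age"] = frame["age"].astype(int)
    frame["weight"] = frame["weight"].astype(float)
    if (frame["weight"] < 0).any():
        raise IntegrityError("negative sampling weights in respondent table")
    return frame


def write_respondents(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.reindex(columns=RESPONDENT_COLUMNS).sort_values("respondent_id").to_csv(
        path, index=False
    )
    return path


def read_environment(path: str | Path) -> pd.DataFrame:
    """Read the post-session environment table; all report fields must be 0/1."""
    frame = pd.read_csv(path, dtype={"respondent_id": str})
    missing = [c for c in ENVIRONMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"environment table missing columns: {missing}")
    for col in ENVIRONMENT_FIELDS:
        if not frame[col].isin([0, 1]).all():
            raise IntegrityError(f"environment field {col} contains non-binary values")
    if frame.duplicated(subset=_SESSION_KEY).any():
        raise IntegrityError("duplicate (respondent, test, session) environment rows")
    return frame


def write_environment(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.reindex(columns=ENVIRONMENT_COLUMNS).sort_values(_SESSION_KEY).to_csv(
        path, index=False
    )
    return path
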