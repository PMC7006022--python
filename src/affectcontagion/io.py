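"""CSV reading and writing for rating datasets.

Two dialects are supported (RFC 4180, UTF-8, ``.`` decimal separator):

``long`` (canonical)
    One row per rating event.  Columns: ``participant_id, group, gender,
    age, event_type, face_id, valence, negativity, positivity, arousal,
    order, ecs, iri, bes, qpc``.  ``event_type`` is ``video`` (exactly one
    row per participant; carries the questionnaire totals) or ``face``.

``wide``
    One row per participant: ``participant_id, group, gender, age,
    video_<dim>`` followed, for each design cell ``happy01``..``angry10``,
    by ``<cell>_face_id, <cell>_negativity, <cell>_positivity,
    <cell>_arousal, <cell>_order``, then the questionnaire columns.

Both files start with a schema comment line (``# affectcontagion-ratings
...``); readers skip ``#`` lines.  Writing is deterministic (rows sorted by
participant_id, then presentation order) and lossless: floats are written
with ``repr`` so that read(write(dataset)) reproduces every field exactly.
Unparseable or out-of-range cells raise errors naming the offending
participant, trial and field -- they are never silently clamped.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import pandas as pd

from .datamodel import (
    GROUPS,
    QUESTIONNAIRES,
    TRIALS_PER_VALENCE,
    VALENCES,
    AffectCoordinate,
    DataError,
    DuplicateParticipantError,
    FaceTrial,
    Participant,
    RatingRangeError,
    SchemaError,
    StudyDataset,
    hard_violations,
    validate_dataset,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
DIALECTS = ("long", "wide")

_DIMS = ("negativity", "positivity", "arousal")
_Q_COLS = {q.lower(): q for q in QUESTIONNAIRES}  # csv column -> instrument key

LONG_COLUMNS = [
    "participant_id", "group", "gender", "age", "event_type", "face_id",
    "valence", "negativity", "positivity", "arousal", "order",
    *_Q_COLS,
]
_LONG_REQUIRED = [
    "participant_id", "group", "event_type", "face_id", "valence",
    "negativity", "positivity", "arousal",
]

_WIDE_CELLS = [f"{v}{i:02d}" for v in VALENCES for i in range(1, TRIALS_PER_VALENCE + 1)]
WIDE_COLUMNS = (
    ["participant_id", "group", "gender", "age"]
    + [f"video_{d}" for d in _DIMS]
    + [
        f"{cell}_{suffix}"
        for cell in _WIDE_CELLS
        for suffix in ("face_id", *_DIMS, "order")
    ]
    + list(_Q_COLS)
)
_WIDE_REQUIRED = (
    ["participant_id", "group"]
    + [f"video_{d}" for d in _DIMS]
    + [f"{cell}_{d}" for cell in _WIDE_CELLS for d in _DIMS]
)

#: Default mapping from common input group labels to the canonical ones.
DEFAULT_GROUP_MAP = {
    "negative_induction": "negative_induction",
    "positive_induction": "positive_induction",
    "negative": "negative_induction",
    "positive": "positive_induction",
    "neg": "negative_induction",
    "pos": "positive_induction",
}


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _comment_line(dialect: str) -> str:
    return f"# affectcontagion-ratings schema v{SCHEMA_VERSION} dialect={dialect}"


def _parse_rating(raw: object, field: str, context: str) -> float | None:
    """Parse one rating cell; '' -> None (missing); bad values raise."""
    if raw is None:
        return None
    text = str(raw).strip()
    if text == "" or text.lower() == "nan":
        return None
    try:
        value = float(text)
    except ValueError:
        raise RatingRangeError(
            f"unparseable rating '{field}' ({context}): {text!r}"
        ) from None
    if not (0.0 <= value <= 100.0):
        raise RatingRangeError(
            f"rating '{field}' ({context}) outside [0, 100]: {value!r}"
        )
    return value


def _parse_optional_float(raw: object) -> float | None:
    if raw is None:
        return None
    text = str(raw).strip()
    if text == "" or text.lower() == "nan":
        return None
    return float(text)


def _parse_optional_str(raw: object) -> str | None:
    if raw is None:
        return None
    text = str(raw).strip()
    return text or None


def _map_group(label: str, group_map: dict[str, str], context: str) -> str:
    mapped = group_map.get(str(label).strip())
    if mapped not in GROUPS:
        raise SchemaError(
            f"unknown induction group label {label!r} ({context}); "
            f"provide a group_map entry targeting one of {GROUPS}"
        )
    return mapped


def _coordinate(
    row: dict, fields: tuple[str, str, str], context: str
) -> AffectCoordinate | None:
    """Build a coordinate from three cells; None if any dimension is missing."""
    values = [_parse_rating(row.get(f), f, context) for f in fields]
    if any(v is None for v in values):
        return None
    return AffectCoordinate(*values)  # type: ignore[arg-type]


def _questionnaires(row: dict) -> dict[str, float]:
    out: dict[str, float] = {}
    for col, key in _Q_COLS.items():
        value = _parse_optional_float(row.get(col))
        if value is not None:
            out[key] = value
    return out


def read_ratings_csv(
    path: str | Path,
    dialect: str = "long",
    group_map: dict[str, str] | None = None,
) -> StudyDataset:
    """Read a ratings CSV into a :class:`StudyDataset`.

    Parameters
    ----------
    path
        CSV file in one of the documented dialects.
    dialect
        ``"long"`` or ``"wide"``.
    group_map
        Mapping from input group labels to the canonical
        ``negative_induction`` / ``positive_induction`` labels; defaults to
        :data:`DEFAULT_GROUP_MAP`.

    Raises
    ------
    SchemaError
        Missing required column, unknown group label, or a participant
        without exactly one video rating.
    RatingRangeError
        A rating cell that is unparseable or outside [0, 100]; the message
        names the participant, trial and field.
    DuplicateParticipantError
        The same participant_id occurs twice.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(f"ratings file not found: {path}")
    group_map = dict(DEFAULT_GROUP_MAP if group_map is None else group_map)

    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    required = _LONG_REQUIRED if dialect == "long" else _WIDE_REQUIRED
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    rows = frame.to_dict(orient="records")
    if dialect == "long":
        dataset = _read_long(rows, group_map)
    else:
        dataset = _read_wide(rows, group_map)
    dataset.metadata.update(
        {"source": str(path), "dialect": dialect, "schema_version": SCHEMA_VERSION}
    )
    return dataset


def _read_long(rows: list[dict], group_map: dict[str, str]) -> StudyDataset:
    order_seen: list[str] = []
    by_pid: dict[str, list[dict]] = {}
    for row in rows:
        pid = str(row["participant_id"]).strip()
        if pid not in by_pid:
            by_pid[pid] = []
            order_seen.append(pid)
        by_pid[pid].append(row)

    participants: list[Participant] = []
    for pid in order_seen:
        prows = by_pid[pid]
        video_rows = [r for r in prows if str(r["event_type"]).strip() == "video"]
        face_rows = [r for r in prows if str(r["event_type"]).strip() == "face"]
        if len(video_rows) != 1:
            raise SchemaError(
                f"participant {pid!r} must have exactly one video row, "
                f"found {len(video_rows)}"
            )
        vrow = video_rows[0]
        video = _coordinate(vrow, _DIMS, f"participant {pid}, video")
        if video is None:
            raise SchemaError(f"participant {pid!r}: video rating incomplete")

        trials: list[FaceTrial] = []
        for row in face_rows:
            face_id = str(row.get("face_id", "")).strip()
            context = f"participant {pid}, face {face_id!r}"
            judgment = _coordinate(row, _DIMS, context)
            if judgment is None:
                logger.warning("%s: incomplete trial excluded", context)
                continue
            order = _parse_optional_float(row.get("order"))
            trials.append(
                FaceTrial(
                    face_id=face_id,
                    valence=str(row["valence"]).strip(),
                    judgment=judgment,
                    presentation_order=None if order is None else int(order),
                )
            )
        participants.append(
            Participant(
                participant_id=pid,
                group=_map_group(vrow["group"], group_map, f"participant {pid}"),
                video_rating=video,
                trials=trials,
                gender=_parse_optional_str(vrow.get("gender")),
                age=_parse_optional_float(vrow.get("age")),
                questionnaires=_questionnaires(vrow),
            )
        )
    _check_unique(participants)
    return StudyDataset(participants=participants)


def _read_wide(rows: list[dict], group_map: dict[str, str]) -> StudyDataset:
    participants: list[Participant] = []
    for row in rows:
        pid = str(row["participant_id"]).strip()
        video = _coordinate(
            row, tuple(f"video_{d}" for d in _DIMS), f"participant {pid}, video"
        )
        if video is None:
            raise SchemaError(f"participant {pid!r}: video rating incomplete")
        trials: list[FaceTrial] = []
        for cell in _WIDE_CELLS:
            context = f"participant {pid}, cell {cell}"
            judgment = _coordinate(
                row, tuple(f"{cell}_{d}" for d in _DIMS), context
            )
            if judgment is None:
                logger.warning("%s: incomplete trial excluded", context)
                continue
            face_id = _parse_optional_str(row.get(f"{cell}_face_id")) or cell
            order = _parse_optional_float(row.get(f"{cell}_order"))
            trials.append(
                FaceTrial(
                    face_id=face_id,
                    valence=cell[:-2],
                    judgment=judgment,
                    presentation_order=None if order is None else int(order),
                )
            )
        trials.sort(
            key=lambda t: (t.presentation_order is None, t.presentation_order)
        )
        participants.append(
            Participant(
                participant_id=pid,
                group=_map_group(row["group"], group_map, f"participant {pid}"),
                video_rating=video,
                trials=trials,
                gender=_parse_optional_str(row.get("gender")),
                age=_parse_optional_float(row.get("age")),
                questionnaires=_questionnaires(row),
            )
        )
    _check_unique(participants)
    return StudyDataset(participants=participants)


def _check_unique(participants: list[Participant]) -> None:
    seen: set[str] = set()
    for p in participants:
        if p.participant_id in seen:
            raise DuplicateParticipantError(
                f"duplicate participant_id {p.participant_id!r}"
            )
        seen.add(p.participant_id)


def write_ratings_csv(
    dataset: StudyDataset,
    path: str | Path,
    dialect: str = "long",
    validate: bool = True,
) -> Path:
    """Write a dataset to CSV; returns the path written.

    Rows are ordered by participant_id (lexicographic), and trials by
    presentation order, so identical datasets always produce identical
    bytes.  With ``validate=True`` (default) the dataset must carry no hard
    validation violations.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    if validate:
        hard = hard_violations(validate_dataset(dataset))
        if hard:
            details = "; ".join(f"{v.participant_id}: {v.message}" for v in hard[:5])
            raise DataError(
                f"dataset has {len(hard)} hard validation violation(s): {details}"
            )

    participants = sorted(dataset.participants, key=lambda p: p.participant_id)
    columns = LONG_COLUMNS if dialect == "long" else WIDE_COLUMNS
    with open(path, "w", newline="", encoding="utf-8") as handle:
        handle.write(_comment_line(dialect) + "\n")
        writer = csv.writer(handle)
        writer.writerow(columns)
        for p in participants:
            if dialect == "long":
                _write_long_rows(writer, p)
            else:
                _write_wide_row(writer, p)
    return path


def _sorted_trials(p: Participant) -> list[FaceTrial]:
    return sorted(
        p.trials,
        key=lambda t: (t.presentation_order is None, t.presentation_order, t.face_id),
    )


def _write_long_rows(writer, p: Participant) -> None:
    q = [_fmt(p.questionnaires.get(key)) for key in QUESTIONNAIRES]
    writer.writerow(
        [p.participant_id, p.group, _fmt(p.gender), _fmt(p.age), "video", "", ""]
        + [_fmt(getattr(p.video_rating, d)) for d in _DIMS]
        + [""]
        + q
    )
    for t in _sorted_trials(p):
        writer.writerow(
            [p.participant_id, p.group, _fmt(p.gender), _fmt(p.age), "face",
             t.face_id, t.valence]
            + [_fmt(getattr(t.judgment, d)) for d in _DIMS]
            + [_fmt(t.presentation_order)]
            + [""] * len(QUESTIONNAIRES)
        )


def _write_wide_row(writer, p: Participant) -> None:
    row = [p.participant_id, p.group, _fmt(p.gender), _fmt(p.age)]
    row += [_fmt(getattr(p.video_rating, d)) for d in _DIMS]
    by_cell: dict[str, FaceTrial] = {}
    for valence in VALENCES:
        in_valence = [t for t in _sorted_trials(p) if t.valence == valence]
        for i, t in enumerate(in_valence, start=1):
            by_cell[f"{valence}{i:02d}"] = t
    for cell in _WIDE_CELLS:
        t = by_cell.get(cell)
        if t is None:
            row += [""] * 5
        else:
            row += (
                [t.face_id]
                + [_fmt(getattr(t.judgment, d)) for d in _DIMS]
                + [_fmt(t.presentation_order)]
            )
    row += [_fmt(p.questionnaires.get(key)) for key in QUESTIONNAIRES]
    writer.writerow(row)
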