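"""Reading and writing colony tables, ROV tables, and JSON reports.

Tables are comma-separated UTF-8 files with a mandatory header row, decimal
points, lengths in mm and weights in g (no unit columns). Validation is
total: a malformed file raises a diagnosed error and never yields a
partially loaded table.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Any, List, Sequence, Union

import pandas as pd

from .errors import EmptyInputError, SchemaError, ValidationError
from .records import ColonyRecord, RovObservation

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

COLONY_COLUMNS = (
    "colony_id",
    "leaves_left",
    "leaves_right",
    "total_length_mm",
    "peduncle_length_mm",
    "fresh_weight_g",
)
COLONY_OPTIONAL_COLUMNS = ("dry_weight_g",)
ROV_COLUMNS = ("colony_id", "leaf_count")


def _read_csv(path: PathLike, required: Sequence[str], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{label} table not found: {path}")
    try:
        frame = pd.read_csv(path, dtype={"colony_id": str})
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{label} table {path} is empty (no header row)")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{label} table {path} is missing required column(s): "
            + ", ".join(missing)
        )
    if len(frame) == 0:
        raise EmptyInputError(f"{label} table {path} contains no data rows")
    return frame


def _warn_duplicates(ids: Sequence[str], label: str) -> None:
    seen: set = set()
    dupes = []
    for cid in ids:
        if cid in seen:
            dupes.append(cid)
        seen.add(cid)
    if dupes:
        # IDs are labels, not keys: duplicates warn but never fail.
        logger.warning("%s table contains duplicate colony_id(s): %s", label, dupes)


def _as_int(value: Any, row: int, column: str) -> int:
    number = float(value)
    if math.isnan(number):
        raise ValidationError(f"row {row}: {column} is missing")
    if number != int(number):
        raise ValidationError(
            f"row {row}: {column} must be an integer count, got {value!r}"
        )
    return int(number)


def read_colony_table(path: PathLike) -> List[ColonyRecord]:
    """Read a colony measurement CSV into validated :class:`ColonyRecord` rows.

    A blank ``dry_weight_g`` cell yields a record without a dry weight. Any
    invariant violation raises :class:`~seapen.errors.ValidationError` naming
    the row (1-based data rows) and the rule; the whole read fails.
    """
    frame = _read_csv(path, COLONY_COLUMNS, "colony")
    records: List[ColonyRecord] = []
    for index, row in enumerate(frame.itertuples(index=False), start=1):
        data = row._asdict()
        dry = data.get("dry_weight_g")
        dry_value = None
        if dry is not None and not (isinstance(dry, float) and math.isnan(dry)):
            dry_value = float(dry)
        try:
            records.append(
                ColonyRecord(
                    colony_id=str(data["colony_id"]),
                    leaves_left=_as_int(data["leaves_left"], index, "leaves_left"),
                    leaves_right=_as_int(data["leaves_right"], index, "leaves_right"),
                    total_length=float(data["total_length_mm"]),
                    peduncle_length=float(data["peduncle_length_mm"]),
                    fresh_weight=float(data["fresh_weight_g"]),
                    dry_weight=dry_value,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {index}: {exc}") from exc
    _warn_duplicates([r.colony_id for r in records], "colony")
    return records


def read_rov_table(path: PathLike) -> List[RovObservation]:
    """Read an ROV observation CSV into validated :class:`RovObservation` rows."""
    frame = _read_csv(path, ROV_COLUMNS, "ROV")
    observations: List[RovObservation] = []
    for index, row in enumerate(frame.itertuples(index=False), start=1):
        data = row._asdict()
        try:
            observations.append(
                RovObservation(
                    colony_id=str(data["colony_id"]),
                    leaf_count=_as_int(data["leaf_count"], index, "leaf_count"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {index}: {exc}") from exc
    _warn_duplicates([o.colony_id for o in observations], "ROV")
    return observations


def write_colony_table(records: Sequence[ColonyRecord], path: PathLike) -> None:
    """Write colony records back to the CSV layout read_colony_table accepts."""
    frame = pd.DataFrame(
        {
            "colony_id": [r.colony_id for r in records],
            "leaves_left": [r.leaves_left for r in records],
            "leaves_right": [r.leaves_right for r in records],
            "total_length_mm": [r.total_length for r in records],
            "peduncle_length_mm": [r.peduncle_length for r in records],
            "fresh_weight_g": [r.fresh_weight for r in records],
            "dry_weight_g": [r.dry_weight for r in records],
        }
    )
    frame.to_csv(path, index=False)


def write_rov_table(observations: Sequence[RovObservation], path: PathLike) -> None:
    frame = pd.DataFrame(
        {
            "colony_id": [o.colony_id for o in observations],
            "leaf_count": [o.leaf_count for o in observations],
        }
    )
    frame.to_csv(path, index=False)


def write_report(report: dict, path: PathLike) -> None:
    """Write a machine-readable JSON report.

    The report is a plain nested dict of numbers, strings and lists (see
    ``docs/report_schema.md``); serialisation uses sorted keys so identical
    reports are byte-identical on disk.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(dumps_report(report), encoding="utf-8")


def dumps_report(report: dict) -> str:
    """Serialise a report deterministically (sorted keys, repr-exact floats)."""
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=False) + "\n"


def read_report(path: PathLike) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
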