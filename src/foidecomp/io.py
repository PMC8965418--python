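"""CSV dialects for the four datasets and validated round-trip I/O.

All files are comma-separated UTF-8 with a required header row, one record per
row. The field survey is long format (one row per week x site x species).
Optional per-snail worm counts travel in a ``worm_counts`` column as a
semicolon-separated list (empty cell = not recorded).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, List, Mapping, Sequence, Union

import pandas as pd

from .records import (
    ContactTrial,
    FieldObservation,
    SentinelTrial,
    TransmissionReplicate,
)

__all__ = [
    "SchemaError",
    "ValidationError",
    "SCHEMAS",
    "read_table",
    "read_tables",
    "write_table",
    "records_to_frame",
]


class SchemaError(ValueError):
    """The file's header does not match the documented schema."""


class ValidationError(ValueError):
    """One or more rows violate a record invariant."""


_RECORD_TYPES = {
    "field_survey": FieldObservation,
    "sentinel_trials": SentinelTrial,
    "contact_trials": ContactTrial,
    "transmission": TransmissionReplicate,
}

_INT_FIELDS = {
    "week_index",
    "n_exposed",
    "n_infested",
    "trial_day",
    "alt_density",
    "n_focal",
    "worms_added",
    "on_donor",
    "on_receiver",
    "in_donor_cup",
    "in_experimental_cup",
    "in_receiver_cup",
}
_STR_FIELDS = {"site_id", "species", "trial_id", "container_id", "replicate_id", "treatment", "source"}

#: Column order of each CSV dialect, keyed by dataset kind.
SCHEMAS = {
    kind: [f.name for f in dataclasses.fields(rec)] for kind, rec in _RECORD_TYPES.items()
}


def _parse_worm_counts(cell) -> Union[None, List[int]]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return None
    return [int(tok) for tok in str(cell).split(";")]


def _coerce(kind: str, name: str, value):
    if name == "worm_counts":
        return _parse_worm_counts(value)
    if name in _STR_FIELDS:
        return str(value)
    if name in _INT_FIELDS:
        f = float(value)
        if f != int(f):
            raise ValueError(f"{name} must be an integer, got {value!r}")
        return int(f)
    return float(value)


def read_table(path: Union[str, Path], kind: str):
    """Read one CSV of the given dataset ``kind`` into validated records.

    Raises :class:`SchemaError` naming any missing column and
    :class:`ValidationError` with row-addressed messages for rows that violate
    a type invariant.
    """
    if kind not in SCHEMAS:
        raise KeyError(f"unknown dataset kind {kind!r}; expected one of {sorted(SCHEMAS)}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in SCHEMAS[kind] if c != "worm_counts"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for dataset kind {kind!r}")
    rec_type = _RECORD_TYPES[kind]
    columns = [c for c in SCHEMAS[kind] if c in df.columns]
    records, errors = [], []
    for idx, row in df.iterrows():
        try:
            kwargs = {name: _coerce(kind, name, row[name]) for name in columns}
            records.append(rec_type(**kwargs))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {idx + 2} ({path}): {exc}")  # +2: header + 1-based
    if errors:
        raise ValidationError("; ".join(errors))
    return records


def read_tables(paths: Mapping[str, Union[str, Path]]):
    """Read several datasets at once: ``{kind: path}`` -> ``{kind: records}``."""
    return {kind: read_table(path, kind) for kind, path in paths.items()}


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Tidy DataFrame view of a homogeneous record list (lists serialised)."""
    rows = []
    for rec in records:
        d = dataclasses.asdict(rec)
        if "worm_counts" in d:
            wc = d["worm_counts"]
            d["worm_counts"] = "" if wc is None else ";".join(str(c) for c in wc)
        rows.append(d)
    return pd.DataFrame(rows)


def write_table(records: Iterable, path: Union[str, Path]) -> None:
    """Write records in the canonical CSV dialect (inverse of read_table)."""
    records = list(records)
    if not records:
        raise ValueError("cannot infer a schema from an empty record list")
    kinds = {type(r) for r in records}
    if len(kinds) != 1:
        raise ValueError(f"mixed record types in one table: {sorted(t.__name__ for t in kinds)}")
    df = records_to_frame(records)
    df.to_csv(path, index=False)
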