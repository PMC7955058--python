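"""Domain types and readers/writers for journey tables and embedding tables.

A *journey table* is the raw longitudinal record stream: one row per
administered medical service, carrying the patient, the doctor, the doctor's
primary specialty, the service code and the date.  Dates are normalized to
integer day (or minute) indices relative to the earliest date in the file so
that all downstream windowing arithmetic is exact.

Embedding tables are serialized in the word2vec text convention: a header
line ``"<count> <dim>"`` followed by one line per entity id.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError

MISSING_SPECIALTY = "UNKNOWN"

JOURNEY_COLUMNS = ("patient_id", "doctor_id", "specialty", "service_code", "date")


class ServiceRecord(NamedTuple):
    patient_id: str
    doctor_id: str
    specialty: str
    service_code: str
    date: int


@dataclass
class JourneyTable:
    """Canonically sorted record stream plus its entity vocabularies.

    Rows are sorted by ``(patient_id, date, service_code, doctor_id)``;
    duplicate rows are retained because multiplicities matter downstream.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in JOURNEY_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"journey table missing column(s): {', '.join(missing)}")
        f = self.frame.loc[:, list(JOURNEY_COLUMNS)].copy()
        f["date"] = f["date"].astype(np.int64)
        if len(f) and (f["date"] < 0).any():
            raise SchemaError("negative date index in journey table")
        f = f.sort_values(
            ["patient_id", "date", "service_code", "doctor_id"],
            kind="mergesort",
        ).reset_index(drop=True)
        self.frame = f

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[ServiceRecord]:
        for row in self.frame.itertuples(index=False):
            yield ServiceRecord(*row)

    @property
    def records(self) -> list[ServiceRecord]:
        return list(self)

    @property
    def patients(self) -> list[str]:
        return sorted(self.frame["patient_id"].unique())

    @property
    def doctors(self) -> list[str]:
        return sorted(self.frame["doctor_id"].unique())

    @property
    def services(self) -> list[str]:
        return sorted(self.frame["service_code"].unique())

    @property
    def specialties(self) -> list[str]:
        return sorted(self.frame["specialty"].unique())

    @classmethod
    def from_records(cls, records) -> "JourneyTable":
        frame = pd.DataFrame(list(records), columns=list(JOURNEY_COLUMNS))
        return cls(frame)


@dataclass
class EmbeddingTable:
    """Mapping entity id -> dense real vector of fixed dimension."""

    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise FormatError("vectors must be a 2-D matrix")
        if len(self.ids) != self.vectors.shape[0]:
            raise FormatError(
                f"{len(self.ids)} ids but {self.vectors.shape[0]} vector rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate entity ids in embedding table")
        if len(self.ids) and not np.isfinite(self.vectors).all():
            raise FormatError("non-finite entries in embedding table")
        self._index = {e: i for i, e in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._index

    def vector(self, entity_id: str) -> np.ndarray:
        try:
            return self.vectors[self._index[entity_id]]
        except KeyError:
            raise KeyError(f"no embedding for entity {entity_id!r}") from None

    def matrix(self, ids) -> np.ndarray:
        """Rows for ``ids`` in order; raises on any missing id."""
        return np.stack([self.vector(i) for i in ids]) if len(ids) else np.empty((0, self.dim))


def _coerce_dates(raw: pd.Series, date_format: str) -> pd.Series:
    """Convert a raw date column to 0-based integer indices.

    ``date_format`` is ``"days"`` (calendar dates or day integers),
    ``"minutes"`` (integer minute offsets, as in ICU event streams) or an explicit
    ``strftime`` pattern for calendar parsing.
    """
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        if not (numeric == numeric.round()).all():
            bad = int(numeric.index[numeric != numeric.round()][0])
            raise FormatError(f"non-integer date index at data row {bad + 1}")
        return numeric.astype(np.int64)
    if date_format == "minutes":
        bad = int(raw.index[numeric.isna()][0])
        raise FormatError(f"unparsable minute index at data row {bad + 1}: {raw.iloc[bad]!r}")
    fmt = None if date_format in ("days", "auto") else date_format
    parsed = pd.to_datetime(raw, format=fmt, errors="coerce")
    if parsed.isna().any():
        bad = int(raw.index[parsed.isna()][0])
        raise FormatError(f"unparsable date at data row {bad + 1}: {raw.iloc[bad]!r}")
    return (parsed - parsed.min()).dt.days.astype(np.int64)


def read_journeys(path, date_format: str = "auto") -> JourneyTable:
    """Read a journey CSV/TSV into a :class:`JourneyTable`.

    Dates become 0-based integer indices relative to the earliest date in
    the file.  Rows with a missing specialty are retained with the sentinel
    ``"UNKNOWN"``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    frame.columns = [c.strip() for c in frame.columns]
    missing = [c for c in JOURNEY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"journey file missing column(s): {', '.join(missing)}")
    frame = frame.loc[:, list(JOURNEY_COLUMNS)]
    if len(frame) == 0:
        frame = frame.assign(date=pd.Series(dtype=np.int64))
        return JourneyTable(frame)
    for col in ("patient_id", "doctor_id", "service_code"):
        if (frame[col].str.strip() == "").any():
            bad = int(frame.index[frame[col].str.strip() == ""][0])
            raise SchemaError(f"empty {col} at data row {bad + 1}")
    frame["specialty"] = frame["specialty"].replace("", MISSING_SPECIALTY)
    dates = _coerce_dates(frame["date"], date_format)
    frame = frame.assign(date=dates - dates.min())
    return JourneyTable(frame)


def write_journeys(table: JourneyTable, path) -> None:
    table.frame.to_csv(path, index=False)


def write_embeddings(table: EmbeddingTable, path) -> None:
    """Write in the word2vec text convention: header "count dim", then rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table.ids)} {table.dim}\n")
        for entity, row in zip(table.ids, table.vectors):
            fh.write(entity + " " + " ".join(repr(float(x)) for x in row) + "\n")


def read_embeddings(path) -> EmbeddingTable:
    with open(path, "r", encoding="utf-8") as fh:
        return _parse_embeddings(fh)


def _parse_embeddings(fh: io.TextIOBase) -> EmbeddingTable:
    header = fh.readline().split()
    if len(header) != 2:
        raise FormatError("embedding header must be '<count> <dim>'")
    count, dim = (int(x) for x in header)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(fh, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split(" ")
        if len(parts) != dim + 1:
            raise FormatError(
                f"line {lineno}: expected {dim} floats, found {len(parts) - 1}"
            )
        ids.append(parts[0])
        rows.append(np.array([float(x) for x in parts[1:]], dtype=np.float64))
    if len(ids) != count:
        raise FormatError(f"header declares {count} rows, file has {len(ids)}")
    vectors = np.stack(rows) if rows else np.empty((0, dim))
    return EmbeddingTable(ids=ids, vectors=vectors)
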