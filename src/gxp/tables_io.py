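"""Reading, validating and serializing quantification and annotation tables.

Quantification tables are TSV/CSV files whose first column holds entity
identifiers and whose remaining column names encode the experimental design:
tokens separated by a configurable character, parsed right-anchored — the
last token is the replicate index, the second-to-last the x-axis factor
level, and any leading tokens are group-factor levels (e.g.
``S_lycopersicum.ctrl1.1``).  Information tables carry free-text,
categorical (possibly multi-valued) or numeric annotation columns keyed by
the same identifiers.  A whole session (settings, tables, plot specs,
analysis results) can be exported to / restored from a zip bundle whose
marker file is ``GXP_settings.json``.
"""

from __future__ import annotations

import io
import json
import math
import os
import tempfile
import warnings
import zipfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from gxp.errors import TableFormatError, ValidationError

BUNDLE_SCHEMA_VERSION = "1.0"
SETTINGS_FILENAME = "GXP_settings.json"


# ---------------------------------------------------------------------------
# sample-name grammar
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleKey:
    """Decomposition of one sample column name.

    ``raw_name`` is reproduced by joining ``group_values + [x_value,
    replicate_id]`` with the separator used at parse time.
    """

    raw_name: str
    group_values: tuple[str, ...]
    x_value: str
    replicate_id: str

    def tokens(self) -> tuple[str, ...]:
        return self.group_values + (self.x_value, self.replicate_id)

    def to_dict(self) -> dict:
        return {
            "raw_name": self.raw_name,
            "group_values": list(self.group_values),
            "x_value": self.x_value,
            "replicate_id": self.replicate_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SampleKey":
        return cls(
            raw_name=d["raw_name"],
            group_values=tuple(d["group_values"]),
            x_value=d["x_value"],
            replicate_id=d["replicate_id"],
        )


def parse_sample_name(raw: str, separator: str = ".") -> SampleKey:
    """Split a sample column name into group levels, x-level and replicate.

    Parsing is anchored at the right: the final token is the replicate
    index, the token before it the x-axis factor level, and everything in
    front (zero or more tokens) the ordered group-factor levels.

    Raises
    ------
    TableFormatError
        If ``raw`` does not contain at least two tokens.
    """
    if len(separator) != 1:
        raise ValidationError(f"separator must be a single character, got {separator!r}")
    tokens = raw.split(separator)
    if len(tokens) < 2 or any(t == "" for t in tokens[-2:]):
        raise TableFormatError(
            f"malformed sample name {raw!r}: expected at least "
            f"<x-value>{separator}<replicate> (>=2 non-empty tokens)"
        )
    return SampleKey(
        raw_name=raw,
        group_values=tuple(tokens[:-2]),
        x_value=tokens[-2],
        replicate_id=tokens[-1],
    )


def join_sample_key(key: SampleKey, separator: str = ".") -> str:
    """Inverse of :func:`parse_sample_name` for separator-free tokens."""
    return separator.join(key.tokens())


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Identifier-by-sample numeric matrix with parsed sample keys."""

    entity_ids: list[str]
    samples: list[SampleKey]
    values: np.ndarray  # shape (n_entities, n_samples), float64
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.samples)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.samples)} samples"
            )
        _check_unique(self.entity_ids, "entity identifier")
        _check_unique([s.raw_name for s in self.samples], "sample column name")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, entity_id: str) -> np.ndarray:
        try:
            i = self.entity_ids.index(entity_id)
        except ValueError:
            raise ValidationError(f"unknown entity id {entity_id!r}") from None
        return self.values[i]

    def x_order(self) -> list[str]:
        """x-axis levels in first-appearance (header) order."""
        seen: list[str] = []
        for s in self.samples:
            if s.x_value not in seen:
                seen.append(s.x_value)
        return seen

    def to_tsv(self, path: str | None = None, delimiter: str = "\t") -> str | None:
        """Write (or return) the matrix as delimited text at full precision."""
        buf = io.StringIO()
        buf.write(delimiter.join(["id"] + [s.raw_name for s in self.samples]) + "\n")
        for i, eid in enumerate(self.entity_ids):
            cells = [repr(float(v)) for v in self.values[i]]
            buf.write(delimiter.join([eid] + cells) + "\n")
        text = buf.getvalue()
        if path is None:
            return text
        _atomic_write_text(path, text)
        return None

    def __eq__(self, other: object) -> bool:  # deep equality incl. values
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.entity_ids == other.entity_ids
            and self.samples == other.samples
            and self.unit == other.unit
            and np.array_equal(self.values, other.values)
        )


def _check_unique(items: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            raise TableFormatError(f"duplicate {what}: {it!r}")
        seen.add(it)


def load_quantification_table(
    path: str,
    delimiter: str = "\t",
    separator: str = ".",
    unit: str = "",
) -> ExpressionMatrix:
    """Load a quantification table; every data cell must be numeric.

    The first column holds entity identifiers; every other column name is
    parsed with :func:`parse_sample_name`.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, engine="python")
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: need an identifier column plus >=1 sample column")
    header = list(df.columns)
    _check_unique(header, "column name")
    sample_names = header[1:]
    samples = []
    for name in sample_names:
        try:
            samples.append(parse_sample_name(name, separator))
        except TableFormatError as exc:
            raise TableFormatError(f"{path}: column {name!r}: {exc}") from None
    entity_ids = df.iloc[:, 0].tolist()
    _check_unique(entity_ids, "entity identifier")
    values = np.empty((len(entity_ids), len(samples)), dtype=float)
    for j, name in enumerate(sample_names):
        col = df[name]
        for i, cell in enumerate(col):
            try:
                # "nan"/"inf" text passes float(); rejected below as non-finite
                v = float(cell)
            except ValueError:
                raise TableFormatError(
                    f"{path}: non-numeric cell {cell!r} at row {entity_ids[i]!r}, "
                    f"column {name!r}"
                ) from None
            if not math.isfinite(v):
                raise TableFormatError(
                    f"{path}: non-finite cell {cell!r} at row {entity_ids[i]!r}, "
                    f"column {name!r}"
                )
            values[i, j] = v
    return ExpressionMatrix(entity_ids=entity_ids, samples=samples, values=values, unit=unit)


# ---------------------------------------------------------------------------
# information table
# ---------------------------------------------------------------------------


@dataclass
class AnnotationColumn:
    """One typed annotation column.

    ``kind`` is ``numeric`` (cells are float or None), ``categorical``
    (repeated vocabulary, optionally multi-valued) or ``text`` (free text).
    """

    name: str
    kind: str  # numeric | categorical | text
    cells: list
    multivalue_delimiter: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical", "text"):
            raise ValidationError(f"unknown column kind {self.kind!r}")
        if self.kind == "numeric":
            for c in self.cells:
                if c is not None and not isinstance(c, float):
                    raise ValidationError(
                        f"numeric column {self.name!r} holds non-float cell {c!r}"
                    )

    def split_cell(self, i: int) -> list[str]:
        """Cell content as a list of values (after multi-value splitting)."""
        cell = self.cells[i]
        if cell is None or cell == "":
            return []
        if self.kind == "numeric":
            return [repr(cell)]
        if self.multivalue_delimiter:
            return [v.strip() for v in str(cell).split(self.multivalue_delimiter) if v.strip()]
        return [str(cell)]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "cells": self.cells,
            "multivalue_delimiter": self.multivalue_delimiter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationColumn":
        cells = d["cells"]
        if d["kind"] == "numeric":
            cells = [None if c is None else float(c) for c in cells]
        return cls(
            name=d["name"],
            kind=d["kind"],
            cells=cells,
            multivalue_delimiter=d.get("multivalue_delimiter"),
        )


@dataclass
class InfoTable:
    """Identifier-keyed table of typed annotation columns."""

    entity_ids: list[str]
    columns: dict[str, AnnotationColumn] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.entity_ids, "entity identifier")
        for col in self.columns.values():
            if len(col.cells) != len(self.entity_ids):
                raise ValidationError(
                    f"column {col.name!r} has {len(col.cells)} cells for "
                    f"{len(self.entity_ids)} entities"
                )
        self._index = {eid: i for i, eid in enumerate(self.entity_ids)}

    def column(self, name: str) -> AnnotationColumn:
        try:
            return self.columns[name]
        except KeyError:
            raise ValidationError(f"unknown annotation column {name!r}") from None

    def cell(self, entity_id: str, column: str):
        return self.column(column).cells[self._index[entity_id]]

    def row_index(self, entity_id: str) -> int:
        try:
            return self._index[entity_id]
        except KeyError:
            raise ValidationError(f"unknown entity id {entity_id!r}") from None

    def to_tsv(self, path: str | None = None, delimiter: str = "\t") -> str | None:
        buf = io.StringIO()
        names = list(self.columns)
        buf.write(delimiter.join(["id"] + names) + "\n")
        for i, eid in enumerate(self.entity_ids):
            cells = []
            for n in names:
                c = self.columns[n].cells[i]
                if c is None:
                    cells.append("")
                elif isinstance(c, float):
                    cells.append(repr(c))
                else:
                    cells.append(str(c))
            buf.write(delimiter.join([eid] + cells) + "\n")
        text = buf.getvalue()
        if path is None:
            return text
        _atomic_write_text(path, text)
        return None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InfoTable):
            return NotImplemented
        return (
            self.entity_ids == other.entity_ids
            and list(self.columns) == list(other.columns)
            and all(
                self.columns[n].to_dict() == other.columns[n].to_dict() for n in self.columns
            )
        )


def _infer_kind(cells: list[str], categorical_fraction: float = 0.5) -> str:
    """numeric iff every non-missing cell parses as a real number; else
    categorical when the vocabulary is small relative to the column, text
    otherwise."""
    non_missing = [c for c in cells if c != ""]
    if not non_missing:
        return "text"
    numeric = True
    for c in non_missing:
        try:
            v = float(c)
        except ValueError:
            numeric = False
            break
        if not math.isfinite(v):
            numeric = False
            break
    if numeric:
        return "numeric"
    distinct = len(set(non_missing))
    if distinct <= max(1, int(categorical_fraction * len(non_missing))):
        return "categorical"
    return "text"


def load_info_table(
    path: str,
    delimiter: str = "\t",
    multivalue_delimiter: str = ",",
    column_kinds: dict[str, str] | None = None,
) -> InfoTable:
    """Load an annotation table keyed by the first column.

    Column kinds are inferred per :func:`_infer_kind`; explicit kinds in
    ``column_kinds`` override inference.  Multi-valued categorical cells are
    split on ``multivalue_delimiter`` by downstream consumers.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, engine="python")
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise TableFormatError(f"{path}: empty information table")
    _check_unique(list(df.columns), "column name")
    entity_ids = df.iloc[:, 0].tolist()
    _check_unique(entity_ids, "entity identifier")
    columns: dict[str, AnnotationColumn] = {}
    overrides = column_kinds or {}
    for name in df.columns[1:]:
        raw = df[name].tolist()
        kind = overrides.get(name) or _infer_kind(raw)
        if kind == "numeric":
            cells: list = [None if c == "" else float(c) for c in raw]
            mv = None
        else:
            cells = list(raw)
            mv = multivalue_delimiter if kind == "categorical" else None
        columns[name] = AnnotationColumn(
            name=name, kind=kind, cells=cells, multivalue_delimiter=mv
        )
    return InfoTable(entity_ids=entity_ids, columns=columns)


def search_entities(
    expr: ExpressionMatrix | None,
    info: InfoTable | None,
    query: str,
) -> list[str]:
    """Case-insensitive substring search over identifiers and non-numeric cells.

    Returns matching ids in input row order (expression matrix order when
    available, information table order otherwise).  The empty query matches
    everything.
    """
    if expr is None and info is None:
        raise ValidationError("search needs at least one table")
    ids = expr.entity_ids if expr is not None else info.entity_ids  # type: ignore[union-attr]
    q = query.lower()
    hits = []
    for eid in ids:
        if q in eid.lower():
            hits.append(eid)
            continue
        if info is not None and eid in info._index:
            i = info._index[eid]
            for col in info.columns.values():
                if col.kind == "numeric":
                    continue
                cell = col.cells[i]
                if cell and q in str(cell).lower():
                    hits.append(eid)
                    break
    return hits


# ---------------------------------------------------------------------------
# settings + session bundle
# ---------------------------------------------------------------------------


@dataclass
class GxpSettings:
    """User-configurable parsing/display settings."""

    separator: str = "."
    x_value_order: list[str] = field(default_factory=list)
    unit: str = ""
    table_field_separators: dict[str, str] = field(
        default_factory=lambda: {"expression": "\t", "info": "\t"}
    )
    multivalue_delimiter: str = ","

    def to_dict(self) -> dict:
        return {
            "schema_version": BUNDLE_SCHEMA_VERSION,
            "separator": self.separator,
            "x_value_order": list(self.x_value_order),
            "unit": self.unit,
            "table_field_separators": dict(self.table_field_separators),
            "multivalue_delimiter": self.multivalue_delimiter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GxpSettings":
        return cls(
            separator=d["separator"],
            x_value_order=list(d["x_value_order"]),
            unit=d["unit"],
            table_field_separators=dict(d["table_field_separators"]),
            multivalue_delimiter=d.get("multivalue_delimiter", ","),
        )


@dataclass
class SessionBundle:
    """A complete restorable session."""

    settings: GxpSettings
    expression: ExpressionMatrix
    info: InfoTable | None = None
    plot_specs: list = field(default_factory=list)  # JSON-able dicts
    analysis_results: list = field(default_factory=list)  # JSON-able dicts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionBundle):
            return NotImplemented
        return (
            self.settings.to_dict() == other.settings.to_dict()
            and self.expression == other.expression
            and self.info == other.info
            and self.plot_specs == other.plot_specs
            and self.analysis_results == other.analysis_results
        )


def check_id_overlap(expr: ExpressionMatrix, info: InfoTable) -> tuple[set, set]:
    """Ids present in only one table: kept, warned about, excluded from
    joint operations by the callers."""
    e, i = set(expr.entity_ids), set(info.entity_ids)
    only_expr, only_info = e - i, i - e
    if only_expr or only_info:
        warnings.warn(
            f"{len(only_expr)} ids only in expression table, "
            f"{len(only_info)} only in information table; "
            "they are excluded from joint operations",
            stacklevel=2,
        )
    return only_expr, only_info


def _atomic_write_text(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_bytes(path: str, data: bytes) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def export_database(session: SessionBundle, path: str) -> None:
    """Write a session as a zip bundle.

    The archive contains ``GXP_settings.json`` (with the schema version),
    the two tables as TSV, and JSON documents for plot specs and analysis
    results.
    """
    buf = io.BytesIO()
    sep = session.settings.table_field_separators.get("expression", "\t")
    isep = session.settings.table_field_separators.get("info", "\t")
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(SETTINGS_FILENAME, json.dumps(session.settings.to_dict(), indent=1))
        expr_meta = {
            "unit": session.expression.unit,
            "samples": [s.to_dict() for s in session.expression.samples],
        }
        zf.writestr("expression.tsv", session.expression.to_tsv(delimiter=sep))
        zf.writestr("expression_meta.json", json.dumps(expr_meta, indent=1))
        if session.info is not None:
            zf.writestr("info.tsv", session.info.to_tsv(delimiter=isep))
            info_meta = {
                name: {"kind": c.kind, "multivalue_delimiter": c.multivalue_delimiter}
                for name, c in session.info.columns.items()
            }
            zf.writestr("info_meta.json", json.dumps(info_meta, indent=1))
        zf.writestr("plot_specs.json", json.dumps(session.plot_specs, indent=1))
        zf.writestr("analysis_results.json", json.dumps(session.analysis_results, indent=1))
    _atomic_write_bytes(path, buf.getvalue())


def import_database(path: str) -> SessionBundle:
    """Restore a session from a bundle written by :func:`export_database`."""
    try:
        zf = zipfile.ZipFile(path)
    except (zipfile.BadZipFile, FileNotFoundError) as exc:
        raise TableFormatError(f"{path}: not a readable bundle ({exc})") from None
    with zf:
        names = set(zf.namelist())
        if SETTINGS_FILENAME not in names:
            raise TableFormatError(f"{path}: missing {SETTINGS_FILENAME}")
        settings_doc = json.loads(zf.read(SETTINGS_FILENAME))
        version = settings_doc.get("schema_version")
        if version != BUNDLE_SCHEMA_VERSION:
            raise TableFormatError(
                f"{path}: unsupported bundle schema version {version!r} "
                f"(this build reads {BUNDLE_SCHEMA_VERSION!r})"
            )
        settings = GxpSettings.from_dict(settings_doc)
        expr_meta = json.loads(zf.read("expression_meta.json"))
        sep = settings.table_field_separators.get("expression", "\t")
        df = pd.read_csv(
            io.StringIO(zf.read("expression.tsv").decode("utf-8")),
            sep=sep,
            dtype=str,
            keep_default_na=False,
            engine="python",
        )
        samples = [SampleKey.from_dict(d) for d in expr_meta["samples"]]
        expression = ExpressionMatrix(
            entity_ids=df.iloc[:, 0].tolist(),
            samples=samples,
            values=df.iloc[:, 1:].astype(float).to_numpy(),
            unit=expr_meta["unit"],
        )
        info = None
        if "info.tsv" in names:
            info_meta = json.loads(zf.read("info_meta.json"))
            isep = settings.table_field_separators.get("info", "\t")
            idf = pd.read_csv(
                io.StringIO(zf.read("info.tsv").decode("utf-8")),
                sep=isep,
                dtype=str,
                keep_default_na=False,
                engine="python",
            )
            columns: dict[str, AnnotationColumn] = {}
            for name in idf.columns[1:]:
                meta = info_meta[name]
                raw = idf[name].tolist()
                if meta["kind"] == "numeric":
                    cells: list = [None if c == "" else float(c) for c in raw]
                else:
                    cells = list(raw)
                columns[name] = AnnotationColumn(
                    name=name,
                    kind=meta["kind"],
                    cells=cells,
                    multivalue_delimiter=meta["multivalue_delimiter"],
                )
            info = InfoTable(entity_ids=idf.iloc[:, 0].tolist(), columns=columns)
        plot_specs = json.loads(zf.read("plot_specs.json"))
        analysis_results = json.loads(zf.read("analysis_results.json"))
    return SessionBundle(
        settings=settings,
        expression=expression,
        info=info,
        plot_specs=plot_specs,
        analysis_results=analysis_results,
    )
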